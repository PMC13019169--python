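"""FRET preprocessing: ratio, bleach correction, normalization, cluster size."""

import numpy as np
import pytest

from arraycrit.fret import (
    FluorescenceTrace,
    FretParams,
    StimulusWindows,
    cluster_intensity,
    fret_index,
    normalize_activity,
    process_cell,
    process_experiment,
    ratio_and_bleach_correct,
)
from arraycrit.synthetic import SynthCellParams, gen_fret_cell, gen_two_state_activity

WIN = StimulusWindows(attractant=[[30.0, 90.0]], repellent=[[810.0, 870.0]])


def _constant_activity_cell(bias, seed=0, **kwargs):
    p = SynthCellParams(noise_sigma=0.0, seed=seed, **kwargs)
    times = np.arange(0, p.duration + 1e-9, 1.0 / p.sample_rate)
    a = np.full(times.size, bias)
    a[(times >= 30) & (times < 90)] = 0.0
    a[(times >= 810) & (times < 870)] = 1.0
    return p, times, a


class TestTraceValidation:
    def test_zero_donor_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceTrace("c", [0.0, 1.0], [1.0, 0.0], [0.5, 0.5])

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceTrace("c", [0.0, 0.0], [1.0, 1.0], [0.5, 0.5])

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            StimulusWindows(attractant=[[0, 10]], repellent=[[5, 15]])


class TestBleachCorrection:
    def test_constant_channels_identity(self):
        t = np.arange(0.0, 900.0)
        tr = FluorescenceTrace("c", t, np.full(t.size, 100.0), np.full(t.size, 40.0))
        R, info = ratio_and_bleach_correct(tr, WIN)
        assert np.allclose(R, 0.4)
        assert info["bleach_rate"] == 0.0

    def test_known_differential_bleach_recovered(self):
        """Constant-bias cell with tau_bleach = 500 s: flat corrected baseline."""
        p, t, a = _constant_activity_cell(0.6, bleach_tau_acceptor=500.0)
        df = gen_fret_cell(t, a, p)
        tr = FluorescenceTrace("c", t, df.donor.values, df.acceptor.values)
        R, info = ratio_and_bleach_correct(tr, WIN)
        buf = WIN.buffer_mask(t)
        rel = R[buf] / R[buf].mean()
        assert info["bleach_rate"] > 0
        assert np.sqrt(((rel - 1) ** 2).mean()) < 0.02


class TestFretIndex:
    def test_zero_at_R0(self):
        f = fret_index(np.full(10, 0.4), FretParams(R0=0.4))
        assert np.allclose(f, 0.0)

    def test_hand_value(self):
        f = fret_index(np.array([0.5]), FretParams(R0=0.4, alpha_fret=0.3))
        assert f[0] == pytest.approx(0.125)

    def test_monotone_in_R(self):
        R = np.linspace(-0.2, 2.0, 50)
        f = fret_index(R, FretParams(R0=0.4))
        assert np.all(np.diff(f) > 0)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            fret_index(np.array([-0.5]), FretParams(R0=0.4, alpha_fret=0.3))


class TestNormalization:
    def test_repellent_window_mean_is_one(self):
        p, t, a = _constant_activity_cell(0.6)
        df = gen_fret_cell(t, a, p)
        tr = FluorescenceTrace("c", t, df.donor.values, df.acceptor.values)
        act = process_cell(tr, WIN)
        rep = WIN.mask(t, "repellent", trim=2)
        assert act.activity[rep].mean() == pytest.approx(1.0, abs=1e-9)

    def test_missing_repellent_window_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            normalize_activity(t, np.full(t.size, 0.1), StimulusWindows(attractant=[[5, 15]]))


class TestRoundTrips:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_noise_free_round_trip_exact(self, seed):
        """Zero noise, equal channel bleach: pipeline inverts exactly."""
        p = SynthCellParams(noise_sigma=0.0, seed=seed)
        t, a, _ = gen_two_state_activity(p)
        df = gen_fret_cell(t, a, p)
        tr = FluorescenceTrace("c", t, df.donor.values, df.acceptor.values)
        act = process_cell(tr, WIN)
        assert np.abs(act.activity - a).max() < 1e-6

    def test_biased_cell_buffer_mean(self):
        """Known bias 0.7, noise-free: buffer-window mean recovered."""
        p = SynthCellParams(
            mean_dt_up=70.0, mean_dt_down=30.0, noise_sigma=0.0, seed=9
        )
        t, a, _ = gen_two_state_activity(p)
        df = gen_fret_cell(t, a, p)
        tr = FluorescenceTrace("c", t, df.donor.values, df.acceptor.values)
        act = process_cell(tr, WIN)
        buf = WIN.buffer_mask(t)
        assert act.activity[buf].mean() == pytest.approx(a[buf].mean(), abs=1e-6)

    def test_bleach_and_noise_round_trip(self):
        """Differential bleach (500 s) + 2% intensity noise: rms error < 0.05."""
        errs = []
        for seed in range(4):
            p, t, a = _constant_activity_cell(0.6, seed=seed, bleach_tau_acceptor=500.0)
            df = gen_fret_cell(t, a, p)
            rng = np.random.default_rng(seed + 70)
            acceptor = df.acceptor.values * (1.0 + rng.normal(0, 0.02, t.size))
            tr = FluorescenceTrace("c", t, df.donor.values, acceptor)
            act = process_cell(tr, WIN)
            errs.append(np.sqrt(((act.activity - a) ** 2).mean()))
        assert np.mean(errs) < 0.05

    def test_activity_noise_round_trip(self):
        """sigma = 0.1 activity noise: rms error < 0.05 over a small cohort."""
        errs = []
        for seed in range(6):
            p = SynthCellParams(noise_sigma=0.0, seed=seed)
            t, a, _ = gen_two_state_activity(p)
            rng = np.random.default_rng(seed + 50)
            noisy = a + rng.normal(0, 0.1, a.size)
            noisy[(t >= 30) & (t < 90)] = np.clip(noisy[(t >= 30) & (t < 90)], -0.1, 0.2)
            df = gen_fret_cell(t, np.clip(noisy, -0.5, 1.5), p)
            tr = FluorescenceTrace("c", t, df.donor.values, df.acceptor.values)
            act = process_cell(tr, WIN)
            errs.append(np.sqrt(((act.activity - np.clip(noisy, -0.5, 1.5)) ** 2).mean()))
        assert np.mean(errs) < 0.05


class TestClusterIntensity:
    def test_flat_profile_zero(self):
        assert cluster_intensity(np.full(50, 3.0)) == 0.0

    def test_narrow_peak_height(self):
        x = np.arange(200.0)
        profile = 5.0 + 2.0 * np.exp(-0.5 * ((x - 30) / 3.0) ** 2)
        dI = cluster_intensity(profile)
        assert dI == pytest.approx(2.0, abs=0.1)

    def test_nonnegative_and_shift_invariant(self, rng):
        profile = rng.normal(-3.0, 1.0, 100)
        dI = cluster_intensity(profile)
        assert dI >= 0.0
        assert cluster_intensity(profile + 17.5) == pytest.approx(dI)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_intensity(np.array([]))


def test_process_experiment_tidy_roundtrip():
    import pandas as pd

    frames = []
    for k in range(2):
        p = SynthCellParams(noise_sigma=0.0, seed=k)
        t, a, _ = gen_two_state_activity(p)
        df = gen_fret_cell(t, a, p)
        df.insert(0, "cell_id", f"c{k}")
        frames.append(df)
    out = process_experiment(pd.concat(frames, ignore_index=True), WIN)
    assert list(out.columns) == ["cell_id", "time_s", "activity"]
    assert out["cell_id"].nunique() == 2
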