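"""Switch detection, dwell and transition statistics, Arrhenius and landscapes."""

import math

import numpy as np
import pytest

from arraycrit.switching import (
    EventDetectionParams,
    SwitchEvent,
    analyze_trace,
    arrhenius_fit,
    classify_two_state,
    delta_G,
    detect_events,
    energy_landscape,
    fit_exponential_residence,
    fit_transition_time,
    noise_strength,
    smooth,
    timescale_ratio,
)
from arraycrit.synthetic import SynthCellParams, gen_two_state_activity


def _telegraph(dwells, dt=1.0, levels=(0.0, 1.0)):
    """Deterministic telegraph trace from a dwell list, starting low."""
    segs = []
    level = 0
    for d in dwells:
        segs.append(np.full(int(round(d / dt)), levels[level]))
        level = 1 - level
    a = np.concatenate(segs)
    return np.arange(a.size) * dt, a


class TestSmooth:
    def test_single_sample_window_is_identity(self):
        a = np.sin(np.arange(50.0))
        assert np.array_equal(smooth(a, 0.5, 1.0), a)

    def test_step_becomes_linear_ramp(self):
        a = np.concatenate([np.zeros(20), np.ones(20)])
        f = smooth(a, 5.0, 1.0)
        ramp = f[(f > 0.05) & (f < 0.95)]
        assert 3 <= ramp.size <= 5
        assert np.all(np.diff(f) >= -1e-12)

    def test_window_exceeding_span_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(10), 20.0, 1.0)


class TestDetectEvents:
    def test_clean_telegraph_counts_and_signs(self):
        t, a = _telegraph([40, 30, 50, 35, 45, 40])
        events = detect_events(t, a)
        assert [e.direction for e in events] == [1, -1, 1, -1, 1]
        truth_times = np.cumsum([40, 30, 50, 35, 45])[:5]
        for e, tt in zip(events, truth_times):
            assert abs(e.t_event - tt) <= 2.0

    def test_constant_trace_no_events(self):
        t = np.arange(500.0)
        assert detect_events(t, np.full(500, 0.3)) == []

    def test_null_noise_false_positive_rate(self):
        """Pure sigma = 0.1 noise: well below one event per 1,000 s."""
        rng = np.random.default_rng(99)
        total = 0
        for _ in range(10):
            a = 0.5 + rng.normal(0, 0.1, 1000)
            total += len(detect_events(np.arange(1000.0), a))
        assert total <= 2

    def test_residences_and_censoring(self):
        t, a = _telegraph([40, 30, 50, 35, 45, 40])
        events = detect_events(t, a)
        assert events[-1].residence is None  # terminal interval censored
        assert events[0].residence == pytest.approx(30.0, abs=2.0)


class TestTransitionTime:
    def test_clean_ramp_recovered(self):
        t = np.arange(0.0, 60.0)
        a = np.where(t < 20, 0.0, 1 - np.exp(-(t - 20) / 2.0))
        tau = fit_transition_time(t, a, SwitchEvent(21.0, 1, 1.0))
        assert tau == pytest.approx(2.0, abs=0.05)

    def test_instantaneous_step_at_resolution_floor(self):
        t = np.arange(0.0, 60.0)
        a = np.where(t < 20, 0.0, 1.0)
        tau = fit_transition_time(t, a, SwitchEvent(20.0, 1, 1.0))
        assert tau <= 1.0

    def test_noisy_cohort_accuracy(self):
        """tau = 2 s ramps at sigma = 0.15: mean relative error < 10%."""
        rng = np.random.default_rng(5)
        taus = []
        for _ in range(60):
            t = np.arange(0.0, 80.0)
            a = np.where(t < 30, 0.0, 1 - np.exp(-(t - 30) / 2.0))
            a = a + rng.normal(0, 0.15, t.size)
            tau = fit_transition_time(t, a, SwitchEvent(31.0, 1, 1.0))
            if np.isfinite(tau):
                taus.append(tau)
        assert abs(np.mean(taus) - 2.0) / 2.0 < 0.10


class TestClassification:
    def _events(self, amps):
        return [SwitchEvent(10.0 * k, 1, a) for k, a in enumerate(amps)]

    def test_all_large_is_two_state(self):
        assert classify_two_state(self._events([0.9] * 6))

    def test_sixty_percent_large_is_not(self):
        amps = [0.9, 0.9, 0.9, 0.5, 0.5]  # 60% of transitions >= 0.7
        assert not classify_two_state(self._events(amps))

    def test_too_few_events_not_switching(self):
        assert not classify_two_state(self._events([0.9, 0.9]))

    def test_threshold_robustness_on_synthetic_cohort(self):
        """Raising (0.65, 0.7) to (0.80, 0.8) barely moves the statistics."""
        strict = EventDetectionParams(two_state_frac=0.80, two_state_amp=0.8)
        dt_default, dt_strict = [], []
        for seed in range(4):
            p = SynthCellParams(
                noise_sigma=0.1, seed=seed, duration=1500.0,
                attractant_windows=[], repellent_windows=[],
            )
            t, a, _ = gen_two_state_activity(p)
            s0, _ = analyze_trace(t, a)
            s1, _ = analyze_trace(t, a, strict)
            if s0.is_two_state and s1.is_two_state:
                dt_default.append(s0.mean_dt)
                dt_strict.append(s1.mean_dt)
        assert dt_default, "cohort produced no two-state cells"
        shift = abs(np.mean(dt_strict) - np.mean(dt_default)) / np.mean(dt_default)
        assert shift < 0.05


class TestDeltaG:
    def test_symmetric_bias_zero(self):
        assert delta_G(0.5) == 0.0

    def test_high_bias(self):
        assert delta_G(0.9) == pytest.approx(math.log(1 / 9), abs=1e-12)

    @pytest.mark.parametrize("a", [0.0, 1.0, -0.1, 1.5])
    def test_boundary_rejected(self, a):
        with pytest.raises(ValueError):
            delta_G(a)


class TestArrhenius:
    def test_parameter_recovery(self, rng):
        dG = np.linspace(-2, 2, 12)
        up = 60.0 * np.exp(-0.35 * dG) * rng.lognormal(0, 0.05, 12)
        dn = 60.0 * np.exp(+0.35 * dG) * rng.lognormal(0, 0.05, 12)
        fit = arrhenius_fit(dG, up, dn)
        assert fit.gamma_up == pytest.approx(0.35, abs=0.05)
        assert fit.gamma_down == pytest.approx(-0.35, abs=0.05)
        assert fit.dt_char == pytest.approx(60.0, rel=0.1)

    def test_symmetric_design_crosses_at_zero(self):
        dG = np.linspace(-1.5, 1.5, 7)
        up = 50.0 * np.exp(-0.4 * dG)
        dn = 50.0 * np.exp(+0.4 * dG)
        fit = arrhenius_fit(dG, up, dn)
        assert fit.dG_cross == pytest.approx(0.0, abs=1e-9)
        assert fit.dt_char == pytest.approx(50.0, rel=1e-9)

    def test_degenerate_design_rejected(self):
        dG = np.full(5, 0.3)
        with pytest.raises(ValueError):
            arrhenius_fit(dG, np.full(5, 40.0), np.full(5, 60.0))

    def test_parallel_lines_rejected(self):
        dG = np.linspace(-1, 1, 6)
        up = 50.0 * np.exp(-0.4 * dG)
        with pytest.raises(ValueError):
            arrhenius_fit(dG, up, 2 * up)


class TestExponentialResidence:
    def test_mean_recovery(self, rng):
        dwells = rng.exponential(50.0, 500)
        fit = fit_exponential_residence(dwells)
        se = 50.0 / math.sqrt(500)
        assert abs(fit.mean - dwells.mean()) < 1e-12
        assert abs(fit.mean - 50.0) < 3 * se
        assert fit.ks_pvalue > 0.01

    def test_deterministic_dwells_rejected(self):
        fit = fit_exponential_residence(np.full(200, 42.0))
        assert fit.ks_pvalue < 0.01

    def test_small_group_skipped(self):
        fit = fit_exponential_residence(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert fit.skipped


class TestLandscape:
    def test_symmetric_two_state(self, rng):
        n = 20000
        state = rng.random(n) < 0.5
        a = np.where(state, 1.0, 0.0) + rng.normal(0, 0.06, n)
        ls = energy_landscape(a)
        assert len(ls.minima) == 2
        assert ls.well_depth_difference < 0.3

    def test_biased_two_state_depth_matches_deltaG(self, rng):
        n = 40000
        state = rng.random(n) < 0.9
        a = np.where(state, 1.0, 0.0) + rng.normal(0, 0.06, n)
        ls = energy_landscape(a)
        assert ls.well_depth_difference == pytest.approx(abs(delta_G(0.9)), abs=0.5)

    def test_unimodal_single_minimum(self, rng):
        ls = energy_landscape(0.5 + rng.normal(0, 0.05, 10000))
        assert len(ls.minima) == 1 or ls.well_depth_difference > 3.0


class TestRatiosAndNoise:
    def test_timescale_ratio_printed_tar_values(self):
        assert round(timescale_ratio(47.0, 4.79, 6.06)) == 9
        assert timescale_ratio(47.0, 4.79, 6.06) == pytest.approx(8.66, abs=0.01)

    def test_timescale_ratio_printed_tsr_values(self):
        assert timescale_ratio(65.5, 4.29, 6.07) == pytest.approx(12.64, abs=0.01)

    def test_timescale_ratio_unity(self):
        assert timescale_ratio(5.0, 5.0, 5.0) == 1.0

    def test_timescale_ratio_invalid(self):
        with pytest.raises(ValueError):
            timescale_ratio(5.0, 0.0, 5.0)

    def test_noise_strength_constant_zero(self):
        assert noise_strength(np.full(100, 0.4), 0.4) == pytest.approx(0.0, abs=1e-12)

    def test_noise_strength_symmetric_telegraph(self):
        a = np.tile([0.0, 1.0], 5000)
        assert noise_strength(a, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_noise_strength_invalid_a0(self):
        with pytest.raises(ValueError):
            noise_strength(np.ones(10), 0.0)


def test_analyze_trace_two_state_summary(clean_switching_cell):
    _, times, activity, truth = clean_switching_cell
    summary, events = analyze_trace(times, activity)
    assert summary.is_two_state
    assert summary.n_events >= 10
    assert 0.3 < summary.mean_activity < 0.7
    assert summary.r > 1.0
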