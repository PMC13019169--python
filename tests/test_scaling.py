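"""Finite-size scaling: J*(L), isolines, constant fitting, omega0 calibration."""

import math

import numpy as np
import pytest

from arraycrit.kmc import SimTrace
from arraycrit.model import J_CRITICAL_INF
from arraycrit.scaling import (
    ScalingConstants,
    SweepRecord,
    calibrate_omega0,
    classify_polarized,
    fit_scaling_constants,
    isoline,
    jstar_of_L,
    reduced_temperature,
    switch_statistics,
)

TRUE = ScalingConstants(z=2.2, b=1.9, c0=0.8, c_tau=0.6, c_dt=0.6 * 10.0)


def _law_r(L, J, c=TRUE):
    eps = reduced_temperature(J, c.J_inf)
    return L ** (c.z - c.b) * math.exp(c.c0 * eps * L) * (c.c_dt / c.c_tau)


def _law_records(L_values, J_values, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for L in L_values:
        for J in J_values:
            tau = TRUE.c_tau * L**TRUE.b * rng.lognormal(0, noise)
            r = _law_r(L, J) * rng.lognormal(0, noise)
            recs.append(
                SweepRecord(
                    L=L, J=J, H_b=0.0, n_events=200, mean_dt=r * tau,
                    mean_tau=tau, r=r, polarized=True, seed=0,
                )
            )
    return recs


class TestJstar:
    def test_thermodynamic_limit(self):
        assert f"{jstar_of_L(1e9):.2f}" == "0.44"
        assert jstar_of_L(1e9) == pytest.approx(J_CRITICAL_INF, rel=1e-8)

    def test_L20_value(self):
        assert jstar_of_L(20) == pytest.approx(0.4407 / (1 - 1.25 / 20), abs=2e-4)
        assert jstar_of_L(20) == pytest.approx(0.4701, abs=2e-4)

    def test_small_L_rejected(self):
        with pytest.raises(ValueError):
            jstar_of_L(1)

    def test_monotone_decreasing_to_limit(self):
        L = np.array([8, 12, 20, 40, 100, 1000])
        vals = np.array([jstar_of_L(x) for x in L])
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] > J_CRITICAL_INF


class TestReducedTemperature:
    def test_zero_at_reference(self):
        assert reduced_temperature(0.44, 0.44) == 0.0

    def test_hand_value(self):
        assert reduced_temperature(0.40, 0.44) == pytest.approx(0.10)

    def test_zero_coupling_rejected(self):
        with pytest.raises(ValueError):
            reduced_temperature(0.0)


class TestSwitchStatistics:
    def test_known_telegraph(self):
        dt = 1.0
        seg = [0.0] * 50 + [1.0] * 70 + [0.0] * 50 + [1.0] * 70 + [0.0] * 50
        a = np.array(seg)
        t = np.arange(a.size) * dt
        ev, dirs, res, (up, dn) = switch_statistics(t, a)
        assert list(dirs) == [-1, 1, -1, 1, -1]
        assert np.allclose(res, [50, 70, 50, 70])
        # instantaneous switches: traversal at the sampling floor
        assert np.all(up <= 2 * dt) and np.all(dn <= 2 * dt)

    def test_ramped_transition_duration(self):
        t = np.arange(0.0, 300.0)
        a = np.where(t < 100, 0.0, np.where(t < 140, (t - 100) / 40.0, 1.0))
        _, _, _, (up, _) = switch_statistics(t, a)
        # linear ramp 0 -> 1 over 40 s: the 0.25 -> 0.75 crossing takes 20 s
        assert up.size == 1
        assert up[0] == pytest.approx(20.0, abs=2.0)


class TestPolarizedClassifier:
    def test_telegraph_polarized(self, rng):
        a = np.where(rng.random(2000) < 0.5, 0.05, 0.95) + rng.normal(0, 0.02, 2000)
        trace = SimTrace(np.arange(2000.0), a)
        assert classify_polarized(trace) is True

    def test_gaussian_not_polarized(self, rng):
        trace = SimTrace(np.arange(2000.0), 0.5 + rng.normal(0, 0.08, 2000))
        assert classify_polarized(trace) is False

    def test_short_trace_undefined(self):
        trace = SimTrace(np.arange(50.0), np.zeros(50))
        assert classify_polarized(trace) is None


class TestIsoline:
    def test_closed_form_inversion(self):
        """J_iso from interpolated records matches the analytic inversion."""
        L_values = [12, 16, 20, 24]
        J_values = np.linspace(0.45, 0.55, 11)
        recs = _law_records(L_values, J_values)
        r_t = 60.0
        res = isoline(recs, r_t, L_values)
        for L, J_hat in zip(res.L, res.J_iso):
            # invert the law: eps = ln(r / L^(z-b) / (c_dt/c_tau)) / (c0 L)
            eps = math.log(r_t / (L ** (TRUE.z - TRUE.b) * TRUE.c_dt / TRUE.c_tau)) / (
                TRUE.c0 * L
            )
            J_exact = TRUE.J_inf / (1 - eps)
            assert J_hat == pytest.approx(J_exact, rel=0.01)

    def test_target_at_jstar_gives_zero_deviation(self):
        L_values = [16, 20]
        J_values = np.linspace(0.45, 0.55, 21)
        recs = _law_records(L_values, J_values)
        for L in L_values:
            r_t = _law_r(L, jstar_of_L(L))
            res = isoline(recs, r_t, [L])
            assert abs(res.pct_dev[0]) < 0.2

    def test_unbracketed_target_flagged(self):
        recs = _law_records([16], [0.45, 0.46])
        res = isoline(recs, 1e6, [16])
        assert res.flags == ["unbracketed"]
        assert math.isnan(res.J_iso[0])


class TestFitScalingConstants:
    def test_recovery_with_noise(self):
        L_values = [12, 16, 20, 24, 28]
        J_values = [jstar_of_L(L) for L in L_values] + list(np.linspace(0.46, 0.55, 6))
        recs = _law_records(L_values, sorted(J_values), noise=0.05, seed=3)
        fit = fit_scaling_constants(recs)
        assert fit.b == pytest.approx(TRUE.b, rel=0.10)
        assert fit.z == pytest.approx(TRUE.z, rel=0.10)
        assert fit.c0 == pytest.approx(TRUE.c0, rel=0.10)
        assert fit.c_tau == pytest.approx(TRUE.c_tau, rel=0.35)

    def test_single_L_rejected(self):
        recs = _law_records([16], np.linspace(0.45, 0.55, 8))
        with pytest.raises(ValueError):
            fit_scaling_constants(recs)

    def test_fitted_collapse_beats_perturbed(self):
        recs = _law_records([12, 16, 20, 24], np.linspace(0.45, 0.55, 8), noise=0.02, seed=4)
        fit = fit_scaling_constants(recs)
        x = np.array([reduced_temperature(r.J, TRUE.J_inf) * r.L for r in recs])
        y = np.array([math.log(r.r) - (fit.z - fit.b) * math.log(r.L) for r in recs])

        def rss(c0):
            resid = y - c0 * x
            return float(np.sum((resid - resid.mean()) ** 2))

        assert rss(fit.c0) <= rss(fit.c0 * 1.5)
        assert rss(fit.c0) <= rss(fit.c0 / 1.5)


class TestCalibrateOmega0:
    def test_linear_in_r(self):
        c = ScalingConstants(z=2.2, b=1.9, c0=0.8, c_tau=0.6)
        w1 = calibrate_omega0(6.0, 60.0, [20, 25], c)
        w2 = calibrate_omega0(12.0, 60.0, [20, 25], c)
        assert np.allclose(w2, 2 * w1)

    def test_monotone_in_L(self):
        c = ScalingConstants(z=2.2, b=1.9, c0=0.8, c_tau=0.6)
        w = calibrate_omega0(12.0, 65.5, np.arange(17, 31), c)
        assert np.all(np.diff(w) > 0)

    def test_zero_residence_rejected(self):
        c = ScalingConstants(z=2.2, b=1.9, c0=0.8, c_tau=0.6)
        with pytest.raises(ValueError):
            calibrate_omega0(12.0, 0.0, [20], c)
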