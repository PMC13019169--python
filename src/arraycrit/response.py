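"""Step-stimulus response ensembles and the speed-amplitude trade-off.

An attractant step is a positive ligand field Delta H switched on at t = 0,
which multiplies each unit's flip-out rate by exp(Delta H (2a - 1)/2) and
drives the array toward the inactive state.  Response time is measured
either per replicate as the first crossing of half-maximal activity
(non-adapting arrays, initialized all-active) or from an exponential or
sigmoidal fit to the ensemble-averaged trace (adapting arrays, initialized
at their a0 ~ 0.5 set point).  Response amplitude follows the convention
1 - <a>/0.5, so full inactivation scores 1 and no response from a = 0.5
scores 0.  Reported speeds are 1/t_R; seconds are obtained from simulation
time through the calibrated 1/omega0 = 30 ms unless configured otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .kmc import AdaptationParams, SimTrace, simulate, simulate_adapting
from .model import FieldProtocol, ModelParams
from .scaling import ScalingConstants, jstar_of_L
from .switching import smooth as _smooth

__all__ = [
    "ResponseRecord",
    "step_response_ensemble",
    "response_time",
    "response_amplitude",
    "tradeoff_scan",
    "OMEGA0_DEFAULT_HZ",
]

#: calibrated fundamental flip frequency used to report seconds (1/30 ms)
OMEGA0_DEFAULT_HZ = 1.0 / 0.030


@dataclass
class ResponseRecord:
    J: float
    dH: float
    n_replicates: int
    t_R: float  # simulation time units
    amplitude: float  # clipped to [0, 1] at reporting
    speed: float  # 1 / t_R
    raw_post_activity: float = math.nan
    censored_frac: float = 0.0
    flag: str = "ok"


@dataclass
class EnsembleResponse:
    times: np.ndarray
    mean: np.ndarray
    replicates: np.ndarray  # (n_reps, n_samples)
    meta: dict = field(default_factory=dict)


def step_response_ensemble(
    params: ModelParams,
    dH: float,
    n_reps: int = 48,
    seed: int = 0,
    adapt: Optional[AdaptationParams] = None,
    duration: float = 6000.0,
    sample_interval: float = 5.0,
    burn_in: float = 0.0,
    init_mode: str = "all_active",
) -> EnsembleResponse:
    """Ensemble of replicate step responses with the field applied at t = 0.

    Non-adapting arrays start all-active; adapting arrays are burnt in to
    their steady state (pass ``burn_in`` > 0) before the step.  Returns the
    per-replicate traces and their mean.
    """
    protocol = FieldProtocol(steps=[(0.0, dH)]) if dH != 0.0 else None
    reps = []
    times = None
    for k in range(n_reps):
        sub = seed + 104729 * k
        if adapt is None:
            tr = simulate(
                params, duration, sample_interval, init_mode=init_mode,
                seed=sub, protocol=protocol, burn_in=burn_in,
            )
        else:
            tr = simulate_adapting(
                params, adapt, duration, sample_interval, seed=sub,
                protocol=protocol, init_mode="random", burn_in=burn_in,
            )
        times = tr.times
        reps.append(tr.activity)
    reps = np.asarray(reps)
    return EnsembleResponse(
        times=times,
        mean=reps.mean(axis=0),
        replicates=reps,
        meta={"J": params.J, "dH": dH, "n_reps": n_reps, "adapt": adapt is not None, "seed": seed},
    )


def _exp_decay(t, a_inf, da, tau):
    return a_inf + da * np.exp(-t / tau)


def _sigmoid(t, a0, a1, t_mid, s):
    return a1 + (a0 - a1) / (1.0 + np.exp((t - t_mid) / s))


def response_time(
    ensemble: EnsembleResponse,
    method: str = "half_crossing",
) -> tuple[float, dict]:
    """Response time t_R of a step-response ensemble.

    ``half_crossing``: mean first-crossing time of a = 0.5 across
    replicates; replicates that never cross are censored at the window end,
    included as lower bounds and flagged.  ``exponential``: time constant of
    a_inf + da exp(-t/tau) fitted to the ensemble mean.  ``sigmoidal``:
    midpoint time of a logistic fit.  Fit non-convergence raises.
    """
    t = ensemble.times
    info: dict = {"method": method}
    if method == "half_crossing":
        crossings = []
        censored = 0
        for a in ensemble.replicates:
            below = np.flatnonzero(a <= 0.5)
            if below.size:
                crossings.append(t[below[0]])
            else:
                crossings.append(t[-1])
                censored += 1
        info["censored_frac"] = censored / len(crossings)
        if censored:
            info["flag"] = "censored"
        return float(np.mean(crossings)), info
    a = ensemble.mean
    if method == "exponential":
        p0 = [float(a[-1]), float(a[0] - a[-1]), max(t[-1] / 10.0, t[1])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _exp_decay, t, a, p0=p0,
                bounds=([-0.5, -2.0, t[1] * 1e-3], [1.5, 2.0, t[-1] * 10]),
                maxfev=5000,
            )
        info["a_inf"] = float(popt[0])
        info["fit"] = [float(v) for v in popt]
        return float(popt[2]), info
    if method == "sigmoidal":
        p0 = [float(a[0]), float(a[-1]), float(t[len(t) // 3]), max(t[-1] / 20.0, t[1])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _sigmoid, t, a, p0=p0,
                bounds=([-0.5, -0.5, t[0], t[1] * 1e-3], [1.5, 1.5, t[-1], t[-1]]),
                maxfev=5000,
            )
        info["fit"] = [float(v) for v in popt]
        return float(popt[2]), info
    raise ValueError(f"unknown method {method!r}")


def response_amplitude(post_activity: float, clip: bool = True) -> float:
    """Response amplitude 1 - <a>(J, dH) / 0.5; clipped to [0, 1] at reporting."""
    amp = 1.0 - post_activity / 0.5
    return float(min(max(amp, 0.0), 1.0)) if clip else float(amp)


def _scan_point_nonadapting(params, dH, n_reps, seed, duration, sample_interval):
    ens = step_response_ensemble(
        params, dH, n_reps=n_reps, seed=seed,
        duration=duration, sample_interval=sample_interval,
    )
    t_R, info = response_time(ens, "half_crossing")
    # late-time plateau of the ensemble mean as the post-response activity
    tail = ens.mean[ens.times >= 0.7 * ens.times[-1]]
    post = float(tail.mean())
    return t_R, post, info.get("censored_frac", 0.0), info.get("flag", "ok")


def crop_to_response(ensemble: EnsembleResponse, pad_frac: float = 0.25) -> EnsembleResponse:
    """Restrict an adapting ensemble to the initial response phase.

    With adaptation the mean trace is non-monotonic (response toward low
    activity, then recovery to the set point); the exponential response fit
    must only see the declining phase, cropped a little past the trough of
    the lightly smoothed mean.
    """
    n = ensemble.mean.size
    dt = float(ensemble.times[1] - ensemble.times[0])
    sm = _smooth(ensemble.mean, max(dt, (n // 50) * dt), dt)
    i_min = int(np.argmin(sm))
    i_hi = min(n, int(i_min * (1 + pad_frac)) + 2)
    if i_hi < 8:
        i_hi = min(n, 8)
    return EnsembleResponse(
        times=ensemble.times[:i_hi],
        mean=ensemble.mean[:i_hi],
        replicates=ensemble.replicates[:, :i_hi],
        meta=dict(ensemble.meta),
    )


def _scan_point_adapting(params, adapt, dH, n_reps, seed, duration, sample_interval, burn_in):
    ens = step_response_ensemble(
        params, dH, n_reps=n_reps, seed=seed, adapt=adapt,
        duration=duration, sample_interval=sample_interval, burn_in=burn_in,
    )
    try:
        t_R, info = response_time(crop_to_response(ens), "exponential")
        post = info["a_inf"]  # fitted response plateau (trough before re-adaptation)
        flag = "ok"
    except (RuntimeError, ValueError):
        t_R, post, flag = math.nan, float(ens.mean[-1]), "fit_failed"
    return t_R, post, 0.0, flag


def tradeoff_scan(
    J_values: Sequence[float],
    dH_values: Sequence[float],
    L: int = 20,
    n_reps: int = 12,
    seed: int = 0,
    adapt: Optional[AdaptationParams] = None,
    duration: Optional[float] = None,
    sample_interval: float = 5.0,
    constants: Optional[ScalingConstants] = None,
) -> tuple[list[ResponseRecord], list[ResponseRecord]]:
    """Speed-amplitude scan over (J, Delta H), plus the critical isoline.

    For each grid point the response time and post-response activity are
    measured on a replicate ensemble (non-adapting: half-crossing and late
    plateau, initialized all-active; adapting: exponential fit to the mean
    after burn-in at the a0 set point).  Returns ``(records, critical)``
    where ``critical`` re-evaluates each Delta H at J = J*(L).
    """
    base = constants or ScalingConstants()
    if duration is None:
        duration = 8000.0 if adapt is None else 6000.0
    records: list[ResponseRecord] = []
    j_grid = list(J_values) + [jstar_of_L(L, base)]
    for i, J in enumerate(j_grid):
        for k, dH in enumerate(dH_values):
            sub = seed + 7 * i + 1303 * k
            params = ModelParams(L=L, J=J, seed=sub)
            if adapt is None:
                t_R, post, cf, flag = _scan_point_nonadapting(
                    params, dH, n_reps, sub, duration, sample_interval
                )
            else:
                burn = 4.0 / max(adapt.k_R + adapt.k_B_rate, 1e-6)
                t_R, post, cf, flag = _scan_point_adapting(
                    params, adapt, dH, n_reps, sub, duration, sample_interval, burn
                )
            records.append(
                ResponseRecord(
                    J=J, dH=dH, n_replicates=n_reps, t_R=t_R,
                    amplitude=response_amplitude(post),
                    speed=1.0 / t_R if t_R > 0 else math.nan,
                    raw_post_activity=post, censored_frac=cf, flag=flag,
                )
            )
    critical = [rec for rec in records if rec.J == j_grid[-1]]
    grid = [rec for rec in records if rec.J != j_grid[-1]]
    return grid, critical
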