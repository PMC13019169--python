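"""Switching statistics of two-state kinase-activity traces.

Implements the event pipeline used for both experimental-style activity
traces and simulated array traces: low-pass moving-average filtering,
switch detection as peaks in the derivative of the filtered signal,
event amplitudes from flanking medians, residence times (interval to the
next event; the terminal, censored interval is dropped), transition times
from saturating-exponential fits, two-state classification with a
renormalization second pass, and the derived statistics: activity bias and
its free-energy difference Delta G = ln[(1 - <a>) / <a>], Arrhenius
residence-time fits, exponential dwell fits, energy landscapes, the
dimensionless timescale ratio r = <Delta t> / <tau>, and the noise
strength eta = sigma_a / a0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "EventDetectionParams",
    "SwitchEvent",
    "CellSwitchingSummary",
    "ArrheniusFit",
    "EnergyLandscape",
    "ExponentialFit",
    "smooth",
    "detect_events",
    "fit_transition_time",
    "classify_two_state",
    "refine_two_state",
    "delta_G",
    "arrhenius_fit",
    "fit_exponential_residence",
    "energy_landscape",
    "timescale_ratio",
    "noise_strength",
    "analyze_trace",
]


@dataclass
class EventDetectionParams:
    """Tunables of the switch detector.

    Time-like fields are in the units of the trace's time axis (seconds for
    experimental traces at 1 Hz; simulation time for model traces).
    ``prominence`` is the required derivative-peak prominence in activity
    units per sample.
    """

    smooth_window: float = 3.0
    prominence: float = 0.10
    min_separation: float = 5.0
    amp_window: float = 4.0
    min_amplitude: float = 0.35
    two_state_frac: float = 0.65
    two_state_amp: float = 0.7
    min_events: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.two_state_frac <= 1 and 0 < self.two_state_amp <= 1):
            raise ValueError("two-state thresholds must lie in (0, 1]")
        if self.smooth_window <= 0 or self.min_separation <= 0 or self.amp_window <= 0:
            raise ValueError("windows must be positive")

    def scaled(self, dt: float) -> "EventDetectionParams":
        """Defaults re-expressed for a trace sampled at interval ``dt``.

        Keeps the per-sample detector geometry of the 1 Hz experimental
        settings (3-sample smoothing, 5-sample separation, 4-sample
        amplitude windows) on traces with a different sampling interval.
        """
        return EventDetectionParams(
            smooth_window=self.smooth_window * dt,
            prominence=self.prominence,
            min_separation=self.min_separation * dt,
            amp_window=self.amp_window * dt,
            min_amplitude=self.min_amplitude,
            two_state_frac=self.two_state_frac,
            two_state_amp=self.two_state_amp,
            min_events=self.min_events,
        )


@dataclass
class SwitchEvent:
    t_event: float
    direction: int  # +1 up, -1 down
    amplitude: float  # signed activity change
    tau: float = math.nan  # transition time; nan when the fit failed
    residence: Optional[float] = None  # time to next event; None if censored


@dataclass
class CellSwitchingSummary:
    cell_id: str
    mean_activity: float
    delta_G: Optional[float]
    n_events: int
    frac_large: float
    is_two_state: bool
    mean_dt_up: float
    mean_dt_down: float
    mean_dt: float
    mean_tau_up: float
    mean_tau_down: float
    mean_tau: float
    r: float
    eta: float


@dataclass
class ArrheniusFit:
    gamma_up: float
    gamma_down: float
    dt_char: float  # characteristic residence time at the line crossing
    dG_cross: float
    intercept_up: float = math.nan
    intercept_down: float = math.nan


@dataclass
class EnergyLandscape:
    bin_centres: np.ndarray
    values: np.ndarray  # -ln p(a), shifted so min = 0; inf where p = 0
    minima: np.ndarray = field(default_factory=lambda: np.empty(0))
    well_depth_difference: float = math.nan


@dataclass
class ExponentialFit:
    rate: float
    mean: float
    n: int
    ks_statistic: float
    ks_pvalue: float
    skipped: bool = False


# ---------------------------------------------------------------------------


def smooth(activity: np.ndarray, window: float, dt: float) -> np.ndarray:
    """Centred moving average with truncated windows at the edges."""
    activity = np.asarray(activity, dtype=np.float64)
    span = dt * (activity.size - 1)
    if window >= span:
        raise ValueError(f"smoothing window {window} >= trace span {span}")
    n = max(1, int(round(window / dt)))
    if n <= 1:
        return activity.copy()
    kernel = np.ones(n)
    num = np.convolve(activity, kernel, mode="same")
    den = np.convolve(np.ones_like(activity), kernel, mode="same")
    return num / den


def detect_events(
    times: np.ndarray,
    activity: np.ndarray,
    params: Optional[EventDetectionParams] = None,
    fit_tau: bool = True,
) -> list[SwitchEvent]:
    """Detect switching events as derivative peaks of the filtered trace.

    Candidate events are prominence-filtered peaks of the derivative of the
    smoothed activity (both signs); overlapping candidates closer than the
    minimum separation are resolved in favour of the stronger derivative,
    and candidates whose flanking activity levels differ by less than
    ``min_amplitude`` are discarded as noise blips.
    Each event gets a signed amplitude (difference of flanking medians over
    ``amp_window``), a residence time to the next event (the terminal
    interval is censored and left ``None``) and, when ``fit_tau``, a
    transition time from a saturating-exponential fit.
    """
    if params is None:
        params = EventDetectionParams()
    times = np.asarray(times, dtype=np.float64)
    activity = np.asarray(activity, dtype=np.float64)
    if times.size < 4:
        return []
    dt = float(times[1] - times[0])
    f = smooth(activity, params.smooth_window, dt)
    d = np.gradient(f)
    cands = []
    for sgn in (+1, -1):
        idx, props = signal.find_peaks(sgn * d, prominence=params.prominence)
        for i, p in zip(idx, props["prominences"]):
            cands.append((float(p), int(i), sgn))
    # greedy strongest-first selection honouring the minimum separation
    cands.sort(reverse=True)
    accepted: list[tuple[int, int]] = []
    min_sep_samples = params.min_separation / dt
    for _, i, sgn in cands:
        if all(abs(i - j) >= min_sep_samples for j, _ in accepted):
            accepted.append((i, sgn))
    accepted.sort()

    guard = params.smooth_window / 2.0
    events = []
    for i, sgn in accepted:
        te = times[i]
        before = activity[(times >= te - guard - params.amp_window) & (times < te - guard)]
        after = activity[(times > te + guard) & (times <= te + guard + params.amp_window)]
        if before.size == 0 or after.size == 0:
            continue
        amp = float(np.median(after) - np.median(before))
        if abs(amp) < params.min_amplitude:
            continue  # derivative blip without a level change: noise
        direction = 1 if amp >= 0 else -1
        events.append(SwitchEvent(t_event=te, direction=direction, amplitude=amp))
    # a slow transition can fire the derivative detector twice; merge
    # same-direction events closer than twice the minimum separation,
    # keeping the larger level change
    merged: list[SwitchEvent] = []
    for ev in events:
        if (
            merged
            and ev.direction == merged[-1].direction
            and ev.t_event - merged[-1].t_event < 2.0 * params.min_separation
        ):
            if abs(ev.amplitude) > abs(merged[-1].amplitude):
                merged[-1] = ev
            continue
        merged.append(ev)
    events = merged
    cap = 6.0 * params.amp_window
    for k, ev in enumerate(events):
        if k + 1 < len(events):
            ev.residence = events[k + 1].t_event - ev.t_event
        if fit_tau:
            # keep a margin from the neighbouring events: their ramps (and
            # the detection lag of the next event) otherwise leak into the
            # fit window and bias tau low
            lo = events[k - 1].t_event + params.amp_window if k > 0 else times[0]
            hi = events[k + 1].t_event - params.amp_window if k + 1 < len(events) else times[-1]
            lo = max(lo, ev.t_event - cap)
            hi = min(hi, ev.t_event + cap)
            popt = None
            if hi > ev.t_event + 2 * dt and ev.t_event - lo > 2 * dt:
                popt = _fit_ramp(times, activity, ev, context=(lo, hi), amp_window=params.amp_window)
            if popt is not None:
                ev.tau = float(popt[1])
                # the fitted plateau change is the full level change, free of
                # the ramp bias that flanking medians pick up on slow switches
                if abs(popt[3]) <= 2.0 and np.sign(popt[3]) == ev.direction:
                    ev.amplitude = float(popt[3])
            else:
                ev.tau = math.nan
    return events


def _ramp_model(t, t0, tau, a_pre, da):
    out = np.full_like(t, a_pre, dtype=np.float64)
    m = t > t0
    out[m] = a_pre + da * (1.0 - np.exp(-(t[m] - t0) / tau))
    return out


def _fit_ramp(times, activity, event, context, amp_window: float = 4.0):
    """Fit the saturating-exponential switch model; None if not converged.

    Returns the optimum of ``a(t) = a_pre + da (1 - exp(-(t - t0)/tau))``
    (parameters t0, tau, a_pre, da) over the context window.  The detected
    event time lags the true switch onset (it is the derivative peak of the
    filtered trace), and the (t0, tau) likelihood surface has local optima
    trading a later onset against a steeper ramp, so the fit is restarted
    from a small grid of onset and timescale initializations and the lowest
    sum of squared residuals wins.
    """
    times = np.asarray(times, dtype=np.float64)
    activity = np.asarray(activity, dtype=np.float64)
    dt = float(times[1] - times[0])
    lo, hi = context
    m = (times >= lo) & (times <= hi)
    if m.sum() < 8:
        return None
    t, a = times[m], activity[m]
    te = event.t_event
    a_pre0 = float(np.median(a[t < te])) if (t < te).any() else a[0]
    da0 = event.amplitude if event.amplitude != 0 else (a[-1] - a[0])
    span = hi - lo
    best = None
    best_ssr = np.inf
    bounds = ([lo, dt * 1e-3, -2.0, -2.5], [hi, span, 3.0, 2.5])
    for t0_off in (-amp_window, -0.5 * amp_window, 0.0):
        for tau0 in (0.5 * amp_window, amp_window, 2.0 * amp_window):
            p0 = [min(max(te + t0_off, lo), hi), min(max(tau0, 2 * dt), span), a_pre0, da0]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(
                        _ramp_model, t, a, p0=p0, bounds=bounds, maxfev=1000
                    )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((_ramp_model(t, *popt) - a) ** 2))
            if ssr < best_ssr:
                best_ssr = ssr
                best = popt
    return best


def fit_transition_time(
    times: np.ndarray,
    activity: np.ndarray,
    event: SwitchEvent,
    context: Optional[tuple] = None,
    amp_window: float = 4.0,
) -> float:
    """Transition time from a saturating-exponential fit.

    Fits ``a(t) = a_pre + da (1 - exp(-(t - t0)/tau))`` for t > t0 in a
    window around the event (mirrored for downward switches via negative
    da) and reports tau, the time over which (1 - 1/e) of the amplitude is
    traversed.  Returns nan when the fit does not converge.
    """
    if context is None:
        te = event.t_event
        context = (te - 6 * amp_window, te + 6 * amp_window)
    popt = _fit_ramp(times, activity, event, context, amp_window=amp_window)
    return math.nan if popt is None else float(popt[1])


def classify_two_state(events: Sequence[SwitchEvent], params: Optional[EventDetectionParams] = None) -> bool:
    """Two-state iff >= ``two_state_frac`` of transitions have |amplitude| >=
    ``two_state_amp`` and the cell has at least ``min_events`` events."""
    if params is None:
        params = EventDetectionParams()
    if len(events) < params.min_events:
        return False
    amps = np.array([abs(e.amplitude) for e in events])
    return float((amps >= params.two_state_amp).mean()) >= params.two_state_frac


def refine_two_state(
    times: np.ndarray,
    activity: np.ndarray,
    events: Sequence[SwitchEvent],
    params: Optional[EventDetectionParams] = None,
) -> tuple[np.ndarray, list[SwitchEvent]]:
    """Second-pass renormalization of a two-state trace.

    Residual bleaching is re-fitted on dwell segments in the cell's dominant
    state (the low state for bias < 0.5, else the high state), divided out,
    and the trace is renormalized by the histogram peak of the high state.
    Events are then re-extracted.  Returns (refined activity, new events).
    """
    if params is None:
        params = EventDetectionParams()
    times = np.asarray(times, dtype=np.float64)
    a = np.asarray(activity, dtype=np.float64).copy()
    bias = float(np.mean(a))
    dominant_high = bias >= 0.5
    mask = np.zeros(times.size, dtype=bool)
    guard = params.smooth_window
    bounds = [times[0]] + [e.t_event for e in events] + [times[-1]]
    level = a[times < bounds[1]].mean() if (times < bounds[1]).any() else bias
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        seg = (times >= lo + guard) & (times <= hi - guard)
        if not seg.any():
            continue
        seg_high = a[seg].mean() >= 0.5
        if seg_high == dominant_high:
            mask |= seg
    # residual bleach: exponential trend of the dominant-state level (only
    # meaningful for the high state; a trend of the a = 0 level carries no
    # multiplicative information)
    if dominant_high and mask.sum() >= 8:
        t_m, a_m = times[mask], a[mask]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    lambda t, c, k: c * np.exp(-k * t),
                    t_m,
                    a_m,
                    p0=[max(a_m.mean(), 1e-3), 0.0],
                    maxfev=1000,
                )
            if popt[0] > 0:
                trend = popt[0] * np.exp(-popt[1] * times)
                a = a / trend * popt[0]
        except (RuntimeError, ValueError):
            pass
    # renormalize by the histogram peak of the high state
    high = a[a > 0.5]
    if high.size >= 10:
        hist, edges = np.histogram(high, bins=20)
        peak = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        if peak > 0.2:
            a = a / peak
    new_events = detect_events(times, a, params)
    return a, new_events


def delta_G(mean_activity: float) -> float:
    """Free-energy difference Delta G = ln[(1 - <a>) / <a>] in k_B T."""
    if not 0.0 < mean_activity < 1.0:
        raise ValueError("mean activity must lie strictly in (0, 1)")
    return math.log((1.0 - mean_activity) / mean_activity)


def arrhenius_fit(
    dG: np.ndarray,
    mean_dt_up: np.ndarray,
    mean_dt_down: np.ndarray,
) -> ArrheniusFit:
    """Arrhenius-type fit <dt_up,down>(dG) = <dt> exp(-gamma_up,down dG).

    Unweighted least squares of ln residence vs Delta G per direction.  The
    characteristic residence time <dt> is read at the crossing of the two
    lines.  Cells lacking residences in a direction are ignored for that
    line (pass nan).
    """
    dG = np.asarray(dG, dtype=np.float64)
    up = np.asarray(mean_dt_up, dtype=np.float64)
    dn = np.asarray(mean_dt_down, dtype=np.float64)
    mu = np.isfinite(dG) & np.isfinite(up) & (up > 0)
    md = np.isfinite(dG) & np.isfinite(dn) & (dn > 0)
    if mu.sum() < 3 or md.sum() < 3:
        raise ValueError("need >= 3 cells with residences in each direction")
    if np.ptp(dG[mu]) == 0 or np.ptp(dG[md]) == 0:
        raise ValueError("degenerate design: all cells at identical Delta G")
    ru = stats.linregress(dG[mu], np.log(up[mu]))
    rd = stats.linregress(dG[md], np.log(dn[md]))
    if math.isclose(ru.slope, rd.slope, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError("Arrhenius lines are parallel; no crossing")
    dg_x = (rd.intercept - ru.intercept) / (ru.slope - rd.slope)
    ln_dt = ru.intercept + ru.slope * dg_x
    return ArrheniusFit(
        gamma_up=-ru.slope,
        gamma_down=-rd.slope,
        dt_char=float(np.exp(ln_dt)),
        dG_cross=float(dg_x),
        intercept_up=float(ru.intercept),
        intercept_down=float(rd.intercept),
    )


def fit_exponential_residence(dwells: np.ndarray, min_n: int = 20) -> ExponentialFit:
    """Maximum-likelihood exponential fit of a dwell-time sample.

    The MLE rate is 1/mean; a Kolmogorov-Smirnov statistic against the
    fitted exponential quantifies goodness of fit.  Groups smaller than
    ``min_n`` are skipped (flagged, not an error).
    """
    dwells = np.asarray(dwells, dtype=np.float64)
    dwells = dwells[np.isfinite(dwells) & (dwells > 0)]
    if dwells.size < min_n:
        return ExponentialFit(math.nan, math.nan, int(dwells.size), math.nan, math.nan, skipped=True)
    mean = float(dwells.mean())
    ks = stats.kstest(dwells, "expon", args=(0.0, mean))
    return ExponentialFit(1.0 / mean, mean, int(dwells.size), float(ks.statistic), float(ks.pvalue))


def energy_landscape(activity: np.ndarray, n_bins: int = 30) -> EnergyLandscape:
    """Coarse-grained landscape -ln p(a), min-shifted to zero.

    Bins with zero counts get +inf.  The two deepest local minima (wells)
    are located and their depth difference reported; it approximates the
    Delta G of the two-state process.
    """
    activity = np.asarray(activity, dtype=np.float64)
    lo = min(-0.15, float(activity.min()))
    hi = max(1.15, float(activity.max()))
    hist, edges = np.histogram(activity, bins=n_bins, range=(lo, hi), density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        vals = -np.log(hist)
    vals = vals - vals[np.isfinite(vals)].min()
    finite = np.where(np.isfinite(vals), vals, np.inf)
    minima_idx, _ = signal.find_peaks(-finite)
    # include edge bins as candidate wells
    cand = list(minima_idx)
    if finite[0] < finite[1]:
        cand.insert(0, 0)
    if finite[-1] < finite[-2]:
        cand.append(n_bins - 1)
    cand = [i for i in cand if np.isfinite(vals[i])]
    cand.sort(key=lambda i: vals[i])
    minima = np.array([centres[i] for i in cand[:2]])
    depth_diff = abs(vals[cand[0]] - vals[cand[1]]) if len(cand) >= 2 else math.nan
    return EnergyLandscape(centres, vals, minima, depth_diff)


def timescale_ratio(mean_dt: float, mean_tau_up: float, mean_tau_down: float) -> float:
    """Dimensionless ratio r = <dt> / <tau>, <tau> = (<tau_+> + <tau_->)/2."""
    if mean_dt <= 0 or mean_tau_up <= 0 or mean_tau_down <= 0:
        raise ValueError("timescales must be positive")
    return mean_dt / (0.5 * (mean_tau_up + mean_tau_down))


def noise_strength(activity: np.ndarray, a0: float) -> float:
    """Noise strength eta = sigma_a / a0 of a steady-state window."""
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    return float(np.std(np.asarray(activity, dtype=np.float64)) / a0)


def _restrict_to_buffer(
    times: np.ndarray,
    events: Sequence[SwitchEvent],
    buffer_mask: np.ndarray,
    margin: float = 4.0,
) -> list[SwitchEvent]:
    """Drop events inside stimulus windows and censor residences that span one.

    Stimulus-driven transitions (and their clamped intervals) must not enter
    the spontaneous-switching statistics; a residence interval interrupted
    by a stimulus window is censored rather than measured across it.
    """
    if buffer_mask.all():
        return list(events)
    kept = []
    for ev in events:
        i = int(np.searchsorted(times, ev.t_event))
        lo = max(0, int(np.searchsorted(times, ev.t_event - margin)))
        hi = min(times.size, int(np.searchsorted(times, ev.t_event + margin)) + 1)
        if buffer_mask[lo:hi].all() and buffer_mask[min(i, times.size - 1)]:
            kept.append(ev)
    for k, ev in enumerate(kept):
        if ev.residence is None:
            continue
        t_next = ev.t_event + ev.residence
        span = (times >= ev.t_event) & (times <= t_next)
        if not buffer_mask[span].all() or (
            k + 1 < len(kept) and not math.isclose(kept[k + 1].t_event, t_next)
        ):
            ev.residence = None
    return kept


def _nanmean(x: list[float]) -> float:
    arr = np.array([v for v in x if v is not None and np.isfinite(v)])
    return float(arr.mean()) if arr.size else math.nan


def analyze_trace(
    times: np.ndarray,
    activity: np.ndarray,
    params: Optional[EventDetectionParams] = None,
    cell_id: str = "",
    buffer_mask: Optional[np.ndarray] = None,
    refine: bool = True,
) -> tuple[CellSwitchingSummary, list[SwitchEvent]]:
    """Full per-cell switching analysis.

    Detects events, classifies the cell, optionally applies the two-state
    renormalization second pass, and summarizes residence/transition
    statistics.  ``buffer_mask`` restricts the activity-bias estimate to
    buffer (stimulus-free) samples.
    """
    if params is None:
        params = EventDetectionParams()
    times = np.asarray(times, dtype=np.float64)
    a = np.asarray(activity, dtype=np.float64)
    events = detect_events(times, a, params)
    sel = buffer_mask if buffer_mask is not None else np.ones(times.size, dtype=bool)
    events = _restrict_to_buffer(times, events, sel, margin=params.amp_window)
    two_state = classify_two_state(events, params)
    if two_state and refine:
        a, new_events = refine_two_state(times, a, events, params)
        new_events = _restrict_to_buffer(times, new_events, sel, margin=params.amp_window)
        if classify_two_state(new_events, params):
            events = new_events
    mean_a = float(a[sel].mean())
    try:
        dG = delta_G(mean_a)
    except ValueError:
        dG = None
    amps = np.array([abs(e.amplitude) for e in events]) if events else np.empty(0)
    frac_large = float((amps >= params.two_state_amp).mean()) if amps.size else 0.0
    dt_up = _nanmean([e.residence for e in events if e.direction > 0])
    dt_dn = _nanmean([e.residence for e in events if e.direction < 0])
    dt_all = _nanmean([e.residence for e in events])
    tau_up = _nanmean([e.tau for e in events if e.direction > 0])
    tau_dn = _nanmean([e.tau for e in events if e.direction < 0])
    tau_mean = 0.5 * (tau_up + tau_dn)
    r = dt_all / tau_mean if (dt_all > 0 and tau_mean > 0) else math.nan
    eta = noise_strength(a[sel], mean_a) if mean_a > 0 else math.nan
    summary = CellSwitchingSummary(
        cell_id=cell_id,
        mean_activity=mean_a,
        delta_G=dG,
        n_events=len(events),
        frac_large=frac_large,
        is_two_state=two_state,
        mean_dt_up=dt_up,
        mean_dt_down=dt_dn,
        mean_dt=dt_all,
        mean_tau_up=tau_up,
        mean_tau_down=tau_dn,
        mean_tau=tau_mean,
        r=r,
        eta=eta,
    )
    return summary, events
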