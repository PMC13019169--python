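"""Rejection-free kinetic Monte Carlo dynamics of the conformational-spread model.

The scheme is the classic two-random-number (BKL / Gillespie) algorithm: one
uniform variate draws the exponentially distributed waiting time to the next
event (mean 1 / total rate), a second selects the event with probability
proportional to its rate.  The rate catalogue is cached per site and only
the flipped site and its <= 4 neighbours are re-rated after each spin flip,
so each event costs O(L) (row-indexed selection) independent of trajectory
length.

Methylation events (adaptation feedback) live in the same continuous-time
event queue as spin flips: every inactive unit with m_i < M carries rate
k_R (+1 methylation), every active unit with m_i > 0 rate k_B (-1), and a
methylation event updates the unit's local bias field H_b,i = alpha (m0 - m_i).

The hot loops are numba-compiled; a pure-Python single step (`kmc_step`) is
kept for small-lattice verification against the exact Boltzmann enumerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .model import (
    AdaptationParams,
    FieldProtocol,
    LatticeState,
    ModelParams,
    build_lattice,
    site_flip_rate,
    uniform_bonds,
)

__all__ = [
    "SimTrace",
    "kmc_step",
    "simulate",
    "simulate_adapting",
    "compute_adaptation_rates",
    "equilibrium_occupancy",
    "sample_states",
]


@dataclass
class SimTrace:
    """Uniformly sampled activity time series from one simulation run.

    ``times`` is the uniform sample grid (1/omega0 units unless rescaled),
    ``activity`` the lattice-mean activity a(t) read piecewise-constantly at
    each grid point, ``mean_methylation`` the lattice-mean methylation level
    (``None`` without adaptation).  ``meta`` records the fully resolved
    parameters and seed for bit-exact replay.
    """

    times: np.ndarray
    activity: np.ndarray
    mean_methylation: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def downsample(self, factor: int) -> "SimTrace":
        """Decimate by an integer factor (mimics slower acquisition)."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("downsampling factor must be a positive integer")
        f = int(factor)
        mm = None if self.mean_methylation is None else self.mean_methylation[::f]
        return SimTrace(self.times[::f], self.activity[::f], mm, dict(self.meta))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c, L):
    s = spins[r, c]
    nb = 0.0
    if c > 0:
        nb += Jh[r, c - 1] * spins[r, c - 1]
    if c < L - 1:
        nb += Jh[r, c] * spins[r, c + 1]
    if r > 0:
        nb += Jv[r - 1, c] * spins[r - 1, c]
    if r < L - 1:
        nb += Jv[r, c] * spins[r + 1, c]
    return omega0 * math.exp(-s * nb + 0.5 * (hglob + bias[r, c]) * s)


@njit(cache=True, inline="always")
def _meth_rate_at(spins, m, M, kR, kB, r, c):
    if spins[r, c] < 0:  # inactive: methylation (CheR)
        if m[r, c] < M:
            return kR
        return 0.0
    if m[r, c] > 0:  # active: demethylation (CheB)
        return kB
    return 0.0


@njit(cache=True)
def _run_segment(
    spins,
    m,
    bias,
    Jh,
    Jv,
    hglob,
    omega0,
    alpha,
    M,
    m0,
    kR,
    kB,
    adapt,
    t_start,
    t_end,
    sample_times,
    act_out,
    mm_out,
    si0,
):
    """Advance the lattice from t_start to t_end, filling samples in place.

    Returns the index of the first unfilled sample.  State arrays are
    modified in place; the caller owns RNG seeding.
    """
    L = spins.shape[0]
    L2 = L * L
    frate = np.empty((L, L))
    mrate = np.zeros((L, L))
    for r in range(L):
        for c in range(L):
            frate[r, c] = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c, L)
            if adapt:
                mrate[r, c] = _meth_rate_at(spins, m, M, kR, kB, r, c)
    row = np.empty(L)
    for r in range(L):
        acc = 0.0
        for c in range(L):
            acc += frate[r, c] + mrate[r, c]
        row[r] = acc
    n_act = 0
    msum = 0.0
    for r in range(L):
        for c in range(L):
            if spins[r, c] > 0:
                n_act += 1
            msum += m[r, c]

    t = t_start
    si = si0
    n_samp = sample_times.size
    while True:
        total = 0.0
        for r in range(L):
            total += row[r]
        t_next = t - math.log(np.random.random()) / total
        # record piecewise-constant samples falling before the next event
        while si < n_samp and sample_times[si] < t_next:
            if sample_times[si] >= t_end:
                return si, t_end
            act_out[si] = n_act / L2
            mm_out[si] = msum / L2
            si += 1
        if t_next >= t_end:
            return si, t_end
        t = t_next
        # --- select event ---
        x = np.random.random() * total
        r = 0
        while r < L - 1 and x >= row[r]:
            x -= row[r]
            r += 1
        c = 0
        is_meth = False
        while True:
            sr = frate[r, c] + mrate[r, c]
            if x < sr or c == L - 1:
                is_meth = x >= frate[r, c] and mrate[r, c] > 0.0
                break
            x -= sr
            c += 1
        # --- execute event ---
        if is_meth:
            if spins[r, c] < 0:
                m[r, c] += 1
                msum += 1.0
            else:
                m[r, c] -= 1
                msum -= 1.0
            bias[r, c] = alpha * (m0 - m[r, c])
            d = (
                _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c, L)
                + _meth_rate_at(spins, m, M, kR, kB, r, c)
                - frate[r, c]
                - mrate[r, c]
            )
            frate[r, c] = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c, L)
            mrate[r, c] = _meth_rate_at(spins, m, M, kR, kB, r, c)
            row[r] += d
        else:
            spins[r, c] = -spins[r, c]
            n_act += 1 if spins[r, c] > 0 else -1
            d = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c, L) - frate[r, c]
            frate[r, c] = d + frate[r, c]
            if adapt:
                nm = _meth_rate_at(spins, m, M, kR, kB, r, c)
                d += nm - mrate[r, c]
                mrate[r, c] = nm
            row[r] += d
            if c > 0:
                nf = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c - 1, L)
                row[r] += nf - frate[r, c - 1]
                frate[r, c - 1] = nf
            if c < L - 1:
                nf = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c + 1, L)
                row[r] += nf - frate[r, c + 1]
                frate[r, c + 1] = nf
            if r > 0:
                nf = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r - 1, c, L)
                row[r - 1] += nf - frate[r - 1, c]
                frate[r - 1, c] = nf
            if r < L - 1:
                nf = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r + 1, c, L)
                row[r + 1] += nf - frate[r + 1, c]
                frate[r + 1, c] = nf


@njit(cache=True)
def _run_occupancy(spins, bias, Jh, Jv, hglob, omega0, n_events):
    """Accumulate time spent in each configuration over n_events flips.

    Configuration index: bit (r * L + c) set iff sigma = +1.  Only sensible
    for small lattices (L <= 4).
    """
    L = spins.shape[0]
    n_conf = 1 << (L * L)
    occ = np.zeros(n_conf)
    frate = np.empty((L, L))
    for r in range(L):
        for c in range(L):
            frate[r, c] = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c, L)
    idx = 0
    for r in range(L):
        for c in range(L):
            if spins[r, c] > 0:
                idx |= 1 << (r * L + c)
    for _ in range(n_events):
        total = 0.0
        for r in range(L):
            for c in range(L):
                total += frate[r, c]
        occ[idx] += -math.log(np.random.random()) / total
        x = np.random.random() * total
        r = 0
        c = 0
        done = False
        for rr in range(L):
            for cc in range(L):
                if x < frate[rr, cc]:
                    r, c = rr, cc
                    done = True
                    break
                x -= frate[rr, cc]
            if done:
                break
        if not done:
            r, c = L - 1, L - 1
        spins[r, c] = -spins[r, c]
        idx ^= 1 << (r * L + c)
        frate[r, c] = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c, L)
        if c > 0:
            frate[r, c - 1] = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c - 1, L)
        if c < L - 1:
            frate[r, c + 1] = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r, c + 1, L)
        if r > 0:
            frate[r - 1, c] = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r - 1, c, L)
        if r < L - 1:
            frate[r + 1, c] = _flip_rate_at(spins, bias, Jh, Jv, hglob, omega0, r + 1, c, L)
    return occ


# ---------------------------------------------------------------------------
# pure-Python reference step
# ---------------------------------------------------------------------------


def kmc_step(
    state: LatticeState,
    params: ModelParams,
    rng: np.random.Generator,
    bonds: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[LatticeState, float]:
    """One rejection-free KMC step (reference implementation).

    Draws the exponential waiting time from the total flip rate, selects the
    flipping site with probability rate/total, and returns the updated state
    together with the waiting time.  Used as a slow, transparent cross-check
    of the compiled kernels on small lattices.
    """
    L = state.L
    rates = np.empty((L, L))
    for r in range(L):
        for c in range(L):
            rates[r, c] = site_flip_rate(state, (r, c), params, bonds=bonds)
    total = rates.sum()
    if not total > 0:
        raise RuntimeError("total flip rate vanished")
    wait = rng.exponential(1.0 / total)
    flat = rates.ravel().cumsum()
    k = int(np.searchsorted(flat, rng.random() * total))
    k = min(k, L * L - 1)
    new = state.copy()
    new.spins[k // L, k % L] *= -1
    new.time = state.time + wait
    return new, wait


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------


def compute_adaptation_rates(n_R: float, V_R: float, L: int, omega0: float) -> float:
    """Methylation rate per unit in omega0 units: (n_R / L^2) * V_R / omega0.

    ``n_R`` is the number of adaptation enzymes per cell, ``V_R`` the
    saturated per-enzyme modification rate (1/s), ``omega0`` the fundamental
    flip frequency (1/s).
    """
    if n_R < 0:
        raise ValueError("n_R must be >= 0")
    if L <= 0 or V_R <= 0 or omega0 <= 0:
        raise ValueError("L, V_R and omega0 must be > 0")
    return (n_R / L**2) * V_R / omega0


def _resolve_segments(params: ModelParams, protocol: Optional[FieldProtocol], duration: float):
    """Split [0, duration] into constant-H_L segments from the protocol."""
    segs = []
    hl = params.H_L
    t_prev = 0.0
    if protocol is not None:
        for t_step, dh in protocol.steps:
            if t_step >= duration:
                break
            if t_step > t_prev:
                segs.append((t_prev, t_step, hl))
                t_prev = t_step
            hl += dh
    segs.append((t_prev, duration, hl))
    return segs


def _simulate(
    params: ModelParams,
    duration: float,
    sample_interval: float,
    init_mode: str,
    seed: Optional[int],
    adapt: Optional[AdaptationParams],
    protocol: Optional[FieldProtocol],
    burn_in: float,
    site_bias: Optional[np.ndarray],
    bonds: Optional[tuple[np.ndarray, np.ndarray]],
    state: Optional[LatticeState],
    return_state: bool,
):
    if not duration > sample_interval > 0:
        raise ValueError("need duration > sample_interval > 0")
    seed = params.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required for reproducible runs")
    L = params.L
    if state is None:
        state = build_lattice(params, init_mode=init_mode, seed=seed, adapt=adapt)
        if site_bias is not None:
            state.site_bias = np.asarray(site_bias, dtype=np.float64).copy()
    if adapt is not None and state.methylation is None:
        state.methylation = np.full((L, L), int(round(adapt.m0)), dtype=np.int64)
    Jh, Jv = uniform_bonds(L, params.J) if bonds is None else bonds
    m = state.methylation if state.methylation is not None else np.zeros((L, L), dtype=np.int64)
    bias = np.ascontiguousarray(state.site_bias, dtype=np.float64)
    if adapt is not None:
        bias = adapt.alpha_m * (adapt.m0 - m.astype(np.float64))
    spins = np.ascontiguousarray(state.spins, dtype=np.int8)

    if adapt is None:
        alpha, M, m0, kR, kB, adapt_on = 0.0, 0, 0.0, 0.0, 0.0, False
    else:
        alpha, M, m0 = adapt.alpha_m, adapt.M, adapt.m0
        kR, kB, adapt_on = adapt.k_R, adapt.k_B_rate, True

    _seed_rng(seed % (2**32))
    empty = np.empty(0, dtype=np.float64)
    if burn_in > 0:
        _run_segment(
            spins, m, bias, np.ascontiguousarray(Jh), np.ascontiguousarray(Jv),
            params.H_b + params.H_L, params.omega0,
            alpha, M, m0, kR, kB, adapt_on,
            -burn_in, 0.0, empty, empty, empty, 0,
        )
    n_samp = int(math.floor(duration / sample_interval)) + 1
    times = np.arange(n_samp) * sample_interval
    act = np.empty(n_samp)
    mm = np.empty(n_samp)
    si = 0
    for t0, t1, hl in _resolve_segments(params, protocol, duration):
        si, _ = _run_segment(
            spins, m, bias, np.ascontiguousarray(Jh), np.ascontiguousarray(Jv),
            params.H_b + hl, params.omega0,
            alpha, M, m0, kR, kB, adapt_on,
            t0, t1, times, act, mm, si,
        )
    # grid points at exactly t = duration (or trailing ties) read final state
    if si < n_samp:
        act[si:] = (spins > 0).mean()
        mm[si:] = m.mean()
    meta = {
        "params": params.to_dict(),
        "adaptation": None if adapt is None else adapt.to_dict(),
        "init": init_mode,
        "seed": int(seed),
        "burn_in": burn_in,
        "sample_interval": sample_interval,
        "duration": duration,
        "protocol": None if protocol is None else [list(s) for s in protocol.steps],
    }
    trace = SimTrace(times, act, mm.copy() if adapt is not None else None, meta)
    if return_state:
        final = LatticeState(
            spins=spins, site_bias=bias,
            methylation=m if adapt is not None else None,
            species=state.species, time=duration,
        )
        return trace, final
    return trace


def simulate(
    params: ModelParams,
    duration: float,
    sample_interval: float,
    init_mode: str = "random",
    seed: Optional[int] = None,
    protocol: Optional[FieldProtocol] = None,
    burn_in: float = 0.0,
    site_bias: Optional[np.ndarray] = None,
    bonds: Optional[tuple[np.ndarray, np.ndarray]] = None,
    downsample: int = 1,
) -> SimTrace:
    """Simulate the non-adapting lattice and sample its mean activity.

    The activity is read piecewise-constantly (value at the latest event at
    or before each grid time) on a uniform grid of spacing
    ``sample_interval``; ``downsample`` applies an additional integer
    decimation to mimic slower acquisition.  ``burn_in`` equilibrates the
    lattice for the given time before sampling starts at t = 0; ``protocol``
    applies ligand-field steps during the sampled window.
    """
    trace = _simulate(
        params, duration, sample_interval, init_mode, seed,
        None, protocol, burn_in, site_bias, bonds, None, False,
    )
    return trace.downsample(downsample) if downsample != 1 else trace


def simulate_adapting(
    params: ModelParams,
    adapt: AdaptationParams,
    duration: float,
    sample_interval: float,
    seed: Optional[int] = None,
    protocol: Optional[FieldProtocol] = None,
    init_mode: str = "random",
    burn_in: float = 0.0,
    bonds: Optional[tuple[np.ndarray, np.ndarray]] = None,
    downsample: int = 1,
) -> SimTrace:
    """Simulate the lattice with methylation feedback.

    Methylation events share the continuous-time event queue with spin
    flips; per-site bias fields track methylation as H_b,i = alpha (m0 - m_i)
    so the feedback counteracts each unit's activity and the mean activity
    relaxes to a0 = k_R / (k_B + k_R).
    """
    trace = _simulate(
        params, duration, sample_interval, init_mode, seed,
        adapt, protocol, burn_in, None, bonds, None, False,
    )
    return trace.downsample(downsample) if downsample != 1 else trace


def equilibrium_occupancy(
    params: ModelParams,
    n_events: int,
    seed: int,
    init_mode: str = "random",
) -> np.ndarray:
    """Empirical time-weighted occupancy of every configuration (L <= 4).

    Runs ``n_events`` KMC flips and accumulates the waiting time spent in
    each configuration, indexed as in :func:`arraycrit.model.exact_equilibrium`.
    Returns normalized occupancies for comparison against the Boltzmann
    distribution.
    """
    if params.L > 4:
        raise ValueError("occupancy tracking limited to L <= 4")
    state = build_lattice(params, init_mode=init_mode, seed=seed)
    Jh, Jv = uniform_bonds(params.L, params.J)
    _seed_rng(seed % (2**32))
    occ = _run_occupancy(
        np.ascontiguousarray(state.spins), state.site_bias, Jh, Jv,
        params.H_b + params.H_L, params.omega0, n_events,
    )
    return occ / occ.sum()


def sample_states(
    params: ModelParams,
    n_states: int,
    spacing: float,
    seed: int,
    burn_in: Optional[float] = None,
    init_mode: str = "random",
    bonds: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> list[np.ndarray]:
    """Snapshot ``n_states`` spin configurations spaced ``spacing`` apart.

    A single chain is burnt in (default: 10 x spacing) and then sampled at
    regular intervals; snapshots feed the correlation-length estimator.
    """
    L = params.L
    state = build_lattice(params, init_mode=init_mode, seed=seed)
    Jh, Jv = uniform_bonds(L, params.J) if bonds is None else bonds
    Jh, Jv = np.ascontiguousarray(Jh), np.ascontiguousarray(Jv)
    spins = np.ascontiguousarray(state.spins)
    m = np.zeros((L, L), dtype=np.int64)
    bias = state.site_bias
    _seed_rng(seed % (2**32))
    empty = np.empty(0, dtype=np.float64)
    if burn_in is None:
        burn_in = 10.0 * spacing
    t = 0.0
    _run_segment(
        spins, m, bias, Jh, Jv, params.H_b + params.H_L, params.omega0,
        0.0, 0, 0.0, 0.0, 0.0, False, t, t + burn_in, empty, empty, empty, 0,
    )
    t += burn_in
    out = []
    for _ in range(n_states):
        _run_segment(
            spins, m, bias, Jh, Jv, params.H_b + params.H_L, params.omega0,
            0.0, 0, 0.0, 0.0, 0.0, False, t, t + spacing, empty, empty, empty, 0,
        )
        t += spacing
        out.append(spins.copy())
    return out
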