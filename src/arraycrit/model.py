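"""Conformational-spread (2D Ising) model of the chemosensory array.

Each allosteric unit (receptor team + kinase) occupies a site of an L x L
lattice with free boundaries and carries a spin ``sigma in {-1, +1}``
(sigma = 2a - 1, where a is the unit's kinase activity).  The lattice energy,
in units of k_B T, is

    H = -sum_<ij> J_ij sigma_i sigma_j + sum_i (h_i / 2) sigma_i

where the first sum runs over nearest-neighbour bonds and
``h_i = H_b + H_b,i + H_L`` collects the global biasing field, any per-site
bias (from methylation or disorder) and the ligand field.  A positive field
favours the inactive state, so a positive ligand step mimics attractant
(kinase-inactivating) stimulation.

This module holds the static model description: parameter containers,
lattice construction, energies, single-site flip rates (the dynamics use
these through a rejection-free kinetic Monte Carlo scheme in
:mod:`arraycrit.kmc`), a brute-force equilibrium enumerator used as a
correctness oracle, and bond-disorder (receptor-species mixing) assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "AdaptationParams",
    "FieldProtocol",
    "LatticeState",
    "J_CRITICAL_INF",
    "build_lattice",
    "neighbour_counts",
    "bond_count",
    "total_energy",
    "site_flip_rate",
    "uniform_bonds",
    "assign_species",
    "exact_equilibrium",
]

#: Exact critical coupling of the infinite 2D Ising lattice under the
#: convention that each anti-aligned bond costs 2J: J* = ln(1 + sqrt(2)) / 2.
J_CRITICAL_INF = 0.5 * math.log(1.0 + math.sqrt(2.0))


@dataclass
class ModelParams:
    """Parameters of the conformational-spread lattice.

    Attributes
    ----------
    L : int
        Lattice side; the array has ``L**2`` allosteric units.
    J : float
        Nearest-neighbour coupling energy (k_B T units).
    H_b : float
        Global biasing field (k_B T).  Positive favours the inactive state.
    H_L : float
        Ligand field (k_B T).  Positive mimics attractant.
    omega0 : float
        Fundamental flip frequency of an isolated unit.  Defaults to 1, i.e.
        simulated times are expressed in units of 1/omega0.
    seed : int, optional
        Default RNG seed for simulations run from these parameters.
    """

    L: int
    J: float
    H_b: float = 0.0
    H_L: float = 0.0
    omega0: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"lattice side L must be >= 2, got {self.L}")
        if self.J < 0:
            raise ValueError(f"coupling J must be >= 0, got {self.J}")
        if self.omega0 <= 0:
            raise ValueError(f"omega0 must be > 0, got {self.omega0}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AdaptationParams:
    """Methylation-feedback parameters.

    Each unit carries an integer methylation level ``0 <= m_i <= M`` that
    sets a local bias field ``H_b,i = alpha_m * (m0 - m_i)``: methylation
    above the offset m0 favours the active state.  Active units are
    demethylated at rate ``k_B_rate`` (CheB analogue) and inactive units
    methylated at rate ``k_R`` (CheR analogue), which is a negative feedback
    driving the mean activity to ``a0 = k_R / (k_B_rate + k_R)``.
    Rates are in omega0 units.
    """

    k_R: float = 0.0015
    k_B_rate: float = 0.0015
    alpha_m: float = 1.0
    M: int = 64
    m0: float = 8.0  # = M / 8

    def __post_init__(self) -> None:
        if not (0 <= self.m0 <= self.M):
            raise ValueError("m0 must lie in [0, M]")
        if self.k_R < 0 or self.k_B_rate < 0:
            raise ValueError("adaptation rates must be >= 0")

    @property
    def a0(self) -> float:
        """Perfect-adaptation set point k_R / (k_B + k_R)."""
        tot = self.k_R + self.k_B_rate
        if tot == 0:
            return float("nan")
        return self.k_R / tot

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FieldProtocol:
    """Ligand-field stimulus protocol.

    ``steps`` is an ordered list of ``(t_start, dH)`` pairs; at each
    ``t_start`` the ligand field H_L is incremented by ``dH``.
    """

    steps: Sequence[tuple] = field(default_factory=list)
    initial_state: str = "random"

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.steps]
        if any(t1 <= t0 for t0, t1 in zip(ts, ts[1:])):
            raise ValueError("protocol step times must be strictly increasing")


@dataclass
class LatticeState:
    """Instantaneous state of the array.

    ``spins`` is an int8 ``(L, L)`` grid of sigma in {-1, +1}; ``site_bias``
    the per-site static field H_b,i; ``methylation`` the integer methylation
    grid (``None`` when adaptation is off); ``species`` the receptor-species
    labels for bond-disordered lattices.
    """

    spins: np.ndarray
    site_bias: np.ndarray
    methylation: Optional[np.ndarray] = None
    species: Optional[np.ndarray] = None
    time: float = 0.0

    @property
    def L(self) -> int:
        return self.spins.shape[0]

    @property
    def activity(self) -> float:
        """Mean activity a = (1/L^2) sum_i (sigma_i + 1) / 2."""
        return float((self.spins.astype(np.float64) + 1.0).mean() / 2.0)

    def copy(self) -> "LatticeState":
        return LatticeState(
            spins=self.spins.copy(),
            site_bias=self.site_bias.copy(),
            methylation=None if self.methylation is None else self.methylation.copy(),
            species=None if self.species is None else self.species.copy(),
            time=self.time,
        )


def build_lattice(
    params: ModelParams,
    init_mode: str = "random",
    seed: Optional[int] = None,
    adapt: Optional[AdaptationParams] = None,
) -> LatticeState:
    """Construct an initial lattice state.

    ``init_mode`` is one of ``all_active`` (sigma = +1 everywhere),
    ``all_inactive`` or ``random`` (i.i.d. fair spins).  When adaptation
    parameters are supplied every site starts at the methylation offset m0,
    so the initial per-site bias is zero.
    """
    L = params.L
    if init_mode == "all_active":
        spins = np.ones((L, L), dtype=np.int8)
    elif init_mode == "all_inactive":
        spins = -np.ones((L, L), dtype=np.int8)
    elif init_mode == "random":
        rng = np.random.default_rng(params.seed if seed is None else seed)
        spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=(L, L))
    else:
        raise ValueError(f"unknown init_mode {init_mode!r}")
    meth = None
    if adapt is not None:
        meth = np.full((L, L), int(round(adapt.m0)), dtype=np.int64)
    return LatticeState(
        spins=spins,
        site_bias=np.zeros((L, L), dtype=np.float64),
        methylation=meth,
    )


def neighbour_counts(L: int) -> np.ndarray:
    """Number of nearest neighbours per site under free boundaries.

    2 at corners, 3 along edges, 4 in the interior.
    """
    n = np.full((L, L), 4, dtype=np.int64)
    n[0, :] -= 1
    n[-1, :] -= 1
    n[:, 0] -= 1
    n[:, -1] -= 1
    return n


def bond_count(L: int) -> int:
    """Number of nearest-neighbour bonds of the free-boundary lattice."""
    return 2 * L * (L - 1)


def uniform_bonds(L: int, J: float) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous bond couplings: (horizontal ``(L, L-1)``, vertical ``(L-1, L)``)."""
    return (np.full((L, L - 1), J, dtype=np.float64), np.full((L - 1, L), J, dtype=np.float64))


def _effective_field(state: LatticeState, params: ModelParams) -> np.ndarray:
    return params.H_b + params.H_L + state.site_bias


def total_energy(
    state: LatticeState,
    params: ModelParams,
    bonds: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Lattice energy -sum_<ij> J_ij s_i s_j + sum_i (h_i/2) s_i in k_B T."""
    s = state.spins.astype(np.float64)
    Jh, Jv = uniform_bonds(state.L, params.J) if bonds is None else bonds
    e_bond = -(Jh * s[:, :-1] * s[:, 1:]).sum() - (Jv * s[:-1, :] * s[1:, :]).sum()
    h = _effective_field(state, params)
    return float(e_bond + 0.5 * (h * s).sum())


def site_flip_rate(
    state: LatticeState,
    site: tuple[int, int],
    params: ModelParams,
    bonds: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Flip rate omega(sigma_i -> -sigma_i) of one unit.

    omega = omega0 * exp(-sigma_i sum_j J_ij sigma_j + (h_i / 2) sigma_i),
    which satisfies detailed balance against the lattice energy exactly.
    """
    r, c = site
    L = state.L
    if not (0 <= r < L and 0 <= c < L):
        raise IndexError(f"site {site} outside {L}x{L} lattice")
    Jh, Jv = uniform_bonds(L, params.J) if bonds is None else bonds
    s = state.spins
    nb = 0.0
    if c > 0:
        nb += Jh[r, c - 1] * s[r, c - 1]
    if c < L - 1:
        nb += Jh[r, c] * s[r, c + 1]
    if r > 0:
        nb += Jv[r - 1, c] * s[r - 1, c]
    if r < L - 1:
        nb += Jv[r, c] * s[r + 1, c]
    h = params.H_b + params.H_L + state.site_bias[r, c]
    si = float(s[r, c])
    return params.omega0 * math.exp(-si * nb + 0.5 * h * si)


def assign_species(
    L: int,
    tar_fraction: float,
    J_same: float,
    J_cross: float,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Well-mixed two-species (Tar/Tsr) labels and per-bond couplings.

    Sites are labelled i.i.d. (1 = Tar with probability ``tar_fraction``,
    0 = Tsr otherwise); bonds between unlike species use ``J_cross``, bonds
    between like species ``J_same``.  Returns ``(species, (Jh, Jv))``.
    """
    if not 0.0 <= tar_fraction <= 1.0:
        raise ValueError("tar_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    species = (rng.random((L, L)) < tar_fraction).astype(np.int8)
    Jh = np.where(species[:, :-1] == species[:, 1:], J_same, J_cross).astype(np.float64)
    Jv = np.where(species[:-1, :] == species[1:, :], J_same, J_cross).astype(np.float64)
    return species, (Jh, Jv)


def exact_equilibrium(params: ModelParams) -> np.ndarray:
    """Exact Boltzmann distribution over all 2^(L^2) spin configurations.

    Configuration ``k`` has site ``(r, c)`` active iff bit ``r * L + c`` of
    ``k`` is set.  Only feasible for L <= 3 (<= 512 states); larger lattices
    are refused.  Serves as a brute-force oracle for the KMC dynamics.
    """
    L = params.L
    if L > 3:
        raise ValueError("exact enumeration limited to L <= 3")
    n_sites = L * L
    n_conf = 1 << n_sites
    energies = np.empty(n_conf, dtype=np.float64)
    state = build_lattice(params, init_mode="all_inactive")
    for k in range(n_conf):
        bits = (k >> np.arange(n_sites)) & 1
        state.spins[:] = (2 * bits - 1).reshape(L, L).astype(np.int8)
        energies[k] = total_energy(state, params)
    w = np.exp(-(energies - energies.min()))
    return w / w.sum()
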