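"""The probabilistic cellular automaton of migration-mode plasticity.

Each lattice site holds at most one cell (volume exclusion) plus an ECM
resistance value ``mu``.  A cell is either amoeboid (``A``: fast,
non-degrading) or mesenchymal (``M``: slow, matrix-degrading).  One model
time step selects a cell uniformly at random and applies, in order:

R1  phenotypic switch — an A-cell becomes M with probability ``alpha*mu``,
    an M-cell becomes A with probability ``beta*(1-mu)``, so stiff/dense
    matrix pushes cells toward the path-generating mesenchymal mode and
    open matrix toward the fast amoeboid mode;
R2  ECM degradation — an M-cell degrades the resistance at its site,
    ``mu -> (1-delta)*mu`` (partial, never complete);
R3  migration — with probability ``c_X / (1 + exp(15*(mu-0.5)))`` the cell
    attempts a step to a von Neumann neighbour drawn from the chemotactic
    distribution; the step succeeds only onto an empty on-lattice site,
    otherwise it is aborted (exclusion process).

``n`` consecutive time steps (``n`` = population size) form one Monte
Carlo step (MCS), the model's time unit.  Boundaries are periodic in
``r1`` and reflecting in ``r2``: a move off the left or right edge is
aborted.  The move-direction distribution weights each neighbour by
``exp(kappa * S2 * dG)`` where ``dG = ±1/S2`` is the gradient increment,
i.e. right ∝ e^kappa, left ∝ e^-kappa, up/down ∝ 1; ``kappa = 0``
recovers an unbiased random walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from enum import Enum
from typing import NamedTuple, Optional

import numpy as np

from .environment import ECMField, LatticeDims, make_homogeneous_ecm

__all__ = [
    "Phenotype",
    "ModelParams",
    "Cell",
    "SimulationState",
    "initialize",
    "switch_rate",
    "migration_rate",
    "degrade_ecm",
    "chemotactic_move_distribution",
    "step_cell",
    "run_mcs",
]

_SIGMOID_SLOPE = 15.0
_SIGMOID_MID = 0.5


class Phenotype(Enum):
    """Migration mode; lattice cell-state values 1 (A) and 2 (M)."""

    A = 1
    M = 2


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ModelParams:
    """Rule parameters and run geometry.

    All rate constants are per-attempt probabilities in ``[0, 1]``.
    ``switching=False`` is the non-switching population: ``alpha`` and
    ``beta`` are forced to zero and the M-cell fraction is ``gamma``.
    For switching populations the initial M fraction is
    ``initial_m_fraction`` (the steady behaviour depends only on
    ``alpha/beta``, not on this split).
    """

    alpha: float = 0.0
    beta: float = 0.0
    c_a: float = 1.0
    c_m: float = 0.5
    delta: float = 0.1
    kappa: float = 1.0
    gamma: float = 0.0
    switching: bool = True
    initial_m_fraction: float = 0.5
    n_cells: int = 50
    mcs: int = 200
    dims: LatticeDims = dc_field(default_factory=lambda: LatticeDims(100, 300))
    seed: Optional[int] = None
    degradation: str = "multiplicative"  # or "subtractive"
    bias: str = "exponential"  # or "linear"
    switch_update: str = "kinetic"  # or "equilibrium"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "c_a", "c_m", "delta", "gamma",
                     "initial_m_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kappa < 0.0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.c_m > self.c_a:
            raise ValueError("c_m must not exceed c_a (A-cells are the faster mode)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.mcs < 0:
            raise ValueError("mcs must be non-negative")
        if not self.switching and (self.alpha != 0.0 or self.beta != 0.0):
            object.__setattr__(self, "alpha", 0.0)
            object.__setattr__(self, "beta", 0.0)
        if self.degradation not in ("multiplicative", "subtractive"):
            raise ValueError(f"unknown degradation mode {self.degradation!r}")
        if self.bias not in ("exponential", "linear"):
            raise ValueError(f"unknown bias form {self.bias!r}")
        if self.switch_update not in ("kinetic", "equilibrium"):
            raise ValueError(f"unknown switch update {self.switch_update!r}")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


class Cell(NamedTuple):
    """Read-only view of one cell in the registry (1-based coordinates)."""

    id: int
    phenotype: Phenotype
    position: tuple[int, int]
    initial_position: tuple[int, int]


@dataclass
class SimulationState:
    """Mutable automaton state.

    ``occupancy[i, j]`` holds the cell id at site ``(r1=i+1, r2=j+1)`` or
    ``-1`` when empty.  Per-cell arrays are 0-based internally; the public
    accessors speak 1-based lattice coordinates.  Cell count is conserved
    (no birth or death) and the ECM is non-increasing at every site.
    """

    ecm: ECMField
    occupancy: np.ndarray
    r1: np.ndarray  # 0-based row per cell
    r2: np.ndarray  # 0-based column per cell
    r1_init: np.ndarray
    r2_init: np.ndarray
    phenotype_code: np.ndarray  # 0 = A, 1 = M
    time: int = 0  # single-cell update attempts so far
    mcs_elapsed: int = 0

    @property
    def dims(self) -> LatticeDims:
        return self.ecm.dims

    @property
    def n_cells(self) -> int:
        return len(self.r1)

    def cell(self, cell_id: int) -> Cell:
        return Cell(
            id=cell_id,
            phenotype=Phenotype.M if self.phenotype_code[cell_id] else Phenotype.A,
            position=(int(self.r1[cell_id]) + 1, int(self.r2[cell_id]) + 1),
            initial_position=(
                int(self.r1_init[cell_id]) + 1,
                int(self.r2_init[cell_id]) + 1,
            ),
        )

    def cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(self.n_cells)]

    def phenotype_counts(self) -> tuple[int, int]:
        """(number of A-cells, number of M-cells)."""
        m = int(self.phenotype_code.sum())
        return self.n_cells - m, m

    def check_consistency(self) -> None:
        """Raise if the occupancy grid and cell registry disagree."""
        occ = np.flatnonzero(self.occupancy.ravel() >= 0)
        sites = self.r1 * self.dims.s2 + self.r2
        if len(occ) != self.n_cells or not np.array_equal(np.sort(sites), occ):
            raise RuntimeError("occupancy grid and cell registry are inconsistent")
        ids = self.occupancy.ravel()[sites]
        if not np.array_equal(ids, np.arange(self.n_cells)):
            raise RuntimeError("occupancy grid and cell registry are inconsistent")


def initialize(
    params: ModelParams,
    ecm: Optional[ECMField] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulationState:
    """Seed the population along the left border ``r2 = 1``.

    ``n_cells`` cells are placed on distinct, randomly chosen rows of the
    first column.  Switching populations start with
    ``round(initial_m_fraction * n)`` M-cells (default: half), non-switching
    populations with ``round(gamma * n)`` M-cells; which cells are M is
    randomised.  If no ECM field is given, a homogeneous ``mu = 0.5`` field
    is installed.
    """
    dims = params.dims
    n = params.n_cells
    if n > dims.s1:
        raise ValueError(
            f"cannot place {n} cells in a seeding column of height {dims.s1}"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if ecm is None:
        ecm = make_homogeneous_ecm(dims, 0.5)
    elif ecm.dims != dims:
        raise ValueError("ECM field dimensions do not match params.dims")

    rows = rng.choice(dims.s1, size=n, replace=False)
    frac = params.initial_m_fraction if params.switching else params.gamma
    m_count = _round_half_up(frac * n)
    phen = np.zeros(n, dtype=np.int8)
    phen[:m_count] = 1
    phen = rng.permutation(phen)

    occupancy = np.full(dims.shape, -1, dtype=np.int64)
    occupancy[rows, 0] = np.arange(n)
    return SimulationState(
        ecm=ecm.copy(),
        occupancy=occupancy,
        r1=rows.astype(np.int64),
        r2=np.zeros(n, dtype=np.int64),
        r1_init=rows.astype(np.int64),
        r2_init=np.zeros(n, dtype=np.int64),
        phenotype_code=phen,
    )


def switch_rate(phenotype: Phenotype, mu: float, params: ModelParams) -> float:
    """R1 rate: ``alpha*mu`` for A-cells, ``beta*(1-mu)`` for M-cells."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    if phenotype is Phenotype.A:
        return params.alpha * mu
    return params.beta * (1.0 - mu)


def migration_rate(phenotype: Phenotype, mu: float, params: ModelParams) -> float:
    """R3 rate: sigmoid decay of motility with local resistance.

    ``c_X / (1 + exp(15*(mu - 0.5)))`` — near ``c_X`` in open matrix,
    steepest at ``mu = 0.5``, close to zero in dense matrix.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    c = params.c_a if phenotype is Phenotype.A else params.c_m
    return c / (1.0 + math.exp(_SIGMOID_SLOPE * (mu - _SIGMOID_MID)))


def degrade_ecm(mu: float, delta: float, mode: str = "multiplicative") -> float:
    """R2: degrade local resistance.

    Default is multiplicative decay ``(1-delta)*mu`` so repeated degradation
    is partial but never complete; ``"subtractive"`` gives ``max(0, mu-delta)``
    for sensitivity checks.
    """
    if mode == "multiplicative":
        return (1.0 - delta) * mu
    if mode == "subtractive":
        return max(0.0, mu - delta)
    raise ValueError(f"unknown degradation mode {mode!r}")


_DIRECTIONS = ("left", "right", "up", "down")


def _direction_probs(kappa: float, bias: str) -> tuple[float, float, float, float]:
    """(left, right, up, down) move probabilities for the given responsiveness."""
    if bias == "exponential":
        w = (math.exp(-kappa), math.exp(kappa), 1.0, 1.0)
    elif bias == "linear":
        w = (max(0.0, 1.0 - kappa), 1.0 + kappa, 1.0, 1.0)
    else:
        raise ValueError(f"unknown bias form {bias!r}")
    z = sum(w)
    return tuple(x / z for x in w)  # type: ignore[return-value]


def chemotactic_move_distribution(
    position: tuple[int, int],
    kappa: float,
    dims: LatticeDims,
    bias: str = "exponential",
) -> dict[str, float]:
    """Move-direction distribution over the von Neumann neighbourhood.

    The linear gradient makes the distribution position-independent:
    weights are ``exp(kappa*S2*dG)`` with ``dG = ±1/S2`` toward/away from
    the target column and 0 transversally.  Moves that would leave the
    lattice in ``r2`` keep their usual weight here and are aborted at
    execution time (reflecting boundary).
    """
    from .environment import _check_coords

    _check_coords(position[0], position[1], dims)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    p = _direction_probs(kappa, bias)
    return dict(zip(_DIRECTIONS, p))


class _Workspace:
    """Flat-list mirror of a SimulationState for the hot update loop.

    Scalar indexing on plain Python lists is several times faster than on
    numpy arrays, which dominates the per-update cost at these problem
    sizes.  ``write_back`` restores the canonical numpy representation.
    """

    __slots__ = (
        "s1", "s2", "ecm", "occ", "site", "phen",
        "alpha", "beta", "c_a", "c_m", "one_minus_delta", "delta",
        "switching", "equilibrium", "multiplicative",
        "cum_left", "cum_right", "cum_up",
    )

    def __init__(self, state: SimulationState, params: ModelParams) -> None:
        dims = state.dims
        self.s1 = dims.s1
        self.s2 = dims.s2
        self.ecm = state.ecm.values.ravel().tolist()
        self.occ = state.occupancy.ravel().tolist()
        self.site = (state.r1 * dims.s2 + state.r2).tolist()
        self.phen = state.phenotype_code.tolist()
        self.alpha = params.alpha
        self.beta = params.beta
        self.c_a = params.c_a
        self.c_m = params.c_m
        self.delta = params.delta
        self.one_minus_delta = 1.0 - params.delta
        self.switching = params.switching
        self.equilibrium = params.switch_update == "equilibrium"
        self.multiplicative = params.degradation == "multiplicative"
        p_left, p_right, p_up, _ = _direction_probs(params.kappa, params.bias)
        self.cum_left = p_left
        self.cum_right = p_left + p_right
        self.cum_up = p_left + p_right + p_up

    def update(self, j: int, u_switch: float, u_mig: float, u_dir: float) -> None:
        """Apply R1→R2→R3 to cell ``j`` with the three supplied uniforms."""
        k = self.site[j]
        mu = self.ecm[k]
        ph = self.phen[j]
        if self.switching:
            if self.equilibrium:
                # fast-switching limit: resample from the local stationary law,
                # which depends on alpha/beta only through their ratio
                a = self.alpha * mu
                b = self.beta * (1.0 - mu)
                if a + b > 0.0:
                    ph = 1 if u_switch < a / (a + b) else 0
                    self.phen[j] = ph
            else:
                rate = self.alpha * mu if ph == 0 else self.beta * (1.0 - mu)
                if u_switch < rate:
                    ph = 1 - ph
                    self.phen[j] = ph
        if ph == 1:
            if self.multiplicative:
                mu *= self.one_minus_delta
            else:
                mu = mu - self.delta
                if mu < 0.0:
                    mu = 0.0
            self.ecm[k] = mu
        c = self.c_a if ph == 0 else self.c_m
        if u_mig >= c / (1.0 + math.exp(15.0 * (mu - 0.5))):
            return
        s2 = self.s2
        r1, r2 = divmod(k, s2)
        if u_dir < self.cum_left:
            if r2 == 0:
                return  # reflecting left boundary
            kt = k - 1
        elif u_dir < self.cum_right:
            if r2 == s2 - 1:
                return  # reflecting right boundary
            kt = k + 1
        elif u_dir < self.cum_up:
            kt = k - s2 if r1 > 0 else k + (self.s1 - 1) * s2
        else:
            kt = k + s2 if r1 < self.s1 - 1 else k - (self.s1 - 1) * s2
        if self.occ[kt] == -1:
            self.occ[k] = -1
            self.occ[kt] = j
            self.site[j] = kt

    def write_back(self, state: SimulationState) -> None:
        dims = state.dims
        state.ecm.values = np.asarray(self.ecm, dtype=np.float64).reshape(dims.shape)
        state.occupancy = np.asarray(self.occ, dtype=np.int64).reshape(dims.shape)
        site = np.asarray(self.site, dtype=np.int64)
        state.r1 = site // dims.s2
        state.r2 = site % dims.s2
        state.phenotype_code = np.asarray(self.phen, dtype=np.int8)


def step_cell(
    state: SimulationState,
    cell_id: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> SimulationState:
    """One single-cell update (rules R1→R2→R3) applied in place.

    Draws three uniforms from ``rng`` (switch, migration, direction) in that
    order.  ``run_mcs`` applies the same kernel with block-wise draws.
    """
    if not 0 <= cell_id < state.n_cells:
        raise IndexError(f"invalid cell id {cell_id}")
    ws = _Workspace(state, params)
    u = rng.random(3)
    ws.update(cell_id, u[0], u[1], u[2])
    ws.write_back(state)
    state.time += 1
    return state


def run_mcs(
    state: SimulationState,
    params: ModelParams,
    rng: np.random.Generator,
    n_mcs: int,
) -> SimulationState:
    """Advance the automaton by ``n_mcs`` Monte Carlo steps in place.

    Executes ``n_mcs * n_cells`` single-cell updates, each on a cell chosen
    uniformly at random with replacement.  Per MCS the stream is consumed
    as one block of ``n`` cell indices followed by a ``3 × n`` uniform
    block (switch, migration, direction rows); update ``j`` of the MCS uses
    column ``j`` of each.
    """
    n = state.n_cells
    ws = _Workspace(state, params)
    update = ws.update
    for _ in range(n_mcs):
        idx = rng.integers(0, n, size=n).tolist()
        u = rng.random((3, n))
        u_sw = u[0].tolist()
        u_mig = u[1].tolist()
        u_dir = u[2].tolist()
        for j in range(n):
            update(idx[j], u_sw[j], u_mig[j], u_dir[j])
    ws.write_back(state)
    state.time += n_mcs * n
    state.mcs_elapsed += n_mcs
    return state
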