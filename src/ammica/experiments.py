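"""Reproducible experiment recipes for the simulation study.

The study compares a *switching* population (cells change mode at rates
``alpha*mu`` / ``beta*(1-mu)``, scanned over the switch ratio ``alpha/beta``)
against *non-switching* populations of fixed composition (M-cell fraction
``gamma``), under combinations of ECM structure (homogeneous level, or
heterogeneous with structure parameter ``theta``) and chemotactic
responsiveness ``kappa``.  Recipes provided here:

* ``run_scenario`` — both arms over their parameter grids at one
  environmental setting;
* ``critical_resistance_scan`` — the homogeneous resistance level at which
  the pure-A / pure-M ranking of mean ``d_p`` flips;
* ``phase_diagram`` — best-switching minus best-non-switching ``d_p``
  (``delta_d_p``) over a ``(theta, c_M/c_A)`` grid;
* ``kappa_sensitivity`` — ``delta_d_p`` as a function of ``kappa``;
* ``cooperativity_experiment`` — four-arm comparison of the farthest cell
  in a population versus the best of equally many solitary cells.

Replicate ``r`` of any arm is seeded ``base_seed + r``, so arms share
common random numbers and every recipe is a pure function of its spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics import ModelParams, initialize, run_mcs
from .environment import (
    ECMField,
    LatticeDims,
    make_heterogeneous_ecm,
    make_homogeneous_ecm,
)
from .observables import (
    ComparisonResult,
    PopulationSummary,
    compare_best,
    summarize_population,
)

__all__ = [
    "EcmSpec",
    "ScenarioSpec",
    "PhaseDiagramSpec",
    "ScenarioResult",
    "CriticalScanResult",
    "PhaseDiagramResult",
    "KappaSensitivityResult",
    "CooperativityResult",
    "DEFAULT_RATIO_GRID",
    "DEFAULT_GAMMA_GRID",
    "ratio_to_alpha_beta",
    "run_single",
    "run_replicates",
    "run_scenario",
    "critical_resistance_scan",
    "phase_diagram",
    "kappa_sensitivity",
    "cooperativity_experiment",
]

# alpha/beta in {1/10, 2/10, ..., 1, 2, ..., 10}
DEFAULT_RATIO_GRID: tuple[float, ...] = tuple(
    [round(i / 10, 10) for i in range(1, 10)] + [float(i) for i in range(1, 11)]
)
DEFAULT_GAMMA_GRID: tuple[float, ...] = (0.0, 0.3, 0.7, 1.0)


def ratio_to_alpha_beta(ratio: float) -> tuple[float, float]:
    """Realize a switch ratio as Table-range rate constants.

    ``ratio <= 1`` gives ``(alpha=ratio, beta=1)``; ``ratio > 1`` gives
    ``(alpha=1, beta=1/ratio)``.  Behaviour depends on the ratio only.
    """
    if ratio <= 0:
        raise ValueError("switch ratio must be positive")
    if ratio <= 1.0:
        return float(ratio), 1.0
    return 1.0, 1.0 / float(ratio)


@dataclass(frozen=True)
class EcmSpec:
    """ECM scenario descriptor: homogeneous level or heterogeneous theta."""

    kind: str = "heterogeneous"
    level: float = 0.5
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown ECM kind {self.kind!r}")

    def build(self, dims: LatticeDims, rng: np.random.Generator) -> ECMField:
        if self.kind == "homogeneous":
            return make_homogeneous_ecm(dims, self.level)
        return make_heterogeneous_ecm(dims, self.theta, rng)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario matrix plus its scan grids."""

    ecm: EcmSpec = dc_field(default_factory=EcmSpec)
    kappa: float = 1.0
    c_ratio: float = 0.25  # c_M / c_A with c_A fixed at 1
    ratio_grid: tuple[float, ...] = DEFAULT_RATIO_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    n_cells: int = 50
    mcs: int = 200
    replicates: int = 50
    base_seed: int = 0
    dims: LatticeDims = dc_field(default_factory=lambda: LatticeDims(100, 300))
    delta: float = 0.1
    c_a: float = 1.0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.ratio_grid or not self.gamma_grid:
            raise ValueError("scan grids must be non-empty")

    def params(self, **overrides) -> ModelParams:
        base = dict(
            c_a=self.c_a,
            c_m=self.c_a * self.c_ratio,
            delta=self.delta,
            kappa=self.kappa,
            n_cells=self.n_cells,
            mcs=self.mcs,
            dims=self.dims,
        )
        base.update(overrides)
        return ModelParams(**base)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    switching: dict[float, list[PopulationSummary]]
    nonswitching: dict[float, list[PopulationSummary]]

    def compare_best(self) -> ComparisonResult:
        return compare_best(self.switching, self.nonswitching)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-(arm, setting, replicate) table."""
        rows = []
        for arm, data, key in (
            ("switching", self.switching, "ratio"),
            ("nonswitching", self.nonswitching, "gamma"),
        ):
            for setting, summaries in data.items():
                for s in summaries:
                    rows.append(
                        {
                            "arm": arm,
                            "setting_name": key,
                            "setting": setting,
                            "replicate": s.replicate_id,
                            "d_p": s.d_p,
                            "d_max": s.d_max,
                            "within_sd": s.within_sd,
                            "d_p_axial": s.d_p_axial,
                            "d_max_axial": s.d_max_axial,
                            "frac_M": s.phenotype_fractions[1],
                        }
                    )
        return pd.DataFrame(rows)


def run_single(
    params: ModelParams,
    ecm_spec: EcmSpec,
    seed,
    replicate_id: Optional[int] = None,
    metric: str = "euclidean",
) -> PopulationSummary:
    """One full simulation: build field, seed cells, run, summarize.

    All randomness (noise field, placement, update stream) comes from a
    single generator seeded by ``seed``.
    """
    rng = np.random.default_rng(seed)
    ecm = ecm_spec.build(params.dims, rng)
    state = initialize(params, ecm, rng)
    run_mcs(state, params, rng, params.mcs)
    return summarize_population(state, metric=metric, replicate_id=replicate_id)


def run_replicates(
    params: ModelParams,
    ecm_spec: EcmSpec,
    replicates: int,
    base_seed: int,
    metric: str = "euclidean",
) -> list[PopulationSummary]:
    return [
        run_single(params, ecm_spec, base_seed + r, replicate_id=r, metric=metric)
        for r in range(replicates)
    ]


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Both arms of one scenario over their scan grids."""
    switching: dict[float, list[PopulationSummary]] = {}
    for ratio in spec.ratio_grid:
        alpha, beta = ratio_to_alpha_beta(ratio)
        params = spec.params(alpha=alpha, beta=beta, switching=True)
        switching[ratio] = run_replicates(
            params, spec.ecm, spec.replicates, spec.base_seed, spec.metric
        )
    nonswitching: dict[float, list[PopulationSummary]] = {}
    for gamma in spec.gamma_grid:
        params = spec.params(switching=False, gamma=gamma)
        nonswitching[gamma] = run_replicates(
            params, spec.ecm, spec.replicates, spec.base_seed, spec.metric
        )
    return ScenarioResult(spec, switching, nonswitching)


@dataclass
class CriticalScanResult:
    levels: tuple[float, ...]
    mean_pure_a: np.ndarray  # gamma = 0
    mean_pure_m: np.ndarray  # gamma = 1
    sd_pure_a: np.ndarray
    sd_pure_m: np.ndarray
    crossover: Optional[float]  # None = no crossover in range


def critical_resistance_scan(
    levels: Sequence[float], spec: ScenarioSpec
) -> CriticalScanResult:
    """Locate the homogeneous resistance where pure-M overtakes pure-A.

    For each level, runs non-switching gamma=0 and gamma=1 arms and finds
    the first adjacent pair of levels where the sign of
    ``mean d_p(A) - mean d_p(M)`` flips; the crossover estimate is their
    midpoint.  Returns ``crossover=None`` when the ranking never flips.
    """
    levels = tuple(sorted(levels))
    if len(levels) < 2:
        raise ValueError("need at least two levels to bracket a crossover")
    means_a, means_m, sds_a, sds_m = [], [], [], []
    for level in levels:
        ecm = EcmSpec(kind="homogeneous", level=level)
        for gamma, means, sds in ((0.0, means_a, sds_a), (1.0, means_m, sds_m)):
            params = spec.params(switching=False, gamma=gamma)
            sums = run_replicates(params, ecm, spec.replicates, spec.base_seed,
                                  spec.metric)
            d_p = np.array([s.d_p for s in sums])
            means.append(d_p.mean())
            sds.append(d_p.std(ddof=1) if len(d_p) > 1 else math.nan)
    diff = np.asarray(means_a) - np.asarray(means_m)
    crossover = None
    sign = np.sign(diff)
    for i in range(len(levels) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            crossover = 0.5 * (levels[i] + levels[i + 1])
            break
    return CriticalScanResult(
        levels,
        np.asarray(means_a),
        np.asarray(means_m),
        np.asarray(sds_a),
        np.asarray(sds_m),
        crossover,
    )


@dataclass(frozen=True)
class PhaseDiagramSpec:
    theta_grid: tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(11))
    c_ratio_grid: tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(1, 11))
    scenario: ScenarioSpec = dc_field(
        default_factory=lambda: ScenarioSpec(replicates=20)
    )

    def __post_init__(self) -> None:
        if not self.theta_grid or not self.c_ratio_grid:
            raise ValueError("phase-diagram grids must be non-empty")
        if list(self.theta_grid) != sorted(self.theta_grid) or list(
            self.c_ratio_grid
        ) != sorted(self.c_ratio_grid):
            raise ValueError("phase-diagram grids must be sorted")


@dataclass
class PhaseDiagramResult:
    theta_grid: tuple[float, ...]
    c_ratio_grid: tuple[float, ...]
    delta_d_p: np.ndarray  # shape (len(theta_grid), len(c_ratio_grid))
    comparisons: dict[tuple[float, float], ComparisonResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (theta, c_ratio), comp in self.comparisons.items():
            rows.append(
                {
                    "theta": theta,
                    "c_ratio": c_ratio,
                    "delta_d_p": comp.delta_d_p,
                    "se_delta_d_p": comp.se_delta_d_p,
                    "best_switch_ratio": comp.best_switch_ratio,
                    "best_gamma": comp.best_gamma,
                }
            )
        return pd.DataFrame(rows)


def phase_diagram(spec: PhaseDiagramSpec) -> PhaseDiagramResult:
    """``delta_d_p`` over the (theta, c_M/c_A) grid."""
    delta = np.zeros((len(spec.theta_grid), len(spec.c_ratio_grid)))
    comps: dict[tuple[float, float], ComparisonResult] = {}
    for i, theta in enumerate(spec.theta_grid):
        for j, c_ratio in enumerate(spec.c_ratio_grid):
            sc = replace(
                spec.scenario,
                ecm=EcmSpec(kind="heterogeneous", theta=theta),
                c_ratio=c_ratio,
            )
            comp = run_scenario(sc).compare_best()
            delta[i, j] = comp.delta_d_p
            comps[(theta, c_ratio)] = comp
    return PhaseDiagramResult(spec.theta_grid, spec.c_ratio_grid, delta, comps)


@dataclass
class KappaSensitivityResult:
    kappas: tuple[float, ...]
    delta_d_p: np.ndarray
    comparisons: list[ComparisonResult]
    spearman_rho: float
    spearman_p: float


def kappa_sensitivity(
    spec: ScenarioSpec, kappa_grid: Sequence[float]
) -> KappaSensitivityResult:
    """``delta_d_p`` versus chemotactic responsiveness, with a trend statistic."""
    kappas = tuple(kappa_grid)
    if not kappas:
        raise ValueError("kappa grid must be non-empty")
    comps = []
    for kappa in kappas:
        comps.append(run_scenario(replace(spec, kappa=kappa)).compare_best())
    delta = np.array([c.delta_d_p for c in comps])
    if len(kappas) > 2:
        rho, p = sps.spearmanr(kappas, delta)
    else:
        rho, p = math.nan, math.nan
    return KappaSensitivityResult(kappas, delta, comps, float(rho), float(p))


@dataclass
class CooperativityResult:
    """Per-repeat ``d_max`` samples of the four arms.

    Arms: (i) switching population, (ii) best of n solitary switching
    cells, (iii) non-switching population, (iv) best of n solitary
    non-switching cells.
    """

    n: int
    repeats: int
    population_switching: np.ndarray
    single_switching: np.ndarray
    population_nonswitching: np.ndarray
    single_nonswitching: np.ndarray


def cooperativity_experiment(
    spec: ScenarioSpec,
    n: int = 500,
    repeats: int = 100,
    ratio: float = 1.0,
    gamma: float = 0.5,
) -> CooperativityResult:
    """Population versus solitary-cell maximum migration distance.

    Each repeat runs (i) one switching population of ``n`` cells at switch
    ratio ``ratio`` and records its ``d_max``; (ii) ``n`` independent
    single-cell switching runs and records the maximum of their distances;
    (iii)/(iv) likewise for the non-switching case with M-fraction
    ``gamma`` (arm (iv) uses an M solitary cell in ``round(gamma*n)`` of
    its ``n`` runs, an A cell otherwise).  ``S1`` is enlarged to ``n`` if
    needed so the seeding column can hold the population.
    """
    dims = spec.dims
    if dims.s1 < n:
        dims = LatticeDims(n, dims.s2)
    alpha, beta = ratio_to_alpha_beta(ratio)
    pop_sw = spec.params(alpha=alpha, beta=beta, switching=True, n_cells=n, dims=dims)
    pop_nsw = spec.params(switching=False, gamma=gamma, n_cells=n, dims=dims)
    # solitary arms keep the spec lattice: S1 only needs to hold the population
    single_sw = spec.params(alpha=alpha, beta=beta, switching=True, n_cells=1)

    m_singles = int(math.floor(gamma * n + 0.5))

    arm_i = np.empty(repeats)
    arm_ii = np.empty(repeats)
    arm_iii = np.empty(repeats)
    arm_iv = np.empty(repeats)
    for r in range(repeats):
        seed = spec.base_seed + r
        arm_i[r] = run_single(pop_sw, spec.ecm, seed, metric=spec.metric).d_max
        arm_iii[r] = run_single(pop_nsw, spec.ecm, seed, metric=spec.metric).d_max
        best_sw = 0.0
        best_nsw = 0.0
        for j in range(n):
            sub_seed = np.random.SeedSequence([seed, j])
            best_sw = max(
                best_sw,
                run_single(single_sw, spec.ecm, sub_seed, metric=spec.metric).d_max,
            )
            phen_frac = 1.0 if j < m_singles else 0.0
            single_nsw = spec.params(switching=False, gamma=phen_frac, n_cells=1)
            sub_seed = np.random.SeedSequence([seed, n + j])
            best_nsw = max(
                best_nsw,
                run_single(single_nsw, spec.ecm, sub_seed, metric=spec.metric).d_max,
            )
        arm_ii[r] = best_sw
        arm_iv[r] = best_nsw
    return CooperativityResult(n, repeats, arm_i, arm_ii, arm_iii, arm_iv)
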