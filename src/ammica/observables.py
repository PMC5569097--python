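"""Migration-distance observables and replicate statistics.

Invasion is quantified per cell by the displacement ``d`` from the initial
position, and per population by the mean ``d_p`` and maximum ``d_max`` of
``d`` over all cells.  Two metrics are supported: the Euclidean distance
with minimal-image convention on the periodic ``r1`` axis (default), and
the axial projection ``|r2 - r2_init|`` along the gradient.  Replicate
spread is summarised by the between-simulation standard deviation and
coefficient of variation of ``d_p``; the within-simulation spread (over
cells of one run) is reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .dynamics import SimulationState
from .environment import LatticeDims

__all__ = [
    "cell_distance",
    "cell_distances",
    "summarize_population",
    "replicate_statistics",
    "compare_best",
    "density_profile",
    "PopulationSummary",
    "ReplicateStats",
    "ComparisonResult",
]

METRICS = ("euclidean", "axial")


@dataclass(frozen=True)
class PopulationSummary:
    """Distance observables of one simulation under both metrics.

    ``d_p``/``d_max``/``within_sd`` are under the requested primary metric;
    the axial-projection counterparts are always carried along.
    """

    d_p: float
    d_max: float
    within_sd: float
    d_p_axial: float
    d_max_axial: float
    n_cells: int
    phenotype_fractions: tuple[float, float]  # (A, M)
    metric: str = "euclidean"
    replicate_id: Optional[int] = None


@dataclass(frozen=True)
class ReplicateStats:
    mean_d_p: float
    sd_between: float
    cv_between: float
    n_replicates: int


@dataclass(frozen=True)
class ComparisonResult:
    """Best-arm comparison: switching minus non-switching mean ``d_p``.

    Positive ``delta_d_p`` means plasticity wins.  ``arm_stats`` maps
    ``("switching", key)`` / ``("nonswitching", key)`` to ReplicateStats.
    """

    delta_d_p: float
    delta_d_max: float
    best_switch_ratio: float
    best_gamma: float
    se_delta_d_p: float
    arm_stats: dict


def _wrap_delta(a: np.ndarray, s1: int) -> np.ndarray:
    d = np.abs(a)
    return np.minimum(d, s1 - d)


def cell_distances(state: SimulationState, metric: str = "euclidean") -> np.ndarray:
    """Per-cell migration distance from the initial position."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    dr2 = state.r2 - state.r2_init
    if metric == "axial":
        return np.abs(dr2).astype(np.float64)
    dr1 = _wrap_delta(state.r1 - state.r1_init, state.dims.s1)
    return np.sqrt(dr1.astype(np.float64) ** 2 + dr2.astype(np.float64) ** 2)


def cell_distance(
    initial: tuple[int, int],
    final: tuple[int, int],
    dims: LatticeDims,
    metric: str = "euclidean",
) -> float:
    """Distance between two 1-based lattice positions under the metric."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    dr2 = final[1] - initial[1]
    if metric == "axial":
        return float(abs(dr2))
    dr1 = abs(final[0] - initial[0])
    dr1 = min(dr1, dims.s1 - dr1)
    return math.hypot(dr1, dr2)


def summarize_population(
    state: SimulationState,
    metric: str = "euclidean",
    replicate_id: Optional[int] = None,
) -> PopulationSummary:
    """Population distance summary of the current state."""
    if state.n_cells < 1:
        raise ValueError("cannot summarize an empty population")
    d = cell_distances(state, metric)
    d_ax = cell_distances(state, "axial")
    n_a, n_m = state.phenotype_counts()
    n = state.n_cells
    within = float(np.std(d, ddof=1)) if n > 1 else 0.0
    return PopulationSummary(
        d_p=float(d.mean()),
        d_max=float(d.max()),
        within_sd=within,
        d_p_axial=float(d_ax.mean()),
        d_max_axial=float(d_ax.max()),
        n_cells=n,
        phenotype_fractions=(n_a / n, n_m / n),
        metric=metric,
        replicate_id=replicate_id,
    )


def _dp_values(
    summaries: Sequence[Union[PopulationSummary, float]], attr: str = "d_p"
) -> np.ndarray:
    return np.asarray(
        [getattr(s, attr) if isinstance(s, PopulationSummary) else float(s)
         for s in summaries],
        dtype=np.float64,
    )


def replicate_statistics(
    summaries: Sequence[Union[PopulationSummary, float]],
) -> ReplicateStats:
    """Across-replicate mean, sd and CV of ``d_p``.

    Raises ``ValueError`` for fewer than two replicates or a zero mean
    (the CV is undefined there).
    """
    d_p = _dp_values(summaries)
    if len(d_p) < 2:
        raise ValueError("replicate statistics require at least 2 replicates")
    mean = float(d_p.mean())
    sd = float(d_p.std(ddof=1))
    if mean == 0.0:
        raise ValueError("mean d_p is zero; coefficient of variation undefined")
    return ReplicateStats(mean, sd, sd / mean, len(d_p))


def compare_best(
    switching: Mapping[float, Sequence[Union[PopulationSummary, float]]],
    nonswitching: Mapping[float, Sequence[Union[PopulationSummary, float]]],
) -> ComparisonResult:
    """Best-setting difference between the two arms.

    Each arm maps its scan parameter (switch ratio ``alpha/beta`` resp.
    M-fraction ``gamma``) to replicate summaries; the arm's representative
    is the setting with the highest replicate-mean ``d_p``.  ``delta_d_p``
    is best-switching minus best-non-switching; ``se_delta_d_p`` combines
    the two best settings' standard errors in quadrature.
    """
    if not switching or not nonswitching:
        raise ValueError("both arms must be non-empty")

    def arm_best(arm: Mapping) -> tuple[float, np.ndarray]:
        means = {k: _dp_values(v).mean() for k, v in arm.items()}
        best = max(means, key=means.get)  # ties: first-seen max
        return best, _dp_values(arm[best])

    best_ratio, sw = arm_best(switching)
    best_gamma, nsw = arm_best(nonswitching)
    delta = float(sw.mean() - nsw.mean())

    def d_max_mean(vals) -> float:
        arr = [s.d_max for s in vals if isinstance(s, PopulationSummary)]
        return float(np.mean(arr)) if arr else math.nan

    def best_by_dmax(arm: Mapping) -> float:
        means = [d_max_mean(v) for v in arm.values()]
        return max(means) if means and not any(math.isnan(m) for m in means) else math.nan

    delta_d_max = best_by_dmax(switching) - best_by_dmax(nonswitching)

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan

    stats = {}
    for label, arm in (("switching", switching), ("nonswitching", nonswitching)):
        for k, v in arm.items():
            vals = _dp_values(v)
            stats[(label, k)] = ReplicateStats(
                float(vals.mean()),
                float(vals.std(ddof=1)) if len(vals) > 1 else math.nan,
                float(vals.std(ddof=1) / vals.mean())
                if len(vals) > 1 and vals.mean() != 0
                else math.nan,
                len(vals),
            )
    return ComparisonResult(
        delta_d_p=delta,
        delta_d_max=float(delta_d_max),
        best_switch_ratio=float(best_ratio),
        best_gamma=float(best_gamma),
        se_delta_d_p=math.hypot(se(sw), se(nsw)),
        arm_stats=stats,
    )


def density_profile(state: SimulationState) -> np.ndarray:
    """Vertically averaged 1-D cell density along ``r2``.

    Entry ``j`` is the fraction of occupied sites in column ``r2 = j+1``;
    the profile sums to ``n_cells / S1``.
    """
    occupied = (state.occupancy >= 0).astype(np.float64)
    return occupied.mean(axis=0)
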