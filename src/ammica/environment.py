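"""Lattice geometry, ECM resistance fields and the chemotactic gradient.

The model lives on a rectangular lattice of ``S1 × S2`` sites.  Coordinates
are 1-based: ``r1`` runs vertically (``1..S1``, periodic axis) and ``r2``
horizontally (``1..S2``, the gradient axis).  Every site carries an ECM
resistance value ``mu`` in ``[0, 1]`` — a lumped scalar standing in for
matrix density, stiffness and porosity as a barrier to cell movement —
and sits in a static linear chemoattractant field ``G(r1, r2) = r2 / S2``
pulling cells toward the right edge.

Two ECM generators are provided.  The homogeneous generator fills the
lattice with a constant resistance.  The heterogeneous generator produces

    mu(r1, r2) = 1 - theta/2
                 + (theta/2) * sin(2*pi*r1/25 + 3*pi/2) * sin(pi*r2/25 + pi/2)
                 - (1 - theta) * xi(r1, r2)

where ``xi`` is i.i.d. uniform(0, 1) per site, frozen for the run, and the
heterogeneity parameter ``theta`` interpolates from pure site-wise noise
(``theta = 0``) to a fully coherent sinusoidal structure (``theta = 1``).
The field is analytically confined to ``[0, 1]`` (extremes at sinusoid
``±1`` with ``xi`` at 0 or 1), so no clipping is applied — an assertion
guards the bound instead.  Its spatial mean is 0.5 for every ``theta``
whenever the lattice spans whole sinusoid periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "LatticeDims",
    "ECMField",
    "make_homogeneous_ecm",
    "make_heterogeneous_ecm",
    "gradient_value",
    "gradient_field",
]

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence]


@dataclass(frozen=True)
class LatticeDims:
    """Rectangular lattice extents.

    ``s1`` is the vertical (periodic) extent, ``s2`` the horizontal extent
    along the chemotactic gradient.
    """

    s1: int
    s2: int

    def __post_init__(self) -> None:
        if self.s1 < 1:
            raise ValueError(f"s1 must be >= 1, got {self.s1}")
        if self.s2 < 2:
            raise ValueError(f"s2 must be >= 2, got {self.s2}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.s1, self.s2)

    @property
    def n_sites(self) -> int:
        return self.s1 * self.s2


@dataclass
class ECMField:
    """A resistance field on the lattice.

    ``values[i, j]`` is the resistance at site ``(r1=i+1, r2=j+1)``.  The
    ``descriptor`` records generator name, parameters and seed so the field
    can be regenerated bit-identically.
    """

    values: np.ndarray
    dims: LatticeDims
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.dims.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match dims {self.dims.shape}"
            )
        if not (np.all(self.values >= 0.0) and np.all(self.values <= 1.0)):
            raise ValueError("ECM resistance values must lie in [0, 1]")

    def at(self, r1: int, r2: int) -> float:
        """Resistance at 1-based lattice coordinates."""
        _check_coords(r1, r2, self.dims)
        return float(self.values[r1 - 1, r2 - 1])

    def copy(self) -> "ECMField":
        return ECMField(self.values.copy(), self.dims, dict(self.descriptor))


def _check_coords(r1: int, r2: int, dims: LatticeDims) -> None:
    if not (1 <= r1 <= dims.s1 and 1 <= r2 <= dims.s2):
        raise IndexError(
            f"coordinates ({r1}, {r2}) outside lattice 1..{dims.s1} × 1..{dims.s2}"
        )


def make_homogeneous_ecm(dims: LatticeDims, level: float) -> ECMField:
    """Constant-resistance field ``mu(r1, r2) = level``."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level must be in [0, 1], got {level}")
    values = np.full(dims.shape, float(level))
    return ECMField(values, dims, {"generator": "homogeneous", "level": float(level)})


def make_heterogeneous_ecm(
    dims: LatticeDims,
    theta: float,
    seed: SeedLike,
    *,
    period_r1: float = 25.0,
    period_r2: float = 50.0,
) -> ECMField:
    """Sinusoid-plus-noise resistance field.

    ``theta`` in ``[0, 1]`` sets the coherent-structure fraction; the noise
    term ``(1 - theta) * xi`` uses per-site i.i.d. uniform(0, 1) draws from
    the seeded stream.  ``period_r1``/``period_r2`` are the sinusoid spatial
    periods in lattice units; the defaults reproduce the standard field and
    are exposed only for robustness checks with other functional forms.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_repr = seed if isinstance(seed, int) else None

    r1 = np.arange(1, dims.s1 + 1, dtype=np.float64)[:, None]
    r2 = np.arange(1, dims.s2 + 1, dtype=np.float64)[None, :]
    structure = np.sin(2.0 * np.pi * r1 / period_r1 + 1.5 * np.pi) * np.sin(
        2.0 * np.pi * r2 / period_r2 + 0.5 * np.pi
    )
    xi = rng.random(dims.shape)
    values = 1.0 - theta / 2.0 + (theta / 2.0) * structure - (1.0 - theta) * xi
    # provable bound; a violation would indicate a generator bug, not data
    assert np.all(values >= 0.0) and np.all(values <= 1.0)
    return ECMField(
        values,
        dims,
        {
            "generator": "heterogeneous",
            "theta": float(theta),
            "seed": seed_repr,
            "period_r1": period_r1,
            "period_r2": period_r2,
        },
    )


def gradient_value(r1: int, r2: int, dims: LatticeDims) -> float:
    """Chemoattractant concentration ``G(r1, r2) = r2 / S2``.

    Constant along ``r1``, strictly increasing toward the target column
    ``r2 = S2`` where it reaches 1.
    """
    _check_coords(r1, r2, dims)
    return r2 / dims.s2

def gradient_field(dims: LatticeDims) -> np.ndarray:
    """The full gradient field as an ``(S1, S2)`` array."""
    col = np.arange(1, dims.s2 + 1, dtype=np.float64) / dims.s2
    return np.broadcast_to(col, dims.shape).copy()
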