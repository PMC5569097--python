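import numpy as np
import pytest

from ammica import (
    ECMField,
    LatticeDims,
    ModelParams,
    SimulationState,
    make_homogeneous_ecm,
)


@pytest.fixture
def small_dims() -> LatticeDims:
    return LatticeDims(10, 12)


def build_state(
    dims: LatticeDims,
    positions: list[tuple[int, int]],
    phenotypes: list[int],
    initial_positions: list[tuple[int, int]] | None = None,
    mu: float = 0.5,
) -> SimulationState:
    """Hand-build a consistent state from 1-based positions."""
    n = len(positions)
    if initial_positions is None:
        initial_positions = positions
    r1 = np.array([p[0] - 1 for p in positions], dtype=np.int64)
    r2 = np.array([p[1] - 1 for p in positions], dtype=np.int64)
    occ = np.full(dims.shape, -1, dtype=np.int64)
    occ[r1, r2] = np.arange(n)
    return SimulationState(
        ecm=make_homogeneous_ecm(dims, mu),
        occupancy=occ,
        r1=r1,
        r2=r2,
        r1_init=np.array([p[0] - 1 for p in initial_positions], dtype=np.int64),
        r2_init=np.array([p[1] - 1 for p in initial_positions], dtype=np.int64),
        phenotype_code=np.array(phenotypes, dtype=np.int8),
    )


class ScriptedRNG:
    """Stub generator feeding predetermined uniforms to step_cell."""

    def __init__(self, triples):
        self._triples = list(triples)

    def random(self, n=None):
        u = self._triples.pop(0)
        return np.asarray(u) if n is not None else float(u)
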