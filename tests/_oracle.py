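"""Independent brute-force oracle: exact Markov chain for one cell.

For a single cell on a homogeneous, non-degrading lattice the automaton is
a finite Markov chain over (r1, r2, phenotype).  This enumerates the exact
one-update transition matrix directly from the printed rule definitions
(kinetic switch, sigmoid migration rate, exponential chemotactic bias,
periodic r1 / reflecting r2 boundaries) without going through the
simulation kernel, so distribution comparisons are a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np

from ammica import LatticeDims, ModelParams


def state_index(r1: int, r2: int, ph: int, dims: LatticeDims) -> int:
    """0-based (row, col, phenotype) to flat chain-state index."""
    return (r1 * dims.s2 + r2) * 2 + ph


def single_cell_transition_matrix(
    dims: LatticeDims, mu: float, params: ModelParams
) -> np.ndarray:
    """Exact transition matrix of one single-cell update attempt.

    Requires delta to be irrelevant (pure-A or delta=0), so the ECM stays
    at the constant ``mu``.
    """
    if params.delta != 0.0 and (params.switching or params.gamma > 0.0):
        raise ValueError("oracle requires a non-degrading setting (delta=0 or pure A)")
    s1, s2 = dims.s1, dims.s2
    n = s1 * s2 * 2
    T = np.zeros((n, n))
    w = (math.exp(-params.kappa), math.exp(params.kappa), 1.0, 1.0)
    z = sum(w)
    dir_probs = [x / z for x in w]
    for r1 in range(s1):
        for r2 in range(s2):
            for ph in range(2):
                i = state_index(r1, r2, ph, dims)
                if params.switching:
                    ps = params.alpha * mu if ph == 0 else params.beta * (1.0 - mu)
                    branches = [(ph, 1.0 - ps), (1 - ph, ps)]
                else:
                    branches = [(ph, 1.0)]
                for ph2, wb in branches:
                    if wb == 0.0:
                        continue
                    c = params.c_a if ph2 == 0 else params.c_m
                    pm = c / (1.0 + math.exp(15.0 * (mu - 0.5)))
                    T[i, state_index(r1, r2, ph2, dims)] += wb * (1.0 - pm)
                    for d, pd in enumerate(dir_probs):
                        nr1, nr2 = r1, r2
                        if d == 0:  # left
                            nr2 = r2 - 1 if r2 > 0 else None
                        elif d == 1:  # right
                            nr2 = r2 + 1 if r2 < s2 - 1 else None
                        elif d == 2:  # up, periodic
                            nr1 = (r1 - 1) % s1
                        else:  # down, periodic
                            nr1 = (r1 + 1) % s1
                        blocked = nr2 is None or (nr1 == r1 and nr2 == r2)
                        if blocked:  # off-lattice or self-target (S1 == 1)
                            T[i, state_index(r1, r2, ph2, dims)] += wb * pm * pd
                        else:
                            T[i, state_index(nr1, nr2, ph2, dims)] += wb * pm * pd
    return T


def distribution_after(
    T: np.ndarray, initial: np.ndarray, attempts: int
) -> np.ndarray:
    return initial @ np.linalg.matrix_power(T, attempts)
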