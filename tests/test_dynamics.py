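import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ammica import (
    LatticeDims,
    ModelParams,
    Phenotype,
    chemotactic_move_distribution,
    degrade_ecm,
    initialize,
    make_heterogeneous_ecm,
    make_homogeneous_ecm,
    migration_rate,
    run_mcs,
    step_cell,
    switch_rate,
)
from conftest import ScriptedRNG, build_state


class TestRateFunctions:
    def test_switch_rate_is_alpha_mu_for_amoeboid(self):
        p = ModelParams(alpha=0.7, beta=0.6, switching=True)
        assert switch_rate(Phenotype.A, 0.5, p) == pytest.approx(0.35)
        assert switch_rate(Phenotype.A, 0.0, p) == 0.0

    def test_mesenchymal_never_reverts_in_dense_matrix(self):
        p = ModelParams(alpha=0.7, beta=0.6, switching=True)
        assert switch_rate(Phenotype.M, 1.0, p) == 0.0
        assert switch_rate(Phenotype.M, 0.5, p) == pytest.approx(0.3)

    def test_migration_rate_sigmoid(self):
        p = ModelParams(c_a=1.0, c_m=0.25)
        assert migration_rate(Phenotype.A, 0.5, p) == pytest.approx(0.5)
        assert migration_rate(Phenotype.M, 0.5, p) == pytest.approx(0.125)
        # open matrix: rate approaches the migration constant
        assert migration_rate(Phenotype.A, 0.0, p) == pytest.approx(
            1.0 / (1.0 + math.exp(-7.5))
        )

    @pytest.mark.parametrize("fn", [switch_rate, migration_rate])
    def test_rates_reject_mu_outside_unit_interval(self, fn):
        p = ModelParams(alpha=0.5, beta=0.5)
        with pytest.raises(ValueError):
            fn(Phenotype.A, 1.2, p)

    def test_degradation_partial_and_monotone(self):
        assert degrade_ecm(0.5, 0.1) == pytest.approx(0.45)
        assert degrade_ecm(0.0, 0.7) == 0.0
        assert degrade_ecm(0.8, 0.0) == 0.8
        assert degrade_ecm(0.05, 0.1, mode="subtractive") == 0.0


class TestMoveDistribution:
    def test_unresponsive_cells_walk_uniformly(self):
        d = chemotactic_move_distribution((3, 3), 0.0, LatticeDims(10, 10))
        assert d == pytest.approx(
            {"left": 0.25, "right": 0.25, "up": 0.25, "down": 0.25}
        )

    def test_kappa_one_weights(self):
        # weights (e^-1, e, 1, 1) normalised
        z = math.exp(-1) + math.exp(1) + 2.0
        d = chemotactic_move_distribution((1, 1), 1.0, LatticeDims(5, 5))
        assert d["left"] == pytest.approx(math.exp(-1) / z)
        assert d["right"] == pytest.approx(math.exp(1) / z)
        assert d["up"] == pytest.approx(1.0 / z) == d["down"]
        assert sum(d.values()) == pytest.approx(1.0)

    def test_strong_bias_is_almost_deterministic(self):
        d = chemotactic_move_distribution((1, 1), 50.0, LatticeDims(5, 5))
        assert d["right"] > 0.999999

    def test_invalid_inputs(self):
        with pytest.raises(IndexError):
            chemotactic_move_distribution((0, 1), 0.5, LatticeDims(5, 5))
        with pytest.raises(ValueError):
            chemotactic_move_distribution((1, 1), -0.5, LatticeDims(5, 5))


class TestModelParams:
    def test_rate_ranges_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(alpha=1.5)
        with pytest.raises(ValueError):
            ModelParams(kappa=-1.0)

    def test_amoeboid_mode_is_the_faster_one(self):
        with pytest.raises(ValueError):
            ModelParams(c_a=0.5, c_m=0.8)

    def test_non_switching_forces_zero_switch_rates(self):
        p = ModelParams(alpha=0.7, beta=0.6, switching=False, gamma=0.3)
        assert p.alpha == 0.0 and p.beta == 0.0


class TestInitialize:
    def test_even_split_for_switching_population(self):
        dims = LatticeDims(60, 50)
        p = ModelParams(alpha=1.0, beta=1.0, switching=True, n_cells=50, dims=dims)
        st_ = initialize(p, rng=np.random.default_rng(0))
        n_a, n_m = st_.phenotype_counts()
        assert (n_a, n_m) == (25, 25)
        assert np.all(st_.r2 == 0)  # left border, r2 = 1
        assert len(set(st_.r1.tolist())) == 50  # distinct rows

    @pytest.mark.parametrize(
        "gamma,expected_m", [(0.0, 0), (0.3, 15), (0.7, 35), (1.0, 50)]
    )
    def test_gamma_composition_for_non_switching(self, gamma, expected_m):
        dims = LatticeDims(60, 50)
        p = ModelParams(switching=False, gamma=gamma, n_cells=50, dims=dims)
        st_ = initialize(p, rng=np.random.default_rng(1))
        assert st_.phenotype_counts()[1] == expected_m

    def test_population_must_fit_in_seeding_column(self):
        p = ModelParams(switching=False, n_cells=20, dims=LatticeDims(10, 30))
        with pytest.raises(ValueError):
            initialize(p, rng=np.random.default_rng(0))

    def test_state_starts_consistent(self):
        p = ModelParams(alpha=0.5, beta=0.5, n_cells=30, dims=LatticeDims(40, 20))
        st_ = initialize(p, rng=np.random.default_rng(2))
        st_.check_consistency()


class TestStepCell:
    """Forced-draw tests of the rule composition and boundary handling.

    ScriptedRNG supplies (u_switch, u_migration, u_direction); with kappa=0
    the direction thresholds are 0.25/0.5/0.75 for left/right/up/down.
    """

    def test_fully_enclosed_cell_never_moves(self):
        dims = LatticeDims(5, 5)
        pos = [(2, 3), (1, 3), (3, 3), (2, 2), (2, 4)]
        state = build_state(dims, pos, [1, 0, 0, 0, 0], mu=0.0)
        p = ModelParams(switching=False, gamma=0.2, n_cells=5, dims=dims, kappa=0.0)
        for u_dir in (0.1, 0.3, 0.6, 0.9):
            step_cell(state, 0, p, ScriptedRNG([(0.9, 0.0, u_dir)]))
            assert state.cell(0).position == (2, 3)
        state.check_consistency()

    def test_periodic_wrap_along_r1(self):
        dims = LatticeDims(4, 5)
        state = build_state(dims, [(1, 3)], [0], mu=0.0)
        p = ModelParams(switching=False, n_cells=1, dims=dims, kappa=0.0)
        step_cell(state, 0, p, ScriptedRNG([(0.9, 0.0, 0.6)]))  # up from r1=1
        assert state.cell(0).position == (4, 3)
        step_cell(state, 0, p, ScriptedRNG([(0.9, 0.0, 0.9)]))  # down from r1=4
        assert state.cell(0).position == (1, 3)

    def test_reflecting_boundaries_abort_moves(self):
        dims = LatticeDims(4, 5)
        state = build_state(dims, [(2, 1)], [0], mu=0.0)
        p = ModelParams(switching=False, n_cells=1, dims=dims, kappa=0.0)
        step_cell(state, 0, p, ScriptedRNG([(0.9, 0.0, 0.1)]))  # left at r2=1
        assert state.cell(0).position == (2, 1)
        state = build_state(dims, [(2, 5)], [0], mu=0.0)
        step_cell(state, 0, p, ScriptedRNG([(0.9, 0.0, 0.3)]))  # right at r2=5
        assert state.cell(0).position == (2, 5)

    def test_rules_apply_in_order_switch_then_degrade_then_move(self):
        # A-cell in resistant matrix: forced switch to M, degradation at the
        # origin site, then a forced right move.
        dims = LatticeDims(3, 4)
        state = build_state(dims, [(2, 2)], [0], mu=0.8)
        p = ModelParams(
            alpha=1.0, beta=1.0, switching=True, c_m=1.0, delta=0.5,
            n_cells=1, dims=dims, kappa=0.0,
        )
        step_cell(state, 0, p, ScriptedRNG([(0.0, 0.0, 0.3)]))
        cell = state.cell(0)
        assert cell.phenotype is Phenotype.M
        assert state.ecm.at(2, 2) == pytest.approx(0.4)  # degraded before moving
        assert cell.position == (2, 3)

    def test_invalid_cell_id(self):
        dims = LatticeDims(3, 4)
        state = build_state(dims, [(1, 1)], [0])
        p = ModelParams(switching=False, n_cells=1, dims=dims)
        with pytest.raises(IndexError):
            step_cell(state, 5, p, np.random.default_rng(0))


class TestRunMcs:
    def test_zero_mcs_is_identity(self):
        dims = LatticeDims(20, 30)
        p = ModelParams(alpha=0.5, beta=0.5, n_cells=10, dims=dims)
        rng = np.random.default_rng(3)
        state = initialize(p, rng=rng)
        before = (state.r1.copy(), state.r2.copy(), state.ecm.values.copy())
        run_mcs(state, p, rng, 0)
        assert np.array_equal(state.r1, before[0])
        assert np.array_equal(state.r2, before[1])
        assert np.array_equal(state.ecm.values, before[2])
        assert state.mcs_elapsed == 0

    def test_attempt_accounting(self):
        dims = LatticeDims(60, 40)
        p = ModelParams(alpha=0.5, beta=0.5, n_cells=50, dims=dims)
        rng = np.random.default_rng(4)
        state = initialize(p, rng=rng)
        run_mcs(state, p, rng, 200)
        assert state.time == 10_000
        assert state.mcs_elapsed == 200

    def test_exclusion_and_conservation_throughout(self):
        dims = LatticeDims(12, 15)
        p = ModelParams(alpha=1.0, beta=1.0, n_cells=10, dims=dims, c_m=0.8)
        rng = np.random.default_rng(5)
        state = initialize(p, rng=rng)
        for _ in range(20):
            run_mcs(state, p, rng, 5)
            state.check_consistency()
            assert state.n_cells == 10

    def test_ecm_never_increases_and_only_m_cells_degrade(self):
        dims = LatticeDims(15, 20)
        ecm = make_heterogeneous_ecm(dims, 0.5, seed=8)
        # mixed switching population degrades
        p = ModelParams(alpha=1.0, beta=1.0, n_cells=8, dims=dims, c_m=0.5)
        rng = np.random.default_rng(6)
        state = initialize(p, ecm, rng)
        initial = state.ecm.values.copy()
        run_mcs(state, p, rng, 50)
        assert np.all(state.ecm.values <= initial + 1e-15)
        # pure-A population leaves the matrix untouched
        p_a = ModelParams(switching=False, gamma=0.0, n_cells=8, dims=dims)
        rng = np.random.default_rng(7)
        state = initialize(p_a, ecm, rng)
        run_mcs(state, p_a, rng, 50)
        assert np.array_equal(state.ecm.values, ecm.values)

    def test_non_switching_population_keeps_phenotypes(self):
        dims = LatticeDims(15, 20)
        p = ModelParams(switching=False, gamma=0.5, n_cells=10, dims=dims)
        rng = np.random.default_rng(9)
        state = initialize(p, rng=rng)
        phen0 = state.phenotype_code.copy()
        run_mcs(state, p, rng, 100)
        assert np.array_equal(state.phenotype_code, phen0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_cells=st.integers(1, 12),
        kappa=st.floats(0.0, 1.0),
        theta=st.floats(0.0, 1.0),
    )
    def test_invariants_hold_for_random_settings(self, seed, n_cells, kappa, theta):
        dims = LatticeDims(12, 10)
        p = ModelParams(
            alpha=0.8, beta=0.4, n_cells=n_cells, dims=dims, kappa=kappa, c_m=0.6
        )
        rng = np.random.default_rng(seed)
        ecm = make_heterogeneous_ecm(dims, theta, rng)
        state = initialize(p, ecm, rng)
        run_mcs(state, p, rng, 10)
        state.check_consistency()
        assert np.all(state.ecm.values >= 0.0)
        assert np.all(state.ecm.values <= ecm.values + 1e-15)

    def test_equilibrium_switch_variant_depends_on_ratio_only(self):
        # same stream, scaled (alpha, beta) at fixed ratio: identical paths
        dims = LatticeDims(30, 40)
        ecm = make_homogeneous_ecm(dims, 0.5)
        results = []
        for alpha, beta in ((0.2, 0.2), (1.0, 1.0)):
            p = ModelParams(
                alpha=alpha, beta=beta, switching=True, n_cells=10, dims=dims,
                c_m=0.25, switch_update="equilibrium",
            )
            rng = np.random.default_rng(42)
            state = initialize(p, ecm, rng)
            run_mcs(state, p, rng, 30)
            results.append((state.r1.copy(), state.r2.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])
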