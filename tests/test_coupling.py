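"""Coupled-pair assembly, the synchronization condition, w+/w- and cores."""

import numpy as np
import pytest

from syncore import (
    CoupledPair,
    SyncConditionError,
    assemble,
    check_sync_condition,
    classify_coupling,
    disassemble,
    from_xi_eta,
    identical_module_split,
    iterate,
    obstruction_map,
    obstruction_matrix,
    random_sync_pair,
    step,
    sync_core_structure,
    sync_equivalent,
    sync_matrix,
    sync_residual,
    synchronized_module,
    to_xi_eta,
    xi_eta_step,
)
from syncore.coupling import XiEtaState, coupled_step

W_CYCLE = [[0.0, 1.6], [-1.6, 0.0]]
W_COUP = [[-4.0, 0.0], [0.0, 0.0]]
W_PLUS = [[-4.0, 1.6], [-1.6, 0.0]]
W_MINUS_STRONG = [[4.0, 1.6], [-1.6, 0.0]]
W_MOD_CONS = [[-2.675, 1.1], [-1.1, 0.0]]
W_COUP_CONS = [[-1.325, 0.5], [-0.5, 0.0]]


def make_pair(w, w_coup, theta=(-4.0, 0.0)):
    t = np.asarray(theta, dtype=float)
    return CoupledPair(thetaA=t, thetaB=t.copy(), wA=w, wB=w, wAB=w_coup, wBA=w_coup)


class TestAssemble:
    def test_block_layout(self, pair_generative):
        mod = assemble(pair_generative)
        expected = [
            [0.0, 1.6, -4.0, 0.0],
            [-1.6, 0.0, 0.0, 0.0],
            [-4.0, 0.0, 0.0, 1.6],
            [0.0, 0.0, -1.6, 0.0],
        ]
        assert np.array_equal(mod.weights, expected)
        assert np.array_equal(mod.theta, [-4.0, 0.0, -4.0, 0.0])

    def test_zero_coupling_is_block_diagonal(self):
        p = make_pair(W_CYCLE, np.zeros((2, 2)))
        w = assemble(p).weights
        assert np.array_equal(w[:2, 2:], np.zeros((2, 2)))
        assert np.array_equal(w[2:, :2], np.zeros((2, 2)))

    def test_disassemble_round_trip(self, pair_conservative):
        back = disassemble(assemble(pair_conservative))
        for attr in ("thetaA", "thetaB", "wA", "wB", "wAB", "wBA"):
            assert np.array_equal(getattr(back, attr), getattr(pair_conservative, attr))

    def test_assembled_step_equals_coupled_equations(self, pair_generative, rng):
        a = rng.normal(size=2)
        b = rng.normal(size=2)
        p = pair_generative
        a_next = p.thetaA + p.wA @ np.tanh(a) + p.wAB @ np.tanh(b)
        b_next = p.thetaB + p.wB @ np.tanh(b) + p.wBA @ np.tanh(a)
        got_a, got_b = coupled_step(p, a, b)
        assert got_a == pytest.approx(a_next, abs=1e-12)
        assert got_b == pytest.approx(b_next, abs=1e-12)


class TestSyncCondition:
    def test_identical_modules_symmetric_coupling(self, pair_generative):
        assert check_sync_condition(pair_generative)
        assert sync_residual(pair_generative) == 0.0

    def test_non_recurrent_coupling_fails(self):
        t = np.zeros(1)
        p = CoupledPair(
            thetaA=t, thetaB=t, wA=[[1.0]], wB=[[1.0]], wAB=[[1.0]], wBA=[[0.0]]
        )
        assert not check_sync_condition(p)

    def test_weight_mismatch_fails_at_tight_tol(self):
        t = np.zeros(1)
        p = CoupledPair(
            thetaA=t, thetaB=t, wA=[[1.0]], wB=[[1.1]], wAB=[[0.5]], wBA=[[0.5]]
        )
        assert not check_sync_condition(p, tol=1e-9)
        assert sync_residual(p) == pytest.approx(0.1)

    def test_violation_error_names_entry(self):
        t = np.zeros(1)
        p = CoupledPair(
            thetaA=t, thetaB=t, wA=[[1.0]], wB=[[1.1]], wAB=[[0.5]], wBA=[[0.5]]
        )
        with pytest.raises(SyncConditionError, match=r"\(0, 0\)"):
            sync_matrix(p)

    def test_unequal_dimensions_rejected_at_construction(self):
        with pytest.raises(ValueError):
            CoupledPair(
                thetaA=np.zeros(2),
                thetaB=np.zeros(3),
                wA=np.zeros((2, 2)),
                wB=np.zeros((3, 3)),
                wAB=np.zeros((2, 2)),
                wBA=np.zeros((2, 2)),
            )


class TestSyncAndObstructionMatrices:
    def test_generative_pair_values(self, pair_generative):
        core = sync_matrix(pair_generative)
        assert np.array_equal(core.w_plus, W_PLUS)
        assert np.array_equal(core.theta, [-4.0, 0.0])
        assert np.array_equal(obstruction_matrix(pair_generative), W_MINUS_STRONG)

    def test_conservative_pair_shares_the_core(self, pair_conservative):
        core = sync_matrix(pair_conservative)
        assert core.w_plus == pytest.approx(np.asarray(W_PLUS), abs=1e-12)
        assert obstruction_matrix(pair_conservative) == pytest.approx(
            np.array([[-1.35, 0.6], [-0.6, 0.0]]), abs=1e-12
        )

    def test_zero_coupling_rejected(self):
        p = make_pair(W_CYCLE, np.zeros((2, 2)))
        with pytest.raises(SyncConditionError, match="recurrent"):
            sync_matrix(p)

    def test_equal_module_and_coupling_gives_zero_obstruction(self):
        w = np.array(W_CYCLE)
        p = CoupledPair(
            thetaA=np.zeros(2), thetaB=np.zeros(2), wA=w, wB=w, wAB=w, wBA=w
        )
        assert np.array_equal(obstruction_matrix(p), np.zeros((2, 2)))


class TestIdenticalModuleSplit:
    def test_recovers_conservative_configuration(self):
        w, w_coup = identical_module_split(W_PLUS, [[-1.35, 0.6], [-0.6, 0.0]])
        assert w == pytest.approx(np.asarray(W_MOD_CONS), abs=1e-12)
        assert w_coup == pytest.approx(np.asarray(W_COUP_CONS), abs=1e-12)

    def test_recovers_generative_configuration(self):
        w, w_coup = identical_module_split(W_PLUS, W_MINUS_STRONG)
        assert np.array_equal(w, W_CYCLE)
        assert np.array_equal(w_coup, W_COUP)

    def test_degenerate_equal_matrices_give_zero_coupling(self):
        w, w_coup = identical_module_split(W_PLUS, W_PLUS)
        assert np.array_equal(w, W_PLUS)
        assert np.array_equal(w_coup, np.zeros((2, 2)))
        assert not make_pair(w, w_coup).is_recurrent()

    def test_round_trip_random_matrices(self, rng):
        p = rng.normal(size=(3, 3))
        m = rng.normal(size=(3, 3))
        w, w_coup = identical_module_split(p, m)
        pair = CoupledPair(
            thetaA=np.zeros(3), thetaB=np.zeros(3),
            wA=w, wB=w, wAB=w_coup, wBA=w_coup,
        )
        assert sync_matrix(pair, tol=1e-12).w_plus == pytest.approx(p, abs=1e-12)
        assert obstruction_matrix(pair, tol=1e-12) == pytest.approx(m, abs=1e-12)


class TestXiEtaCoordinates:
    def test_synchronized_state_has_zero_eta(self):
        s = to_xi_eta([1.0, 2.0], [1.0, 2.0])
        assert np.array_equal(s.xi, [1.0, 2.0])
        assert np.array_equal(s.eta, [0.0, 0.0])

    def test_antisymmetric_state_sits_on_obstruction_manifold(self):
        s = to_xi_eta([1.0, 0.0], [-1.0, 0.0])
        assert np.array_equal(s.xi, [0.0, 0.0])
        assert np.array_equal(s.eta, [1.0, 0.0])

    def test_round_trip_is_identity(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        a2, b2 = from_xi_eta(to_xi_eta(a, b))
        assert a2 == pytest.approx(a, abs=1e-15)
        assert b2 == pytest.approx(b, abs=1e-15)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            to_xi_eta([1.0], [1.0, 2.0])


class TestXiEtaDynamics:
    def test_matches_direct_route_on_reference_pair(self, pair_generative, rng):
        a, b = rng.normal(size=2), rng.normal(size=2)
        s_next = xi_eta_step(pair_generative, to_xi_eta(a, b))
        a_next, b_next = coupled_step(pair_generative, a, b)
        expected = to_xi_eta(a_next, b_next)
        assert s_next.xi == pytest.approx(expected.xi, abs=1e-10)
        assert s_next.eta == pytest.approx(expected.eta, abs=1e-10)

    def test_matches_direct_route_even_without_sync_condition(self, rng):
        # the transformed equations are the full dynamics, not a reduction
        p = CoupledPair(
            thetaA=rng.normal(size=3),
            thetaB=rng.normal(size=3),
            wA=rng.normal(size=(3, 3)),
            wB=rng.normal(size=(3, 3)),
            wAB=rng.normal(size=(3, 3)),
            wBA=rng.normal(size=(3, 3)),
        )
        for _ in range(5):
            a, b = rng.normal(size=3), rng.normal(size=3)
            s_next = xi_eta_step(p, to_xi_eta(a, b))
            a2, b2 = coupled_step(p, a, b)
            want = to_xi_eta(a2, b2)
            assert s_next.xi == pytest.approx(want.xi, abs=1e-10)
            assert s_next.eta == pytest.approx(want.eta, abs=1e-10)

    def test_manifold_is_exactly_invariant_in_adapted_coordinates(self):
        # with the condition holding exactly in floats, eta' == 0 bitwise:
        # both half-updates are the same computation on the same arrays
        for seed in range(20):
            p = random_sync_pair(4, seed=seed)
            s = XiEtaState(xi=np.tanh(np.arange(4) * 0.3), eta=np.zeros(4))
            for _ in range(50):
                s = xi_eta_step(p, s)
                assert np.all(s.eta == 0.0)

    def test_obstruction_manifold_dynamics_uses_w_minus(self, pair_generative):
        # at xi = 0 with zero bias and the symmetric configuration,
        # eta' = w- @ tanh(eta)
        p = make_pair(W_CYCLE, W_COUP, theta=(0.0, 0.0))
        eta = np.array([0.3, -0.7])
        s_next = xi_eta_step(p, XiEtaState(xi=np.zeros(2), eta=eta))
        assert s_next.eta == pytest.approx(
            np.array(W_MINUS_STRONG) @ np.tanh(eta), abs=1e-12
        )


class TestSynchronizedModule:
    def test_is_the_w_plus_module(self, pair_generative):
        mod = synchronized_module(pair_generative)
        assert np.array_equal(mod.weights, W_PLUS)
        assert np.array_equal(mod.theta, [-4.0, 0.0])

    def test_trajectory_equals_coupled_diagonal_orbit(self, pair_generative):
        xi0 = np.array([0.4, -0.3])
        full = iterate(
            assemble(pair_generative), np.concatenate([xi0, xi0]), 0, 1_000
        ).states
        reduced = iterate(synchronized_module(pair_generative), xi0, 0, 1_000).states
        xi_from_full = (full[:, :2] + full[:, 2:]) / 2.0
        assert np.abs(xi_from_full - reduced).max() < 1e-9

    def test_conservative_pair_gives_same_module(self, pair_generative, pair_conservative):
        m1 = synchronized_module(pair_generative)
        m2 = synchronized_module(pair_conservative)
        assert m2.weights == pytest.approx(m1.weights, abs=1e-12)


class TestObstructionMap:
    def test_origin_is_fixed(self, pair_generative):
        assert np.array_equal(obstruction_map(pair_generative, np.zeros(2)), np.zeros(2))

    def test_matches_scalar_evaluation(self, pair_conservative):
        got = obstruction_map(pair_conservative, [0.1, 0.1])
        w_minus = np.array([[-1.35, 0.6], [-0.6, 0.0]])
        assert got == pytest.approx(w_minus @ np.tanh([0.1, 0.1]), abs=1e-12)

    def test_contraction_regime_converges_to_origin(self, rng):
        # all |w-| < 1/n: the origin attracts globally
        p = random_sync_pair(3, seed=11, stable_manifold=True)
        eta = rng.normal(size=3) * 2
        for _ in range(10_000):
            eta = obstruction_map(p, eta)
        assert np.abs(eta).max() < 1e-6


class TestCouplingClassification:
    def test_strong_coupling_is_generative_with_witness(self, pair_generative):
        cls = classify_coupling(pair_generative)
        assert cls.is_generative
        assert cls.witnesses == ((0, 0),)

    def test_rewired_configuration_is_conservative(self, pair_conservative):
        assert classify_coupling(pair_conservative).label == "conservative"

    def test_coupling_on_module_support_is_conservative(self):
        w = np.array(W_CYCLE)
        coup = np.array([[0.0, 0.4], [-0.4, 0.0]])  # only where w is nonzero
        p = make_pair(w, coup)
        assert classify_coupling(p).label == "conservative"

    def test_invariant_under_positive_rescaling(self, pair_generative):
        p = pair_generative
        for c in (0.5, 2.0, 10.0):
            scaled = CoupledPair(
                thetaA=p.thetaA, thetaB=p.thetaB,
                wA=c * p.wA, wB=c * p.wB, wAB=c * p.wAB, wBA=c * p.wBA,
            )
            assert classify_coupling(scaled).label == "generative"

    def test_sign_pattern_of_core(self, pair_generative, pair_conservative):
        assert sync_core_structure(pair_generative) == [[-1, 1], [-1, 0]]
        assert sync_core_structure(pair_conservative) == [[-1, 1], [-1, 0]]


class TestSyncEquivalence:
    def test_generative_and_conservative_examples_are_equivalent(
        self, pair_generative, pair_conservative
    ):
        assert sync_equivalent(pair_generative, pair_conservative)

    def test_reflexive(self, pair_generative):
        assert sync_equivalent(pair_generative, pair_generative)

    def test_detects_differing_core_sign(self, pair_generative):
        w = np.array([[4.0, 1.6], [-1.6, 0.0]])  # flipped self-connection sign
        other = make_pair(*identical_module_split(w, [[-1.35, 0.6], [-0.6, 0.0]]))
        assert not sync_equivalent(pair_generative, other)

    def test_permutation_mode(self, pair_generative):
        # relabel the two neurons of the core
        w_perm = np.array(W_PLUS)[np.ix_([1, 0], [1, 0])]
        other = make_pair(*identical_module_split(w_perm, w_perm * 0.5))
        assert not sync_equivalent(pair_generative, other)
        assert sync_equivalent(pair_generative, other, up_to_permutation=True)


class TestHelperIdentities:
    def test_tanh_sum_difference_identities(self):
        # G+-(x, 0) = tanh(x); G+(0, y) = -G-(0, y) = tanh(y)
        grid = np.linspace(-5, 5, 41)
        x, y = np.meshgrid(grid, grid)
        assert np.abs(np.tanh(x + 0) - np.tanh(x)).max() < 1e-14
        assert np.abs(np.tanh(0 + y) + np.tanh(0 - y)).max() < 1e-14


class TestRandomPairProperties:
    def test_construction_satisfies_condition_with_zero_residual(self):
        for seed in range(30):
            p = random_sync_pair(3, seed=seed)
            assert check_sync_condition(p, tol=0.0)
            assert sync_residual(p) == 0.0

    def test_generative_flag_forces_generative_coupling(self):
        for seed in range(15):
            p = random_sync_pair(4, seed=seed, generative=True)
            assert classify_coupling(p).is_generative

    def test_split_reconstruction_round_trip(self, rng):
        for seed in range(10):
            p_target = rng.normal(size=(3, 3))
            m_target = rng.normal(size=(3, 3))
            w, w_coup = identical_module_split(p_target, m_target)
            pair = CoupledPair(
                thetaA=np.zeros(3), thetaB=np.zeros(3),
                wA=w, wB=w, wAB=w_coup, wBA=w_coup,
            )
            assert sync_matrix(pair, tol=1e-9).w_plus == pytest.approx(
                p_target, abs=1e-12
            )
            assert obstruction_matrix(pair, tol=1e-9) == pytest.approx(
                m_target, abs=1e-12
            )

    def test_diagonal_orbits_stay_synchronized_on_stable_manifolds(self):
        # transversally contracting couplings damp rounding noise, so the
        # invariant diagonal is preserved to machine precision
        for seed in range(10):
            p = random_sync_pair(3, seed=seed, stable_manifold=True)
            mod = assemble(p)
            r = np.random.default_rng(500 + seed)
            a0 = np.arctanh(r.uniform(-0.99, 0.99, 3))
            x = np.concatenate([a0, a0])
            div = 0.0
            for _ in range(1_000):
                x = step(mod, x)
                div = max(div, np.abs(x[:3] - x[3:]).max())
            assert div < 1e-6
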