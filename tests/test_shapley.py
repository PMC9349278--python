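"""Exact Shapley oracle: lifts, axioms, distribution decomposition, partitions."""

import numpy as np
import pytest

from gdshap.shapley import (
    Partition,
    SingleBaselineLift,
    check_efficiency,
    exact_shapley,
    exact_shapley_distribution,
    k_partition_shapley,
    lift_value,
    permutation_shapley,
)


def random_game(rng, m):
    """A smooth nonlinear model with interactions, plus a random input pair."""
    W = rng.standard_normal((m, m)) / m
    b = rng.standard_normal(m)

    def f(x):
        return float(x @ W @ x + b @ x)

    return f, rng.standard_normal(m), rng.standard_normal(m)


class TestLift:
    def test_full_and_empty_splices(self, rng):
        f, xe, xb = random_game(rng, 4)
        lift = SingleBaselineLift(f, xe, xb)
        assert lift_value(lift, range(4)) == pytest.approx(f(xe))
        assert lift_value(lift, []) == pytest.approx(f(xb))

    def test_direct_splice_evaluation(self):
        lift = SingleBaselineLift(lambda x: x[0] + 10 * x[1], [1.0, 1.0], [0.0, 0.0])
        assert lift_value(lift, [1]) == pytest.approx(10.0)


class TestExactShapley:
    def test_linear_model_recovers_weighted_deltas(self):
        lift = SingleBaselineLift(lambda x: 2 * x[0] + 3 * x[1], [1, 1], [0, 0])
        np.testing.assert_allclose(exact_shapley(lift).phi, [2.0, 3.0])

    def test_max_game_hand_enumeration(self):
        # both orderings of the two players, averaged: (1.5, 0.5)
        lift = SingleBaselineLift(lambda x: max(x[0], x[1]), [2, 1], [0, 0])
        np.testing.assert_allclose(exact_shapley(lift).phi, [1.5, 0.5])

    def test_unchanged_feature_gets_exact_zero(self, rng):
        f, xe, xb = random_game(rng, 5)
        xe[2] = xb[2]
        assert exact_shapley(SingleBaselineLift(f, xe, xb)).phi[2] == 0.0

    def test_symmetry_and_game(self):
        lift = SingleBaselineLift(lambda x: x[0] * x[1], [1, 1], [0, 0])
        np.testing.assert_allclose(exact_shapley(lift).phi, [0.5, 0.5])

    def test_dummy_player_gets_zero(self, rng):
        lift = SingleBaselineLift(lambda x: x[0] ** 2, rng.standard_normal(3), rng.standard_normal(3))
        phi = exact_shapley(lift).phi
        assert phi[1] == 0.0 and phi[2] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_permutation_and_subset_forms_agree(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 7))
        f, xe, xb = random_game(rng, m)
        lift = SingleBaselineLift(f, xe, xb)
        np.testing.assert_allclose(
            exact_shapley(lift).phi, permutation_shapley(lift).phi, atol=1e-10
        )

    def test_linearity_in_the_game(self, rng):
        m = 5
        f, xe, xb = random_game(rng, m)
        g, _, _ = random_game(rng, m)
        phi_sum = exact_shapley(SingleBaselineLift(lambda x: f(x) + g(x), xe, xb)).phi
        phi_f = exact_shapley(SingleBaselineLift(f, xe, xb)).phi
        phi_g = exact_shapley(SingleBaselineLift(g, xe, xb)).phi
        np.testing.assert_allclose(phi_sum, phi_f + phi_g, atol=1e-10)

    def test_cap_refusal(self, rng):
        lift = SingleBaselineLift(lambda x: x.sum(), np.ones(13), np.zeros(13))
        with pytest.raises(ValueError, match="cap"):
            exact_shapley(lift)

    def test_efficiency_always_holds(self, rng):
        for _ in range(10):
            f, xe, xb = random_game(rng, 5)
            phi = exact_shapley(SingleBaselineLift(f, xe, xb)).phi
            assert abs(phi.sum() - (f(xe) - f(xb))) <= 1e-9 * max(1.0, abs(f(xe)))


class TestDistribution:
    def test_single_row_degenerates_to_single_baseline(self, rng):
        f, xe, xb = random_game(rng, 4)
        phi_d = exact_shapley_distribution(f, xe, xb[None, :]).phi
        phi_1 = exact_shapley(SingleBaselineLift(f, xe, xb)).phi
        np.testing.assert_allclose(phi_d, phi_1)

    def test_linear_model_mean_baseline_closed_form(self, rng):
        beta = rng.standard_normal(4)
        D = rng.standard_normal((2, 4))
        xe = rng.standard_normal(4)
        phi = exact_shapley_distribution(lambda x: float(beta @ x), xe, D).phi
        np.testing.assert_allclose(phi, beta * (xe - D.mean(axis=0)), atol=1e-12)

    def test_product_game_dual_enumeration(self, rng):
        D = rng.standard_normal((3, 2))
        # the per-baseline mean vs distribution-lift equality is asserted inside
        phi = exact_shapley_distribution(lambda x: x[0] * x[1], [1.0, 1.0], D, check=True).phi
        assert np.all(np.isfinite(phi))

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            exact_shapley_distribution(lambda x: x[0], [1.0], np.empty((0, 1)))


class TestKPartition:
    def test_singletons_match_oracle(self, rng):
        m = 4
        beta = rng.standard_normal(m)
        xe, xb = rng.standard_normal(m), rng.standard_normal(m)
        f = np.tanh
        phi = k_partition_shapley(beta, 0.3, f, xe, xb, Partition.singletons(m)).phi
        oracle = exact_shapley(
            SingleBaselineLift(lambda x: float(f(beta @ x + 0.3)), xe, xb)
        ).phi
        np.testing.assert_allclose(phi, oracle, atol=1e-10)

    def test_one_partition_square_closed_form(self):
        # single cell: credit Δf/Δg-scaled linear deltas -> (3,-1)·(16-0)/(2-0)
        phi = k_partition_shapley(
            np.ones(2), 0.0, lambda z: z**2, [3.0, -1.0], [0.0, 0.0], Partition([[0, 1]], 2)
        ).phi
        np.testing.assert_allclose(phi, [6.0, -2.0])

    def test_sign_split_two_partition_matches_group_game_oracle(self, rng):
        # 4-feature ReLU unit, cells split by the sign of beta_i * delta_i
        m = 4
        beta = rng.standard_normal(m)
        xe, xb = rng.standard_normal(m), rng.standard_normal(m)
        d = beta * (xe - xb)
        pos = [i for i in range(m) if d[i] > 0]
        neg = [i for i in range(m) if d[i] <= 0]
        assert pos and neg  # seeded draw exercises both cells
        part = Partition([pos, neg], m)
        relu = lambda z: max(z, 0.0)
        phi = k_partition_shapley(beta, 0.1, relu, xe, xb, part).phi

        # independent oracle: enumerate the 2-player group game by hand
        def v(cells):
            chi = xb.copy()
            for cell in cells:
                chi[cell] = xe[cell]
            return relu(float(beta @ chi + 0.1))

        phi_pos = 0.5 * (v([pos]) - v([])) + 0.5 * (v([pos, neg]) - v([neg]))
        phi_neg = 0.5 * (v([neg]) - v([])) + 0.5 * (v([pos, neg]) - v([pos]))
        expected = np.zeros(m)
        expected[pos] = phi_pos * d[pos] / d[pos].sum()
        expected[neg] = phi_neg * d[neg] / d[neg].sum()
        np.testing.assert_allclose(phi, expected, atol=1e-10)

    def test_zero_delta_cell_uniform_fallback(self):
        # cell {0,1} has cancelling linear deltas; credit splits uniformly
        beta = np.array([1.0, 1.0, 1.0])
        xe, xb = np.array([1.0, -1.0, 1.0]), np.zeros(3)
        with pytest.warns(UserWarning, match="uniform"):
            phi = k_partition_shapley(
                beta, 0.0, lambda z: z**2, xe, xb, Partition([[0, 1], [2]], 3)
            ).phi
        assert phi[0] == phi[1]
        assert phi.sum() == pytest.approx(1.0 - 0.0)  # h(xe)=1, h(xb)=0

    def test_partition_validation(self):
        with pytest.raises(ValueError, match="empty"):
            Partition([[0, 1], []], 2)
        with pytest.raises(ValueError, match="overlap"):
            Partition([[0, 1], [1]], 2)
        with pytest.raises(ValueError, match="cover"):
            Partition([[0]], 2)


class TestEfficiencyCheck:
    def test_exact_attribution_passes(self, rng):
        f, xe, xb = random_game(rng, 4)
        phi = exact_shapley(SingleBaselineLift(f, xe, xb)).phi
        ok, residual = check_efficiency(phi, f, xe, xb)
        assert ok and residual < 1e-9

    def test_zero_vector_fails_with_full_delta(self, rng):
        f, xe, xb = random_game(rng, 3)
        ok, residual = check_efficiency(np.zeros(3), f, xe, xb)
        assert not ok
        assert residual == pytest.approx(abs(f(xe) - f(xb)))

    def test_distribution_target_is_mean_prediction(self, rng):
        f, xe, _ = random_game(rng, 3)
        D = rng.standard_normal((5, 3))
        phi = exact_shapley_distribution(f, xe, D, check=False).phi
        ok, _ = check_efficiency(phi, f, xe, D)
        assert ok
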