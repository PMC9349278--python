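"""Chained propagation: Hadamard division, recursion, baseline averaging."""

import json
import multiprocessing

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gdshap.chain import (
    combine_messages,
    explain,
    explain_batch,
    hadamard_div,
    propagate,
    stage_message,
)
from gdshap.models import LinearStage, SeriesModel, series_to_dict
from gdshap.shapley import SingleBaselineLift, exact_shapley
from gdshap.synthetic import FixtureSpec, gen_random_stage, gen_series, gen_tabular

finite = st.floats(-1e6, 1e6, allow_nan=False)


class TestHadamardDiv:
    def test_zero_denominator_maps_to_zero(self):
        np.testing.assert_array_equal(hadamard_div([4.0, 2.0], [2.0, 0.0]), [2.0, 0.0])

    @given(hnp.arrays(float, 5, elements=st.floats(0.5, 1e3)))
    def test_self_division_is_one(self, a):
        np.testing.assert_allclose(hadamard_div(a, a), np.ones(5))

    @given(hnp.arrays(float, 4, elements=finite))
    def test_zero_numerator_stays_zero(self, b):
        np.testing.assert_array_equal(hadamard_div(np.zeros(4), b), np.zeros(4))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hadamard_div([1.0], [1.0, 2.0])


def mixed_series(seed: int, m: int) -> SeriesModel:
    rng = np.random.default_rng(seed)
    widths = [m, int(rng.integers(2, 6)), int(rng.integers(2, 5))]
    stages = [
        gen_random_stage("linear", widths[0], seed=seed, n_outputs=widths[1]),
        gen_random_stage("dense", widths[1], seed=seed + 1, hidden=(5,), n_outputs=widths[2]),
        gen_random_stage("tree", widths[2], seed=seed + 2, depth=2, n_trees=2),
        gen_random_stage("transform", 1, seed=seed + 3, transform="sigmoid"),
    ]
    return SeriesModel(stages)


class TestPropagate:
    def test_single_stage_recursion_base(self, rng):
        stage = gen_random_stage("linear", 4, seed=0, n_outputs=1)
        series = SeriesModel([stage])
        xe, xb = rng.standard_normal(4), rng.standard_normal(4)
        res = propagate(series, xe, xb)
        np.testing.assert_array_equal(res.phi, stage.weights[0] * (xe - xb))

    def test_two_linear_stages_equal_collapsed_oracle(self, rng):
        W1, W2 = rng.standard_normal((3, 5)), rng.standard_normal((1, 3))
        series = SeriesModel([LinearStage(W1, rng.standard_normal(3)), LinearStage(W2)])
        xe, xb = rng.standard_normal(5), rng.standard_normal(5)
        phi = propagate(series, xe, xb).phi
        oracle = exact_shapley(SingleBaselineLift(series.predict, xe, xb)).phi
        np.testing.assert_allclose(phi, oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_every_intermediate_sums_to_final_delta(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 7))
        series = mixed_series(seed, m)
        xe, xb = rng.standard_normal(m), rng.standard_normal(m)
        res = propagate(series, xe, xb)
        target = float(series.predict(xe[None])[0] - series.predict(xb[None])[0])
        for psi in res.psi:
            assert psi.sum() == pytest.approx(target, rel=1e-8, abs=1e-8)

    def test_requires_scalar_final_output(self, rng):
        series = SeriesModel([LinearStage(rng.standard_normal((2, 3)))])
        with pytest.raises(ValueError, match="scalar"):
            propagate(series, np.zeros(3), np.ones(3))

    def test_unchanged_feature_gets_exact_zero(self, rng):
        series = mixed_series(3, 5)
        xe = rng.standard_normal(5)
        xb = xe.copy()
        xb[1] = xe[1] + 1.0
        phi = propagate(series, xe, xb).phi
        assert all(phi[i] == 0.0 for i in range(5) if i != 1)


class TestExplain:
    def test_single_baseline_degenerates_to_propagate(self, rng):
        series = mixed_series(0, 4)
        xe, xb = rng.standard_normal(4), rng.standard_normal(4)
        np.testing.assert_array_equal(explain(series, xe, xb[None, :]).phi, propagate(series, xe, xb).phi)

    def test_all_linear_series_closed_form(self, rng):
        W1, W2 = rng.standard_normal((3, 4)), rng.standard_normal((1, 3))
        series = SeriesModel([LinearStage(W1), LinearStage(W2)])
        D = rng.standard_normal((7, 4))
        xe = rng.standard_normal(4)
        beta = (W2 @ W1)[0]
        np.testing.assert_allclose(
            explain(series, xe, D).phi, beta * (xe - D.mean(axis=0)), atol=1e-10
        )

    def test_phi_is_mean_of_independent_chains(self, rng):
        series = mixed_series(5, 5)
        D = rng.standard_normal((10, 5))
        xe = rng.standard_normal(5)
        res = explain(series, xe, D, retain_intermediate=True)
        assert len(res.per_baseline) == 10
        np.testing.assert_allclose(
            res.phi, np.mean([propagate(series, xe, xb).phi for xb in D], axis=0)
        )

    def test_empty_baselines_rejected(self):
        series = SeriesModel([LinearStage([[1.0, 1.0]])])
        with pytest.raises(ValueError, match="empty"):
            explain(series, np.zeros(2), np.empty((0, 2)))

    def test_distribution_efficiency(self, rng):
        series = mixed_series(7, 5)
        D = rng.standard_normal((8, 5))
        xe = rng.standard_normal(5)
        phi = explain(series, xe, D).phi
        target = series.predict(xe[None])[0] - series.predict(D).mean()
        assert phi.sum() == pytest.approx(target, rel=1e-8, abs=1e-8)


class TestExplainBatch:
    def test_same_seed_identical(self, rng):
        series = mixed_series(1, 4)
        X_e = rng.standard_normal((3, 4))
        D = rng.standard_normal((30, 4))
        a = explain_batch(series, X_e, D, n_baselines=10, seed=7)
        b = explain_batch(series, X_e, D, n_baselines=10, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_full_subsample_equals_full_distribution(self, rng):
        series = mixed_series(2, 4)
        X_e = rng.standard_normal((2, 4))
        D = rng.standard_normal((6, 4))
        full = np.vstack([explain(series, x, D).phi for x in X_e])
        np.testing.assert_array_equal(explain_batch(series, X_e, D, n_baselines=6, seed=0), full)


class TestSingleBaselineBias:
    def test_planted_feature_hidden_from_single_baseline(self):
        """A feature fixed at the baseline's value gets zero single-baseline
        credit but nonzero credit under a baseline distribution."""
        spec = FixtureSpec(n=200, m=6, seed=11)
        X, _ = gen_tabular(spec)
        series = SeriesModel(
            [gen_random_stage("dense", 6, seed=11, hidden=(6,), n_outputs=1)]
        )
        xb = X[0]
        xe = X[1].copy()
        xe[2] = xb[2]  # informative feature pinned at this baseline's value
        assert propagate(series, xe, xb).phi[2] == 0.0
        assert abs(explain(series, xe, X[2:102]).phi[2]) > 1e-3


def _worker(payload: str) -> dict:
    """Institution-side endpoint: receives a stage document and the
    intermediate input pair as JSON, returns the attribution message."""
    doc = json.loads(payload)
    from gdshap.models import _stage_from_dict

    stage = _stage_from_dict(doc["stage"], "$")
    msg = stage_message(stage, np.array(doc["z_e"]), np.array(doc["z_b"]))
    return {k: v.tolist() for k, v in msg.items()}


class TestDistributedChain:
    def test_split_processes_reproduce_phi_bitwise(self, rng):
        """Stages evaluated in separate processes, exchanging only attribution
        matrices and intermediate value pairs, reproduce the in-process result
        bit for bit."""
        series = mixed_series(9, 5)
        xe, xb = rng.standard_normal(5), rng.standard_normal(5)
        reference = propagate(series, xe, xb)

        ctx = multiprocessing.get_context("spawn")
        messages = []
        z_e, z_b = xe, xb
        with ctx.Pool(1) as pool:
            for stage in series.stages:
                payload = json.dumps(
                    {
                        "stage": stage.to_dict(),
                        "z_e": list(z_e),
                        "z_b": list(z_b),
                    }
                )
                raw = pool.apply(_worker, (payload,))
                msg = {k: np.array(v) for k, v in raw.items()}
                messages.append(msg)
                z_e, z_b = msg["out_e"], msg["out_b"]
        distributed = combine_messages(messages)
        for psi_d, psi_r in zip(distributed.psi, reference.psi):
            np.testing.assert_array_equal(psi_d, psi_r)
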