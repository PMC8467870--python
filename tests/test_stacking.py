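"""Logistic meta-classifier: analytic values, oracles, optimizer agreement."""

import numpy as np
import pytest

from arousalstack.config import GdConfig
from arousalstack.stacking import (
    MetaCoefs,
    cost,
    cost_grad,
    fit_meta,
    logistic,
    predict_meta,
    stack_probabilities,
)


def _simulate(rng, beta_true, M):
    X = np.column_stack([np.ones(M), rng.standard_normal((M, len(beta_true) - 1))])
    p = logistic(X, np.asarray(beta_true))
    y = (rng.random(M) < p).astype(float)
    return X, y


class TestLogistic:
    def test_zero_beta_gives_half(self):
        assert logistic(np.ones((1, 3)), np.zeros(3))[0] == pytest.approx(0.5)

    def test_log3_gives_three_quarters(self):
        P = np.array([[1.0, 0.0]])
        beta = np.array([np.log(3.0), 5.0])
        assert logistic(P, beta)[0] == pytest.approx(0.75, rel=1e-12)

    def test_saturation_without_overflow(self):
        P = np.array([[1.0], [-1.0]])
        h = logistic(P, np.array([40.0]))
        assert h[0] == pytest.approx(1.0, abs=1e-10)
        assert h[1] == pytest.approx(0.0, abs=1e-10)
        assert np.all(np.isfinite(h))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            logistic(np.ones((2, 3)), np.zeros(4))


class TestCost:
    def test_zero_beta_cost_is_ln2(self, rng):
        P = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
        y = rng.integers(0, 2, 50).astype(float)
        assert cost(P, y, np.zeros(3)) == pytest.approx(np.log(2.0), rel=1e-12)

    def test_perfect_predictions_cost_near_zero(self):
        P = np.array([[1.0, 10.0], [1.0, -10.0]])
        y = np.array([1.0, 0.0])
        assert cost(P, y, np.array([0.0, 10.0])) < 1e-8

    def test_vectorized_equals_naive_loop(self, rng):
        P = np.column_stack([np.ones(30), rng.standard_normal((30, 3))])
        y = rng.integers(0, 2, 30).astype(float)
        beta = rng.standard_normal(4)
        naive = 0.0
        for j in range(30):
            z = float(P[j] @ beta)
            h = np.exp(z) / (1 + np.exp(z))
            naive += -(y[j] * np.log(h) + (1 - y[j]) * np.log(1 - h))
        assert cost(P, y, beta) == pytest.approx(naive / 30, abs=1e-12)

    def test_empty_trainset_rejected(self):
        with pytest.raises(ValueError):
            cost(np.empty((0, 3)), np.empty(0), np.zeros(3))

    def test_duplicating_rows_leaves_cost_unchanged(self, rng):
        P = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        y = rng.integers(0, 2, 20).astype(float)
        beta = rng.standard_normal(3)
        assert cost(np.vstack([P, P]), np.concatenate([y, y]), beta) == pytest.approx(
            cost(P, y, beta), rel=1e-12
        )


class TestFit:
    def test_monotone_descent_on_separable_toy(self):
        P = np.array([[1.0, x] for x in (-2.0, -1.0, 1.0, 2.0)])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        cfg = GdConfig(max_iter=200)
        # re-run the descent manually to observe J at every iterate
        beta = np.zeros(2)
        J_prev = cost(P, y, beta)
        for _ in range(50):
            g = cost_grad(P, y, beta)
            step = cfg.step
            while cost(P, y, beta - step * g) > J_prev - cfg.armijo * step * (g @ g):
                step *= cfg.backtrack
            beta = beta - step * g
            J = cost(P, y, beta)
            assert J <= J_prev + 1e-15
            J_prev = J

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_meta(np.ones((5, 2)), np.ones(5))

    def test_parameter_recovery_within_5_percent(self, rng):
        beta_true = np.array([0.5, -1.2, 2.0, 0.8])
        X, y = _simulate(rng, beta_true, 100_000)
        coefs = fit_meta(X, y, GdConfig(tol=1e-5, max_iter=10_000))
        rel = np.abs(coefs.beta - beta_true) / np.abs(beta_true)
        assert rel.max() < 0.05

    def test_first_order_optimality(self, rng):
        X, y = _simulate(rng, np.array([0.3, -0.7, 1.1]), 2000)
        cfg = GdConfig(tol=1e-7, max_iter=30_000)
        coefs = fit_meta(X, y, cfg)
        assert np.abs(cost_grad(X, y, coefs.beta)).max() < cfg.tol

    def test_agrees_with_irls_oracle(self, rng):
        """Independent optimizer: statsmodels Newton/IRLS on full-rank data."""
        import statsmodels.api as sm

        X, y = _simulate(rng, np.array([0.2, 1.0, -1.5, 0.7]), 5000)
        ours = fit_meta(X, y, GdConfig(tol=1e-7, max_iter=30_000)).beta
        theirs = sm.Logit(y, X).fit(disp=0, tol=1e-12).params
        np.testing.assert_allclose(ours, theirs, atol=1e-4)


class TestPredict:
    def test_threshold_strictly_above_half(self):
        coefs = MetaCoefs(beta=np.array([0.0]), feature_names=["x0"])
        labels, h = predict_meta(np.array([[0.0]]), coefs)
        assert h[0] == pytest.approx(0.5)
        assert labels[0] == 0  # exactly 0.5 is "normal"

    def test_just_above_half_is_positive(self):
        coefs = MetaCoefs(beta=np.array([0.09]), feature_names=["x0"])
        labels, h = predict_meta(np.array([[1.0]]), coefs)
        assert h[0] > 0.5 and labels[0] == 1

    def test_labels_depend_only_on_linear_predictor(self, rng):
        P = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        beta = rng.standard_normal(3)
        l1, h1 = predict_meta(P, MetaCoefs(beta=beta, feature_names=list("abc")))
        # scale inputs and coefficients inversely: p^T beta unchanged
        l2, h2 = predict_meta(P * 2.0, MetaCoefs(beta=beta / 2.0,
                                                 feature_names=list("abc")))
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(h1, h2, atol=1e-12)


class TestStackAssembly:
    def test_intercept_and_pair_layout(self, rng):
        pairs = []
        for _ in range(4):
            p1 = rng.random(6)
            pairs.append(np.column_stack([1 - p1, p1]))
        P = stack_probabilities(pairs)
        assert P.shape == (6, 9)
        np.testing.assert_array_equal(P[:, 0], 1.0)
        for i in range(4):
            np.testing.assert_allclose(P[:, 2 * i + 1] + P[:, 2 * i + 2], 1.0)

    def test_mismatched_rows_rejected(self, rng):
        pairs = [np.ones((6, 2))] * 3 + [np.ones((5, 2))]
        with pytest.raises(ValueError):
            stack_probabilities(pairs)

    def test_coefs_json_roundtrip(self, tmp_path, rng):
        c = MetaCoefs(beta=rng.standard_normal(9), feature_names=[f"f{i}" for i in range(9)],
                      n_iter=42, grad_norm=1e-9)
        c.to_json(tmp_path / "beta.json")
        c2 = MetaCoefs.from_json(tmp_path / "beta.json")
        np.testing.assert_allclose(c2.beta, c.beta, atol=1e-15)
        assert c2.feature_names == c.feature_names
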