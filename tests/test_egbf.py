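"""EGBF boosting: derivatives, leaf weights, tree growth, end-to-end fits."""

import numpy as np
import pytest

from nutrihawk.egbf import (
    EGBFConfig,
    EGBFModel,
    fit,
    grow_tree,
    leaf_weight,
    softmax_grad_hess,
    structural_score,
)
from nutrihawk.fuzzy import fit_fuzzy_terms


def numeric_grad_hess(scores, labels, eps=1e-5):
    """Central finite differences of the summed multiclass cross-entropy."""

    def loss(s):
        z = s - s.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return -logp[np.arange(labels.size), labels].sum()

    n, C = scores.shape
    g = np.zeros_like(scores)
    h = np.zeros_like(scores)
    for i in range(n):
        for c in range(C):
            up, dn = scores.copy(), scores.copy()
            up[i, c] += eps
            dn[i, c] -= eps
            g[i, c] = (loss(up) - loss(dn)) / (2 * eps)
            h[i, c] = (loss(up) - 2 * loss(scores) + loss(dn)) / eps ** 2
    return g, h


def exhaustive_best_split(X, p, q, terms, config):
    """Independent maximum-structural-gain search over all fuzzy-term
    thresholds, using the closed-form gain expression directly."""
    best = None
    P, Q = p.sum(), q.sum()
    for j, ft in enumerate(terms.features):
        for term, thr in ft.thresholds():
            left = X[:, j] <= thr
            if left.all() or not left.any():
                continue
            PL, QL = p[left].sum(), q[left].sum()
            PR, QR = P - PL, Q - QL
            if QL < config.min_child_hessian or QR < config.min_child_hessian:
                continue
            gain = 0.5 * (PL ** 2 / (QL + config.beta)
                          + PR ** 2 / (QR + config.beta)
                          - P ** 2 / (Q + config.beta)) - config.alpha
            if gain > 0 and (best is None or gain > best[0] + 1e-15):
                best = (gain, j, thr)
    return best


class TestGradHess:
    def test_zero_scores_binary(self):
        p, q = softmax_grad_hess(np.zeros((1, 2)), np.array([0]))
        np.testing.assert_allclose(p[0], [-0.5, 0.5])
        np.testing.assert_allclose(q[0], [0.25, 0.25])

    def test_perfect_fit_limit(self):
        scores = np.array([[50.0, -50.0]])
        p, _ = softmax_grad_hess(scores, np.array([0]))
        np.testing.assert_allclose(p[0], [0.0, 0.0], atol=1e-12)

    def test_matches_finite_differences(self, rng):
        for _ in range(20):
            scores = rng.normal(size=(6, 4))
            labels = rng.integers(0, 4, size=6)
            p, q = softmax_grad_hess(scores, labels)
            gn, hn = numeric_grad_hess(scores, labels)
            np.testing.assert_allclose(p, gn, atol=1e-5)
            np.testing.assert_allclose(q, hn, atol=1e-4)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            softmax_grad_hess(np.zeros((2, 3)), np.array([0, 3]))


class TestLeafAndScore:
    def test_leaf_weight_variants(self):
        assert leaf_weight(2, 3, 1, "standard") == pytest.approx(-0.5)
        assert leaf_weight(2, 3, 1, "as_printed") == pytest.approx(-2 / 7)
        assert leaf_weight(0, 3, 1, "standard") == 0.0
        assert leaf_weight(0, 3, 1, "as_printed") == 0.0

    def test_leaf_weight_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            leaf_weight(1, 0, 0, "standard")

    def test_structural_score_single_leaf(self):
        assert structural_score([(2, 3)], alpha=0, beta=1) == pytest.approx(-0.5)

    def test_identical_gradient_split_gain_is_pure_penalty(self):
        # splitting a leaf into halves with identical gradient/hessian
        # shares leaves the quadratic term unchanged (beta=0), so the gain
        # is exactly the extra-leaf penalty -alpha
        alpha = 0.3
        parent = structural_score([(4, 6)], alpha, 0.0)
        children = structural_score([(2, 3), (2, 3)], alpha, 0.0)
        assert parent - children == pytest.approx(-alpha)

    def test_matches_direct_formula(self, rng):
        aggs = [(rng.normal(), rng.random() + 0.1) for _ in range(5)]
        expect = -0.5 * sum(P * P / (Q + 2.0) for P, Q in aggs) + 0.7 * len(aggs)
        assert structural_score(aggs, 0.7, 2.0) == pytest.approx(expect, abs=1e-12)


class TestGrowTree:
    def make_instance(self, rng, n=40, d=3, C=3):
        X = rng.random((n, d))
        y = rng.integers(0, C, size=n)
        scores = rng.normal(size=(n, C))
        p, q = softmax_grad_hess(scores, y)
        return X, y, p[:, 0], q[:, 0]

    def test_lambda_zero_reduces_to_pure_structural_split(self, rng):
        config = EGBFConfig(fuzzy_weight=0.0, max_depth=1, learning_rate=1.0)
        for _ in range(20):
            X, y, p, q = self.make_instance(rng, n=int(rng.integers(10, 51)))
            terms = fit_fuzzy_terms(X)
            tree = grow_tree(X, y, p, q, terms, config)
            oracle = exhaustive_best_split(X, p, q, terms, config)
            if oracle is None:
                assert tree.is_leaf
            else:
                assert not tree.is_leaf
                assert (tree.feature, tree.threshold) == (oracle[1], oracle[2])

    def test_max_depth_one_gives_stump(self, rng):
        X, y, p, q = self.make_instance(rng)
        tree = grow_tree(X, y, p, q, fit_fuzzy_terms(X),
                         EGBFConfig(max_depth=1))
        if not tree.is_leaf:
            assert tree.left.is_leaf and tree.right.is_leaf

    def test_equal_gradients_yield_single_leaf(self, rng):
        X = rng.random((30, 2))
        y = np.zeros(30, int)
        p = np.full(30, 0.25)
        q = np.full(30, 0.2)
        tree = grow_tree(X, y, p, q, fit_fuzzy_terms(X), EGBFConfig())
        assert tree.is_leaf

    def test_leaf_value_is_scaled_optimal_weight(self, rng):
        X = rng.random((10, 2))
        p = np.full(10, 1.0)
        q = np.full(10, 0.5)
        cfg = EGBFConfig(learning_rate=0.3, beta=1.0)
        tree = grow_tree(X, np.zeros(10, int), p, q, fit_fuzzy_terms(X), cfg)
        assert tree.is_leaf
        assert tree.value == pytest.approx(0.3 * (-10.0 / (5.0 + 1.0)))


class TestFit:
    def test_zero_rounds_predicts_priors(self, rng):
        X = rng.random((60, 3))
        y = np.array([0] * 40 + [1] * 20)
        model = fit(X, y, EGBFConfig(rounds=0))
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba, np.tile([2 / 3, 1 / 3], (60, 1)), atol=1e-12)

    def test_training_logloss_non_increasing(self, cohort_features):
        Xn, y = cohort_features
        model = fit(Xn, y, EGBFConfig(rounds=15, learning_rate=0.1))
        ll = np.array(model.train_logloss)
        assert len(ll) == 16
        assert np.all(np.diff(ll) <= 1e-10)

    def test_heldout_recovery(self, cohort_features):
        Xn, y = cohort_features
        tr = np.arange(0, 480)
        te = np.arange(480, 600)
        model = fit(Xn[tr], y[tr], EGBFConfig(rounds=25))
        acc = float((model.predict(Xn[te]) == y[te]).mean())
        assert acc >= 0.85

    def test_overfit_small_separable_set(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (25, 2)), rng.normal(1, 0.05, (25, 2))])
        y = np.array([0] * 25 + [1] * 25)
        model = fit(X, y, EGBFConfig(rounds=60, max_depth=6, learning_rate=0.3))
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit(rng.random((10, 2)), np.zeros(10, int), EGBFConfig(rounds=1))

    def test_probabilities_normalized(self, cohort_features):
        Xn, y = cohort_features
        model = fit(Xn[:200], y[:200], EGBFConfig(rounds=5))
        proba = model.predict_proba(Xn[200:300])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_serialization_round_trip_bit_equal(self, cohort_features):
        Xn, y = cohort_features
        model = fit(Xn[:150], y[:150], EGBFConfig(rounds=4))
        clone = EGBFModel.from_dict(model.to_dict())
        np.testing.assert_array_equal(
            model.predict_proba(Xn[:50]), clone.predict_proba(Xn[:50]))

    def test_schema_mismatch_rejected(self, cohort_features):
        Xn, y = cohort_features
        model = fit(Xn[:100], y[:100], EGBFConfig(rounds=1))
        with pytest.raises(ValueError):
            model.predict_proba(Xn[:5, :4])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EGBFConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            EGBFConfig(leaf_denominator="bogus")
        with pytest.raises(ValueError):
            EGBFConfig(fuzzy_weight=1.5)

    def test_as_printed_variants_still_learn(self, cohort_features):
        Xn, y = cohort_features
        model = fit(Xn[:300], y[:300], EGBFConfig(
            rounds=10, leaf_denominator="as_printed", entropy_sign="as_printed"))
        acc = float((model.predict(Xn[:300]) == y[:300]).mean())
        assert acc > 0.5  # fidelity variants remain usable classifiers
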