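import itertools
import json

import numpy as np
import pytest
from scipy.optimize import minimize

from polytomize.blr import (
    BLRConfig,
    BLRModel,
    confusion_counts,
    cv_select,
    default_variance_grid,
    evaluate,
    fit_map,
    fit_map_detailed,
    roc_auc,
    threshold_candidates,
    tune_threshold,
)


def reference_objective(X, y, prior, V):
    """The negative log-posterior, written independently for oracle fits."""

    def obj(p):
        w, b = p[:-1], p[-1]
        margins = y * (X @ w + b)
        loss = np.sum(np.log1p(np.exp(-np.clip(margins, -500, 500))))
        if prior == "gaussian":
            return loss + np.sum(w**2) / (2 * V)
        return loss + np.sqrt(2 / V) * np.sum(np.abs(w))

    return obj


def random_problem(rng, n=40, d=2, sep=1.0):
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    y = np.where(X @ w + sep * rng.normal(size=n) > 0, 1, -1)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    return X, y


class TestMapFit:
    def test_zero_features_balanced_classes(self):
        X = np.zeros((10, 2))
        y = np.array([1, -1] * 5)
        w, b = fit_map(X, y, "gaussian", 1.0)
        np.testing.assert_allclose(w, 0.0, atol=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_one_dim_matches_dense_grid_oracle(self):
        X = np.array([[-2.0], [-1.0], [-0.5], [0.5], [1.0], [2.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        V = 0.5
        w, b = fit_map(X, y, "gaussian", V, tol=1e-9)
        obj = reference_objective(X, y, "gaussian", V)
        grid = np.linspace(-5, 5, 401)
        best = min(
            (float(obj(np.array([wi, bi]))), wi, bi)
            for wi, bi in itertools.product(grid, grid)
        )
        # refine around the coarse grid optimum
        fine_w = np.linspace(best[1] - 0.05, best[1] + 0.05, 201)
        fine_b = np.linspace(best[2] - 0.05, best[2] + 0.05, 201)
        best = min(
            (float(obj(np.array([wi, bi]))), wi, bi)
            for wi, bi in itertools.product(fine_w, fine_b)
        )
        assert w[0] == pytest.approx(best[1], abs=1e-3)
        assert b == pytest.approx(best[2], abs=1e-3)
        assert obj(np.array([w[0], b])) <= best[0] + 1e-8

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_gaussian_matches_generic_optimizer(self, d, rng):
        for _ in range(3):
            X, y = random_problem(rng, n=50, d=d)
            V = float(rng.uniform(0.05, 2.0))
            w, b = fit_map(X, y, "gaussian", V, tol=1e-9)
            obj = reference_objective(X, y, "gaussian", V)
            res = minimize(obj, np.zeros(d + 1), method="BFGS", options={"gtol": 1e-10})
            np.testing.assert_allclose(np.r_[w, b], res.x, atol=1e-4)

    def test_objective_never_increases(self, rng):
        X, y = random_problem(rng, n=60, d=3)
        for prior in ("gaussian", "laplace"):
            res = fit_map_detailed(X, y, prior, 0.5)
            h = np.array(res.objective_history)
            assert np.all(np.diff(h) <= 1e-9)
            assert h[-1] <= h[0]

    def test_gaussian_shrinkage_monotone_in_variance(self, rng):
        X, y = random_problem(rng, n=60, d=2, sep=0.3)
        norms = []
        for V in default_variance_grid(12):
            w, _ = fit_map(X, y, "gaussian", V)
            norms.append(np.linalg.norm(w))
        assert all(b >= a - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_laplace_strong_shrinkage_gives_exact_zeros(self, rng):
        X, y = random_problem(rng, n=50, d=3, sep=0.5)
        X[:, 2] = X[:, 0] + 0.01 * rng.normal(size=50)  # collinear feature
        w, _ = fit_map(X, y, "laplace", 0.002)
        assert np.any(w == 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_map(np.ones((5, 1)), np.ones(5), "gaussian", 1.0)

    def test_nonfinite_features_rejected(self):
        X = np.array([[np.nan], [1.0]])
        with pytest.raises(ValueError):
            fit_map(X, np.array([1, -1]), "gaussian", 1.0)


class TestPredict:
    def _model(self, w, b, theta=0.5):
        w = np.asarray(w, dtype=float)
        return BLRModel(
            weights=w,
            intercept=b,
            prior_type="gaussian",
            variance=1.0,
            criterion=0,
            threshold=theta,
            feature_names=[f"f{i}" for i in range(len(w))],
            means=np.zeros(len(w)),
            scales=np.ones(len(w)),
        )

    def test_null_model_gives_half(self):
        m = self._model([0.0, 0.0], 0.0)
        assert m.predict_prob([[1.0, 2.0]])[0] == pytest.approx(0.5)

    def test_logistic_symmetry(self):
        m = self._model([1.0], 0.0)
        p1 = m.predict_prob([[0.7]])[0]
        p2 = m.predict_prob([[-0.7]])[0]
        assert p1 + p2 == pytest.approx(1.0)

    def test_monotone_in_decision_value(self):
        m = self._model([1.0], 0.0)
        xs = np.linspace(-3, 3, 10)[:, None]
        p = m.predict_prob(xs)
        assert np.all(np.diff(p) > 0)

    def test_dimension_mismatch(self):
        m = self._model([1.0, 2.0], 0.0)
        with pytest.raises(ValueError):
            m.predict_prob([[1.0]])

    def test_json_round_trip(self):
        m = self._model([1.5, -0.5], 0.25, theta=0.4)
        m2 = BLRModel.from_json(m.to_json())
        np.testing.assert_allclose(m2.weights, m.weights)
        assert (m2.intercept, m2.threshold) == (m.intercept, m.threshold)
        with pytest.raises(ValueError):
            BLRModel.from_json(json.dumps({"format_version": 99}))


def oracle_tune(scores, y, t, positive=+1):
    """Independent exhaustive threshold search (same tie rule)."""
    uniq = np.unique(scores)
    cands = [uniq[0] / 2] + [
        (a + b) / 2 for a, b in zip(uniq, uniq[1:])
    ] + [(uniq[-1] + 1) / 2]
    results = []
    for theta in cands:
        pred = np.where(scores >= theta, 1, -1)
        cm = confusion_counts(y, pred, positive)
        if t == 1:
            val = -(cm.fp + cm.fn)
        elif t == 2:
            sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0
            spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0
            val = (sens + spec) / 2
        elif t == 3:
            val = 2 * cm.tp - cm.fp
        elif t == 4:
            val = 2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn) if cm.tp else 0.0
        else:
            val = 20 * cm.tp - cm.fp
        results.append((val, theta))
    best_val = max(r[0] for r in results)
    optimal = [th for v, th in results if abs(v - best_val) <= 1e-12]
    return best_val, optimal


class TestThresholdTuning:
    def test_no_tuning_returns_half(self, rng):
        scores = rng.uniform(size=10)
        y = np.where(rng.uniform(size=10) > 0.5, 1, -1)
        assert tune_threshold(scores, y, 0) == 0.5

    def test_printed_example_t11u(self):
        theta = tune_threshold(
            np.array([0.1, 0.4, 0.6, 0.9]), np.array([-1, -1, 1, 1]), 3,
            positive_class=1,
        )
        assert 0.4 < theta < 0.6

    def test_perfect_separation_zero_errors_for_every_criterion(self):
        scores = np.array([0.05, 0.1, 0.2, 0.8, 0.9, 0.95])
        y = np.array([-1, -1, -1, 1, 1, 1])
        for t in range(6):
            theta = tune_threshold(scores, y, t)
            pred = np.where(scores >= theta, 1, -1)
            cm = confusion_counts(y, pred, -1)
            assert cm.fp == cm.fn == 0

    @pytest.mark.parametrize("t", [1, 2, 3, 4, 5])
    def test_matches_exhaustive_oracle(self, t, rng):
        for _ in range(20):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.uniform(size=n), 3)
            y = np.where(rng.uniform(size=n) > 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            theta = tune_threshold(scores, y, t, positive_class=1)
            best_val, optimal = oracle_tune(scores, y, t)
            assert any(abs(theta - th) <= 1e-12 for th in optimal)
            closest = min(optimal, key=lambda th: (abs(th - 0.5), th))
            assert theta == pytest.approx(closest)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tune_threshold(np.array([0.2, 0.8]), np.array([1, 1]), 4)

    def test_candidates_cover_extremes(self):
        c = threshold_candidates(np.array([0.2, 0.6]))
        assert c[0] < 0.2 and c[-1] > 0.6


class TestMetrics:
    def test_f1_printed_formula(self):
        y = np.array([1] * 10 + [-1] * 10)
        pred = np.array([1] * 8 + [-1] * 2 + [1] * 2 + [-1] * 8)
        m = evaluate(y, pred_labels=pred, positive_class=1)
        assert m.f1 == pytest.approx(0.8)  # TP=8, FP=2, FN=2
        assert m.t11u == 2 * 8 - 2
        assert m.t13u == 20 * 8 - 2

    def test_perfect_scores(self):
        y = np.array([-1, -1, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        m = evaluate(y, scores=scores, positive_class=1)
        assert m.auc == 1.0 and m.f1 == 1.0

    def test_constant_scores_give_auc_half(self):
        y = np.array([-1, 1, -1, 1])
        assert roc_auc(np.full(4, 0.5), y) == pytest.approx(0.5)

    def test_auc_matches_sklearn_midrank(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(5):
            n = 40
            scores = np.round(rng.uniform(size=n), 2)  # force ties
            y = np.where(rng.uniform(size=n) > 0.4, 1, -1)
            assert roc_auc(scores, y, positive_class=1) == pytest.approx(
                roc_auc_score((y + 1) // 2, scores)
            )

    def test_permutation_invariance_and_harmonic_mean(self, rng):
        y = np.where(rng.uniform(size=30) > 0.5, 1, -1)
        pred = np.where(rng.uniform(size=30) > 0.5, 1, -1)
        m1 = evaluate(y, pred_labels=pred)
        perm = rng.permutation(30)
        m2 = evaluate(y[perm], pred_labels=pred[perm])
        assert m1.f1 == m2.f1 and m1.precision == m2.precision
        if m1.precision > 0 and m1.recall > 0:
            hm = 2 * m1.precision * m1.recall / (m1.precision + m1.recall)
            assert m1.f1 == pytest.approx(hm)

    def test_zero_tp_gives_zero_f1(self):
        y = np.array([1, 1, -1])
        pred = np.array([-1, -1, -1])
        assert evaluate(y, pred_labels=pred, positive_class=1).f1 == 0.0


class TestCVSelect:
    def test_default_grid_is_doubling_ladder(self):
        grid = BLRConfig().variance_grid
        assert len(grid) == 20
        assert grid[0] == pytest.approx(0.002)
        for a, b in zip(grid, grid[1:]):
            assert b == pytest.approx(2 * a)

    def _separable(self, rng, n=120):
        X = rng.normal(size=(n, 2))
        y = np.where(X[:, 0] + 0.2 * rng.normal(size=n) > 0, 1, -1)
        return X, y

    def test_deterministic_under_seed(self, rng):
        X, y = self._separable(rng)
        cfg = dict(
            variance_grid=default_variance_grid(6),
            tuning_criteria=(0, 3, 4),
            seed=42,
        )
        m1 = cv_select(X, y, BLRConfig(**cfg))
        m2 = cv_select(X, y, BLRConfig(**cfg))
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert (m1.variance, m1.criterion, m1.threshold) == (
            m2.variance,
            m2.criterion,
            m2.threshold,
        )

    def test_selection_maximizes_cv_f1_over_grid(self, rng):
        X, y = self._separable(rng)
        cfg = BLRConfig(
            variance_grid=default_variance_grid(5), tuning_criteria=(1, 4), seed=7
        )
        model = cv_select(X, y, cfg)
        scores = model.cv_report["mean_heldout_f1"]
        best = max(scores.values())
        key = f"{model.variance:g}|{model.criterion}"
        assert scores[key] == pytest.approx(best)
        assert model.cv_report["mean_heldout_loglik_per_V"]  # recorded per V

    def test_standardization_makes_fit_scale_invariant(self, rng):
        X, y = self._separable(rng, n=80)
        cfg = dict(variance_grid=(0.128,), tuning_criteria=(4,), seed=3)
        m1 = cv_select(X, y, BLRConfig(**cfg))
        X2 = X * np.array([100.0, 0.01]) + np.array([5.0, -3.0])
        m2 = cv_select(X2, y, BLRConfig(**cfg))
        np.testing.assert_allclose(
            m1.predict_prob(X), m2.predict_prob(X2), atol=1e-6
        )

    def test_too_few_per_class_rejected(self):
        X = np.zeros((4, 1))
        y = np.array([1, 1, 1, -1])
        with pytest.raises(ValueError):
            cv_select(X, y, BLRConfig())
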