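"""Bayesian logistic regression (MAP) for dichotomy/polytomy classification.

The classifier is penalized logistic regression fitted to its maximum a
posteriori point under one of two priors on the weights, both parameterized
by a prior variance ``V``:

* Gaussian prior: penalty ``sum_j w_j^2 / (2V)`` (ridge-like),
* Laplace prior: penalty ``lambda * sum_j |w_j|`` with ``lambda = sqrt(2/V)``
  (lasso-like; the Laplace(0, b) density has variance 2 b^2, so this choice
  makes the prior variance equal V).

The intercept is always unpenalized.  Fitting uses cyclic coordinate
descent with a per-coordinate trust region and a curvature upper bound on
the logistic loss (the CLG scheme of ridge/lasso logistic regression
solvers); each coordinate step cannot increase the objective, and under the
Laplace prior weights are driven *exactly* to zero.

Model selection runs a stratified k-fold cross-validated grid search over
the prior variance ladder ``V_1 = 0.002, V_{i+1} = 2 V_i`` (20 values) and
over the threshold-tuning criterion ``t``:

====  =========================================
t     criterion for tuning the decision threshold
====  =========================================
0     none (threshold fixed at 0.5)
1     minimize sum of errors = FP + FN
2     maximize (sensitivity + specificity) / 2
3     maximize T11U = 2*TP - FP
4     maximize F1 = 2*TP / (2*TP + FP + FN)
5     maximize T13U = 20*TP - FP
====  =========================================

Labels are coded +1 (dichotomy) and -1 (polytomy) throughout; reported
detection metrics treat the polytomy class as positive by default, since
polytomy identification is the task.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BLRConfig",
    "BLRModel",
    "ConfusionCounts",
    "Metrics",
    "FitResult",
    "default_variance_grid",
    "fit_map",
    "fit_map_detailed",
    "tune_threshold",
    "threshold_candidates",
    "confusion_counts",
    "evaluate",
    "roc_auc",
    "cv_select",
]

CRITERION_NAMES = {
    0: "none",
    1: "sum_of_errors",
    2: "balanced_accuracy",
    3: "T11U",
    4: "F1",
    5: "T13U",
}


def default_variance_grid(n: int = 20, v1: float = 0.002) -> tuple[float, ...]:
    """The doubling prior-variance ladder: v1, 2*v1, ..., v1 * 2**(n-1)."""
    return tuple(v1 * (2.0**i) for i in range(n))


@dataclass
class BLRConfig:
    prior_type: str = "gaussian"
    variance_grid: tuple[float, ...] = field(default_factory=default_variance_grid)
    tuning_criteria: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    cv_folds: int = 3
    standardize: bool = True
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 1000
    positive_class: int = -1  # polytomy is the class being detected

    def __post_init__(self) -> None:
        if self.prior_type not in ("gaussian", "laplace"):
            raise ValueError(f"unknown prior type {self.prior_type!r}")
        grid = tuple(float(v) for v in self.variance_grid)
        if any(v <= 0 for v in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("variance grid must be positive and increasing")
        self.variance_grid = grid
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        bad = set(self.tuning_criteria) - set(CRITERION_NAMES)
        if bad:
            raise ValueError(f"unknown tuning criteria: {sorted(bad)}")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float
    balanced_accuracy: float
    auc: float | None
    sum_of_errors: int
    t11u: float
    t13u: float
    confusion: ConfusionCounts


@dataclass
class FitResult:
    weights: np.ndarray
    intercept: float
    objective_history: list[float]
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# MAP fitting (cyclic coordinate descent with trust region)
# ---------------------------------------------------------------------------


def _objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, prior_type: str, V: float
) -> float:
    margins = y * (X @ w + b)
    loss = float(np.sum(np.logaddexp(0.0, -margins)))
    if prior_type == "gaussian":
        penalty = float(np.sum(w**2)) / (2.0 * V)
    else:
        penalty = math.sqrt(2.0 / V) * float(np.sum(np.abs(w)))
    return loss + penalty


def _curvature_bound(yr: np.ndarray, width: np.ndarray) -> np.ndarray:
    """Upper bound on the logistic loss curvature over |r' - r| <= width."""
    a = np.abs(yr)
    out = np.full_like(a, 0.25)
    far = a > width
    if np.any(far):
        gap = np.clip(a[far] - width[far], None, 500.0)
        out[far] = 1.0 / (2.0 + np.exp(gap) + np.exp(-gap))
    return out


def _sigma_neg(yr: np.ndarray) -> np.ndarray:
    """sigma(-yr) = 1/(1+exp(yr)), overflow-safe."""
    return 1.0 / (1.0 + np.exp(np.clip(yr, -500.0, 500.0)))


def fit_map_detailed(
    X: np.ndarray,
    y: np.ndarray,
    prior_type: str = "gaussian",
    V: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> FitResult:
    """MAP fit; returns weights, intercept and the per-sweep objective trace."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {+1, -1}")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to fit")
    if V <= 0:
        raise ValueError("prior variance must be positive")
    if prior_type not in ("gaussian", "laplace"):
        raise ValueError(f"unknown prior type {prior_type!r}")

    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    r = np.zeros(n)  # linear predictor per instance
    delta = np.ones(d + 1)  # trust-region half-widths; index d = intercept
    lam = math.sqrt(2.0 / V)
    Xsq = X**2
    history = [_objective(X, y, w, b, prior_type, V)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_step = 0.0
        for j in range(d + 1):
            xj = X[:, j] if j < d else None
            yr = y * r
            p = _sigma_neg(yr)  # d/dr of loss is -y*p
            if j < d:
                grad_ll = float(np.sum(y * xj * p))
                width = delta[j] * np.abs(xj)
                denom0 = float(np.sum(Xsq[:, j] * _curvature_bound(yr, width)))
                if denom0 <= 0 and prior_type == "laplace":
                    continue
                if prior_type == "gaussian":
                    dv = (grad_ll - w[j] / V) / (denom0 + 1.0 / V)
                    step = float(np.clip(dv, -delta[j], delta[j]))
                else:
                    if w[j] != 0.0:
                        s = math.copysign(1.0, w[j])
                        dv = (grad_ll - lam * s) / denom0
                        step = float(np.clip(dv, -delta[j], delta[j]))
                        if (w[j] + step) * s < 0:
                            step = -w[j]  # crossed zero: park at exactly 0
                    else:
                        dv = (grad_ll - lam) / denom0
                        if dv <= 0:
                            dv = (grad_ll + lam) / denom0
                            if dv >= 0:
                                dv = 0.0
                        step = float(np.clip(dv, -delta[j], delta[j]))
                w[j] += step
                if step != 0.0:
                    r += step * xj
            else:
                grad_ll = float(np.sum(y * p))
                width = np.full(n, delta[j])
                denom0 = float(np.sum(_curvature_bound(yr, width)))
                if denom0 <= 0:
                    continue
                dv = grad_ll / denom0
                step = float(np.clip(dv, -delta[j], delta[j]))
                b += step
                if step != 0.0:
                    r += step
            delta[j] = max(2.0 * abs(step), delta[j] / 2.0)
            max_step = max(max_step, abs(step))
        history.append(_objective(X, y, w, b, prior_type, V))
        if max_step <= tol:
            if prior_type == "laplace":
                converged = True
                break
            # Gaussian contract: gradient norm below tol
            p = _sigma_neg(y * r)
            grad = np.concatenate(
                [-(X * (y * p)[:, None]).sum(axis=0) + w / V, [-(y * p).sum()]]
            )
            if float(np.linalg.norm(grad)) <= tol:
                converged = True
                break
    return FitResult(w, b, history, converged, it)


def fit_map(
    X: np.ndarray,
    y: np.ndarray,
    prior_type: str = "gaussian",
    V: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, float]:
    res = fit_map_detailed(X, y, prior_type=prior_type, V=V, tol=tol, max_iter=max_iter)
    return res.weights, res.intercept


# ---------------------------------------------------------------------------
# Thresholds, confusion counts and metrics
# ---------------------------------------------------------------------------


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, positive_class: int = -1
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_class
    pred_pos = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def _criterion_value(cm: ConfusionCounts, t: int) -> float:
    if t == 1:
        return -(cm.fp + cm.fn)  # maximized form of "minimize sum of errors"
    if t == 2:
        sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
        spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else 0.0
        return 0.5 * (sens + spec)
    if t == 3:
        return 2.0 * cm.tp - cm.fp
    if t == 4:
        denom = 2 * cm.tp + cm.fp + cm.fn
        return (2.0 * cm.tp / denom) if denom else 0.0
    if t == 5:
        return 20.0 * cm.tp - cm.fp
    raise ValueError(f"criterion {t} has no utility value")


def threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted scores, plus one
    candidate below the minimum and one above the maximum."""
    s = np.unique(np.asarray(scores, dtype=float))
    mids = 0.5 * (s[:-1] + s[1:])
    return np.concatenate([[s[0] / 2.0], mids, [(s[-1] + 1.0) / 2.0]])


def tune_threshold(
    scores: np.ndarray,
    y: np.ndarray,
    t: int,
    positive_class: int = +1,
) -> float:
    """Pick the probability threshold optimizing criterion ``t``.

    ``scores`` are P(label = +1); an instance is predicted +1 when its score
    is >= the threshold.  Ties between equally good thresholds go to the one
    closest to 0.5 (then the smaller).
    """
    if t == 0:
        return 0.5
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError(f"criterion {t} needs both classes present")
    best_theta, best_val = None, -np.inf
    for theta in threshold_candidates(scores):
        pred = np.where(scores >= theta, 1, -1)
        val = _criterion_value(confusion_counts(y, pred, positive_class), t)
        if (
            best_theta is None
            or val > best_val + 1e-12
            or (
                abs(val - best_val) <= 1e-12
                and (
                    abs(theta - 0.5) < abs(best_theta - 0.5) - 1e-12
                    or (
                        abs(abs(theta - 0.5) - abs(best_theta - 0.5)) <= 1e-12
                        and theta < best_theta
                    )
                )
            )
        ):
            best_theta, best_val = float(theta), val
    return best_theta


def roc_auc(scores: np.ndarray, y: np.ndarray, positive_class: int = -1) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney statistic."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    s = scores if positive_class == +1 else -scores
    ranks = rankdata(s)
    return (float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def evaluate(
    y_true: np.ndarray,
    pred_labels: np.ndarray | None = None,
    scores: np.ndarray | None = None,
    positive_class: int = -1,
    threshold: float = 0.5,
) -> Metrics:
    """Precision/recall/F1/balanced accuracy/AUC and the utility values.

    ``scores`` are P(label = +1).  When ``pred_labels`` is omitted they are
    derived from ``scores`` at ``threshold``.
    """
    y_true = np.asarray(y_true)
    if pred_labels is None:
        if scores is None:
            raise ValueError("need pred_labels or scores")
        pred_labels = np.where(np.asarray(scores) >= threshold, 1, -1)
    cm = confusion_counts(y_true, pred_labels, positive_class)
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
    denom = 2 * cm.tp + cm.fp + cm.fn
    f1 = (2.0 * cm.tp / denom) if denom else 0.0
    sens = recall
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else 0.0
    auc = None
    if scores is not None:
        auc = roc_auc(np.asarray(scores), y_true, positive_class)
    return Metrics(
        precision=precision,
        recall=recall,
        f1=f1,
        balanced_accuracy=0.5 * (sens + spec),
        auc=auc,
        sum_of_errors=cm.fp + cm.fn,
        t11u=2.0 * cm.tp - cm.fp,
        t13u=20.0 * cm.tp - cm.fp,
        confusion=cm,
    )


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


@dataclass
class BLRModel:
    weights: np.ndarray
    intercept: float
    prior_type: str
    variance: float
    criterion: int
    threshold: float
    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    cv_report: dict | None = field(default=None, repr=False)

    def _standardized(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.weights):
            raise ValueError(
                f"feature dimension mismatch: model has {len(self.weights)}, "
                f"input has {X.shape[1]}"
            )
        return (X - self.means) / self.scales

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._standardized(X) @ self.weights + self.intercept

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        """P(label = +1, i.e. dichotomy) per row."""
        return _sigma_neg(-self.decision(X))

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.predict_prob(X) >= self.threshold, 1, -1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "prior": self.prior_type,
                "V": self.variance,
                "t": self.criterion,
                "theta": self.threshold,
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "feature_names": list(self.feature_names),
                "means": self.means.tolist(),
                "scales": self.scales.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BLRModel":
        obj = json.loads(text)
        if obj.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {obj.get('format_version')!r}"
            )
        return cls(
            weights=np.array(obj["weights"], dtype=float),
            intercept=float(obj["intercept"]),
            prior_type=obj["prior"],
            variance=float(obj["V"]),
            criterion=int(obj["t"]),
            threshold=float(obj["theta"]),
            feature_names=list(obj["feature_names"]),
            means=np.array(obj["means"], dtype=float),
            scales=np.array(obj["scales"], dtype=float),
        )


# ---------------------------------------------------------------------------
# Cross-validated (V, t) selection
# ---------------------------------------------------------------------------


def _standardization(X: np.ndarray, on: bool) -> tuple[np.ndarray, np.ndarray]:
    if not on:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    return means, scales


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified k-fold assignment; returns test-index arrays."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def _mean_loglik(scores: np.ndarray, y: np.ndarray) -> float:
    """Mean log-likelihood of the true labels under predicted probabilities."""
    p = np.clip(scores, 1e-12, 1 - 1e-12)
    pos = y == 1
    return float(np.mean(np.where(pos, np.log(p), np.log(1 - p))))


def cv_select(X: np.ndarray, y: np.ndarray, config: BLRConfig) -> BLRModel:
    """Grid-search (V, t) by stratified k-fold CV, then refit on all data.

    For each (V, t) pair the model is fitted on k-1 folds, the decision
    threshold is tuned on the *training* folds under criterion t, and the
    held-out F-measure (positive class per config) is recorded.  The pair
    maximizing the mean held-out F-measure wins; ties prefer the smaller V,
    then the smaller t.  The mean held-out log-likelihood per V — the
    alternative selection rule — is recorded in ``model.cv_report``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y), np.unique(y, return_counts=True)[1]
    if len(classes) < 2 or counts.min() < config.cv_folds:
        raise ValueError(
            f"need at least {config.cv_folds} instances of each class for CV"
        )
    folds = stratified_folds(y, config.cv_folds, config.seed)
    all_idx = np.arange(len(y))

    fold_cache: list[dict] = []
    loglik_per_v: dict[float, list[float]] = {v: [] for v in config.variance_grid}
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        Xtr, ytr = X[train_idx], y[train_idx]
        Xte, yte = X[test_idx], y[test_idx]
        means, scales = _standardization(Xtr, config.standardize)
        Ztr = (Xtr - means) / scales
        Zte = (Xte - means) / scales
        per_v = {}
        for V in config.variance_grid:
            w, b = fit_map(
                Ztr, ytr, config.prior_type, V, tol=config.tol, max_iter=config.max_iter
            )
            p_tr = _sigma_neg(-(Ztr @ w + b))
            p_te = _sigma_neg(-(Zte @ w + b))
            per_v[V] = (p_tr, ytr, p_te, yte)
            loglik_per_v[V].append(_mean_loglik(p_te, yte))
        fold_cache.append(per_v)

    grid_scores: dict[tuple[float, int], float] = {}
    for V in config.variance_grid:
        for t in config.tuning_criteria:
            f_scores = []
            for per_v in fold_cache:
                p_tr, ytr, p_te, yte = per_v[V]
                theta = tune_threshold(p_tr, ytr, t, config.positive_class)
                m = evaluate(
                    yte,
                    scores=p_te,
                    positive_class=config.positive_class,
                    threshold=theta,
                )
                f_scores.append(m.f1)
            grid_scores[(V, t)] = float(np.mean(f_scores))

    best_v, best_t = min(
        grid_scores, key=lambda vt: (-grid_scores[vt], vt[0], vt[1])
    )

    means, scales = _standardization(X, config.standardize)
    Z = (X - means) / scales
    w, b = fit_map(
        Z, y, config.prior_type, best_v, tol=config.tol, max_iter=config.max_iter
    )
    p_all = _sigma_neg(-(Z @ w + b))
    theta = tune_threshold(p_all, y, best_t, config.positive_class)
    report = {
        "mean_heldout_f1": {f"{v:g}|{t}": s for (v, t), s in grid_scores.items()},
        "mean_heldout_loglik_per_V": {
            f"{v:g}": float(np.mean(ll)) for v, ll in loglik_per_v.items()
        },
        "selected": {"V": best_v, "t": best_t},
    }
    return BLRModel(
        weights=w,
        intercept=b,
        prior_type=config.prior_type,
        variance=best_v,
        criterion=best_t,
        threshold=theta,
        feature_names=[f"f{i}" for i in range(X.shape[1])],
        means=means,
        scales=scales,
        cv_report=report,
    )
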