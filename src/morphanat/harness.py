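"""Cross-validated prediction-evaluation harness.

Protocol: features are z-score standardized with statistics fitted on the
training fold only, models are evaluated by shuffled 10-fold
cross-validation, hyperparameters by exhaustive grid search over the CV
score, and performance is reported as accuracy / macro recall / macro
F-score / macro one-vs-rest AUC for classification and R^2 / MSE / MAE for
regression.  Any sklearn-style estimator (fit/predict, optionally
predict_proba) plugs in; two self-contained reference estimators — a
nearest-neighbor classifier and a closed-form ridge regressor — are built
in so the harness is testable end to end.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.metrics import accuracy_score, f1_score, recall_score
from sklearn.model_selection import KFold

__all__ = [
    "standardize",
    "kfold_split",
    "cross_validate",
    "grid_search",
    "classification_metrics",
    "regression_metrics",
    "CVResult",
    "NearestNeighborClassifier",
    "RidgeRegressor",
]


def standardize(
    features: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-column z-scores.

    With ``stats=None`` the mean/std are fitted on the given rows (training
    use); otherwise the provided training statistics are applied (test
    use).  Constant columns are passed through as zeros with a warning.
    """
    X = np.asarray(features, dtype=float)
    if stats is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        if (std < 1e-12).any():
            warnings.warn("constant feature column(s) standardized to zero",
                          UserWarning, stacklevel=2)
    else:
        mean, std = stats
    safe = np.where(std < 1e-12, 1.0, std)
    return (X - mean) / safe, (mean, std)


def kfold_split(n: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Shuffled partition of range(n) into k near-equal test folds."""
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.zeros(n))]


@dataclass
class CVResult:
    per_fold_metrics: list[dict[str, float]]
    mean_metrics: dict[str, float]
    sd_metrics: dict[str, float]
    seed: int
    best_params: dict | None = field(default=None)


class NearestNeighborClassifier(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbor majority-vote classifier (Euclidean distance).

    Reference estimator for the harness; ties in the vote and in distance
    are broken by the smaller class/row index, making it deterministic.
    """

    def __init__(self, n_neighbors: int = 1):
        self.n_neighbors = n_neighbors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestNeighborClassifier":
        self.X_ = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, self.y_idx_ = np.unique(y, return_inverse=True)
        return self

    def _vote(self, X: np.ndarray) -> np.ndarray:
        d = ((np.asarray(X, dtype=float)[:, None, :] - self.X_[None]) ** 2).sum(-1)
        nn = np.argsort(d, axis=1, kind="stable")[:, : self.n_neighbors]
        votes = np.zeros((len(X), len(self.classes_)))
        for j in range(nn.shape[1]):
            np.add.at(votes, (np.arange(len(X)), self.y_idx_[nn[:, j]]), 1.0)
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._vote(X), axis=1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        votes = self._vote(X)
        return votes / votes.sum(axis=1, keepdims=True)


class RidgeRegressor(BaseEstimator, RegressorMixin):
    """Closed-form ridge regression with unpenalized intercept."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        xm, ym = X.mean(axis=0), y.mean()
        Xc, yc = X - xm, y - ym
        p = X.shape[1]
        self.coef_ = np.linalg.solve(Xc.T @ Xc + self.alpha * np.eye(p), Xc.T @ yc)
        self.intercept_ = ym - xm @ self.coef_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def _binary_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest AUC via the Mann-Whitney rank statistic."""
    pos = truth.astype(bool)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_metrics(
    truth: np.ndarray, predicted: np.ndarray, scores: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> dict[str, float]:
    """Accuracy, macro recall, macro F-score and macro one-vs-rest AUC.

    ``scores`` is an n x n_classes score matrix (column order ``classes``);
    AUC is omitted when scores are absent.  Classes absent from the truth
    are excluded from the macro averages with a warning.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    present = np.unique(truth)
    if len(present) < 2:
        raise ValueError("need at least 2 classes in the truth labels")
    out = {
        "accuracy": float(accuracy_score(truth, predicted)),
        "recall": float(recall_score(truth, predicted, labels=present,
                                     average="macro", zero_division=0)),
        "f_score": float(f1_score(truth, predicted, labels=present,
                                  average="macro", zero_division=0)),
    }
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if classes is None:
            classes = present
        classes = np.asarray(classes)
        missing = [c for c in classes if c not in present]
        if missing:
            warnings.warn(f"classes absent from truth excluded from AUC: {missing}",
                          UserWarning, stacklevel=2)
        aucs = [
            _binary_auc(truth == c, scores[:, j])
            for j, c in enumerate(classes) if c in present
        ]
        out["auc"] = float(np.mean(aucs))
    return out


def regression_metrics(truth: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """R^2, MSE and MAE.  Zero-variance truth makes R^2 undefined; it is
    reported as 1.0 for a perfect fit and NaN otherwise, with a flag."""
    truth = np.asarray(truth, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if truth.shape != predicted.shape or truth.ndim != 1 or len(truth) < 2:
        raise ValueError("need aligned 1-d vectors with n >= 2")
    ss_res = float(((truth - predicted) ** 2).sum())
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    if ss_tot < 1e-30:
        r2 = 1.0 if ss_res < 1e-30 else float("nan")
        warnings.warn("zero-variance truth: R^2 undefined", UserWarning, stacklevel=2)
    else:
        r2 = 1.0 - ss_res / ss_tot
    return {
        "r2": r2,
        "mse": float(((truth - predicted) ** 2).mean()),
        "mae": float(np.abs(truth - predicted).mean()),
    }


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator,
    k: int = 10,
    seed: int = 0,
    task: str = "classification",
) -> CVResult:
    """k-fold cross-validation with per-fold standardization.

    Standardization statistics are fitted inside each training fold and
    applied to the held-out fold, so no test information leaks into the
    preprocessing.  Mean and standard deviation over folds are reported.
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = kfold_split(len(X), k=k, seed=seed)
    all_idx = np.arange(len(X))
    per_fold: list[dict[str, float]] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        Xtr, stats = standardize(X[train_idx])
        Xte, _ = standardize(X[test_idx], stats=stats)
        est = clone(estimator)
        try:
            est.fit(Xtr, y[train_idx])
            pred = est.predict(Xte)
        except Exception as exc:
            raise RuntimeError(f"estimator failed on fold {fi}: {exc}") from exc
        if task == "classification":
            scores = None
            classes = getattr(est, "classes_", None)
            if hasattr(est, "predict_proba"):
                scores = est.predict_proba(Xte)
            metrics = classification_metrics(y[test_idx], pred, scores, classes)
        else:
            metrics = regression_metrics(y[test_idx].astype(float), pred)
        per_fold.append(metrics)
    keys = per_fold[0].keys()
    mean = {kk: float(np.nanmean([f[kk] for f in per_fold])) for kk in keys}
    sd = {kk: float(np.nanstd([f[kk] for f in per_fold])) for kk in keys}
    return CVResult(per_fold_metrics=per_fold, mean_metrics=mean,
                    sd_metrics=sd, seed=seed)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator,
    param_grid: dict[str, list],
    k: int = 10,
    seed: int = 0,
    task: str = "classification",
) -> tuple[dict, CVResult]:
    """Exhaustive hyperparameter search by CV score.

    Best = max mean accuracy (classification) or min mean MSE (regression);
    ties are broken by first-in-grid order.  Returns (best params, its CV
    result with ``best_params`` set).
    """
    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("empty hyperparameter grid")
    names = list(param_grid)
    best: tuple[dict, CVResult] | None = None
    best_score = None
    for combo in itertools.product(*(param_grid[n] for n in names)):
        params = dict(zip(names, combo))
        est = clone(estimator).set_params(**params)
        result = cross_validate(X, y, est, k=k, seed=seed, task=task)
        score = (result.mean_metrics["accuracy"] if task == "classification"
                 else -result.mean_metrics["mse"])
        if best_score is None or score > best_score:  # strict: first wins ties
            best_score = score
            result.best_params = params
            best = (params, result)
    assert best is not None
    return best
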