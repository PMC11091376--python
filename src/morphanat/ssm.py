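"""Landmark statistical shape model.

A population of skull landmark configurations (m landmarks x 3 coordinates
per subject) is reduced by PCA, and the principal-component scores are
regressed on four centered body characteristics (gender, age, height, BMI):

    P = X_c A^T + eps

where P is the n x k score matrix, X_c the centered (optionally
unit-scaled) n x 4 characteristic matrix, A the k x 4 coefficient matrix
and eps the n x k residual matrix.  Because PC scores are mean-centered by
construction, centering the characteristics makes the intercept-free form
well-posed.  New landmark configurations are predicted as

    landmarks(x) = mean_shape + basis @ (A (x - x_bar) / s).

Rigid Procrustes alignment (rotation + translation removed, scale kept —
body size is signal) is available as a preprocessing mode; whether to align
is the caller's choice since size and pose conventions of the source data
vary.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .io import SubjectCharacteristics

__all__ = [
    "align_landmarks",
    "LandmarkShapeModel",
    "CharacteristicRegression",
    "fit_pca",
    "fit_characteristic_regression",
    "predict_landmarks",
    "sample_design_grid",
    "DEFAULT_RANGES",
    "DEFAULT_GRID_COUNTS",
]

#: default characteristic ranges for design-grid sampling
DEFAULT_RANGES = {"age": (10.0, 90.0), "height": (1.45, 1.95), "bmi": (15.0, 35.0)}
#: default level counts (age, height, bmi); with 2 genders -> 200 grid points
DEFAULT_GRID_COUNTS = (5, 5, 4)


def _rigid_fit(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best rigid (rotation + translation, no scaling) map source->target."""
    mu_s, mu_t = source.mean(axis=0), target.mean(axis=0)
    H = (source - mu_s).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return R, t


def align_landmarks(
    landmark_arrays: Sequence[np.ndarray], mode: str = "rigid_procrustes"
) -> tuple[list[np.ndarray], list[tuple[np.ndarray, np.ndarray]]]:
    """Rigidly superimpose landmark configurations (no scaling).

    ``mode='none'`` returns copies with identity transforms.  In
    ``'rigid_procrustes'`` mode every configuration is aligned to the
    iteratively re-estimated mean shape; only rotation and translation are
    removed, so centroid size differences (height/BMI signal) survive.

    Returns (aligned arrays, per-subject (R, t) with aligned = R x + t).
    """
    arrays = [np.asarray(a, dtype=float) for a in landmark_arrays]
    m = arrays[0].shape[0]
    if any(a.shape != (m, 3) for a in arrays):
        raise ValueError("all landmark arrays must share the same (m, 3) shape")
    if mode == "none":
        return [a.copy() for a in arrays], [
            (np.eye(3), np.zeros(3)) for _ in arrays
        ]
    if mode != "rigid_procrustes":
        raise ValueError(f"unknown alignment mode {mode!r}")
    for i, a in enumerate(arrays):
        if np.linalg.matrix_rank(a - a.mean(axis=0), tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
            raise ValueError(f"landmark configuration {i} is collinear; rotation ill-posed")
    reference = arrays[0] - arrays[0].mean(axis=0)
    aligned = arrays
    transforms: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(5):
        transforms = []
        aligned = []
        for a in arrays:
            R, t = _rigid_fit(a, reference)
            aligned.append(a @ R.T + t)
            transforms.append((R, t))
        new_ref = np.mean(aligned, axis=0)
        new_ref -= new_ref.mean(axis=0)
        if np.linalg.norm(new_ref - reference) < 1e-12 * max(1.0, np.linalg.norm(reference)):
            reference = new_ref
            break
        reference = new_ref
    return aligned, transforms


class LandmarkShapeModel(BaseEstimator):
    """PCA shape model of stacked landmark coordinates.

    Parameters
    ----------
    n_components : int, default 40
        Number of retained principal components k; must satisfy
        k <= min(n_subjects - 1, 3 m).
    align : {'rigid_procrustes', 'none'}, default 'rigid_procrustes'
        Alignment applied to the training configurations before PCA.

    Attributes (after ``fit``)
    --------------------------
    mean_shape_ : (3m,) mean landmark vector
    basis_ : (3m, k) orthonormal component matrix
    scores_ : (n, k) training scores (column means zero)
    explained_variance_ : (k,) non-increasing variance spectrum
    """

    def __init__(self, n_components: int = 40, align: str = "rigid_procrustes"):
        self.n_components = n_components
        self.align = align

    def fit(self, landmark_arrays: Sequence[np.ndarray]) -> "LandmarkShapeModel":
        arrays, _ = align_landmarks(landmark_arrays, mode=self.align)
        n = len(arrays)
        m = arrays[0].shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        k = self.n_components
        if not 1 <= k <= min(n - 1, 3 * m):
            raise ValueError(
                f"n_components={k} outside [1, min(n-1, 3m)] = [1, {min(n - 1, 3 * m)}]"
            )
        X = np.stack([a.ravel() for a in arrays])  # n x 3m
        pca = PCA(n_components=k, svd_solver="full")
        self.scores_ = pca.fit_transform(X)
        self.mean_shape_ = pca.mean_
        self.basis_ = pca.components_.T  # 3m x k
        self.explained_variance_ = pca.explained_variance_
        self.n_subjects_ = n
        self.n_landmarks_ = m
        return self

    def transform(self, landmark_arrays: Sequence[np.ndarray]) -> np.ndarray:
        X = np.stack([np.asarray(a, dtype=float).ravel() for a in landmark_arrays])
        return (X - self.mean_shape_) @ self.basis_

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Scores -> landmark arrays, shape (n, m, 3)."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        flat = self.mean_shape_ + scores @ self.basis_.T
        return flat.reshape(len(scores), self.n_landmarks_, 3)

    def reconstruction_error(self, landmark_arrays: Sequence[np.ndarray]) -> float:
        X = np.stack([np.asarray(a, dtype=float).ravel() for a in landmark_arrays])
        recon = self.mean_shape_ + self.transform(landmark_arrays) @ self.basis_.T
        return float(np.abs(X - recon).max())


class CharacteristicRegression(BaseEstimator):
    """Least-squares regression of PC scores on body characteristics.

    Characteristics are centered on the training mean and (by default)
    scaled to unit standard deviation before the per-component
    least-squares solve; ``coef_`` is the k x 4 matrix A acting on the
    centered/scaled characteristics.  ``raw_coef_`` undoes the scaling so
    it acts on raw characteristic units directly.
    """

    CHARACTERISTIC_NAMES = ("gender", "age", "height", "bmi")

    def __init__(self, scale: bool = True):
        self.scale = scale

    def fit(self, model: LandmarkShapeModel, characteristics: np.ndarray) -> "CharacteristicRegression":
        scores = model.scores_
        X = np.asarray(characteristics, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("characteristics must be n x 4 (gender, age, height, bmi)")
        n = X.shape[0]
        if n != scores.shape[0]:
            raise ValueError("characteristic rows must align with model scores")
        if n <= 4:
            raise ValueError("need more than 4 subjects to fit 4 coefficients")
        self.characteristic_means_ = X.mean(axis=0)
        stds = X.std(axis=0, ddof=0)
        for j, s in enumerate(stds):
            if s < 1e-12:
                raise ValueError(
                    f"characteristic column {self.CHARACTERISTIC_NAMES[j]!r} is "
                    "constant; regression is rank-deficient"
                )
        self.characteristic_scales_ = stds if self.scale else np.ones(4)
        Xc = (X - self.characteristic_means_) / self.characteristic_scales_
        if np.linalg.matrix_rank(Xc) < 4:
            raise ValueError("characteristic matrix is rank-deficient")
        coef, *_ = np.linalg.lstsq(Xc, scores, rcond=None)
        self.coef_ = coef.T  # k x 4
        fitted = Xc @ coef
        self.residuals_ = scores - fitted
        ss_res = (self.residuals_ ** 2).sum(axis=0)
        ss_tot = ((scores - scores.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - ss_res / ss_tot
        self.fit_r2_ = np.where(ss_tot < 1e-30, 1.0, r2)
        self._train_min = X.min(axis=0)
        self._train_max = X.max(axis=0)
        return self

    @property
    def raw_coef_(self) -> np.ndarray:
        """Coefficients on raw characteristic units (chain rule)."""
        return self.coef_ / self.characteristic_scales_[None, :]

    def predict_scores(self, characteristics: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(characteristics, dtype=float))
        outside = (X < self._train_min) | (X > self._train_max)
        if outside.any():
            cols = [self.CHARACTERISTIC_NAMES[j] for j in np.where(outside.any(axis=0))[0]]
            warnings.warn(
                f"characteristics outside training range for {cols}; extrapolating",
                UserWarning,
                stacklevel=2,
            )
        Xc = (X - self.characteristic_means_) / self.characteristic_scales_
        return Xc @ self.coef_.T


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_pca(
    landmark_arrays: Sequence[np.ndarray], k: int, align: str = "none"
) -> LandmarkShapeModel:
    """Fit a :class:`LandmarkShapeModel` on pre-aligned arrays."""
    return LandmarkShapeModel(n_components=k, align=align).fit(landmark_arrays)


def fit_characteristic_regression(
    model: LandmarkShapeModel, characteristics: np.ndarray, scale: bool = True
) -> CharacteristicRegression:
    return CharacteristicRegression(scale=scale).fit(model, characteristics)


def predict_landmarks(
    model: LandmarkShapeModel,
    regression: CharacteristicRegression,
    chars: SubjectCharacteristics | np.ndarray,
) -> np.ndarray:
    """Predict an m x 3 landmark configuration for one subject."""
    if isinstance(chars, SubjectCharacteristics):
        chars = chars.as_array()
    scores = regression.predict_scores(chars)
    return model.inverse_transform(scores)[0]


def sample_design_grid(
    ranges: dict[str, tuple[float, float]] | None = None,
    counts: tuple[int, int, int] | None = None,
    gender_levels: Sequence[int] = (0, 1),
    total: int | None = None,
) -> list[SubjectCharacteristics]:
    """Full-factorial characteristic grid to homogenize the design space.

    Levels are evenly spaced over each range (endpoints included); a
    single-level axis sits at the range midpoint.  The default
    2 genders x 5 ages x 5 heights x 4 BMIs layout yields 200 points.
    """
    ranges = dict(DEFAULT_RANGES, **(ranges or {}))
    counts = counts or DEFAULT_GRID_COUNTS
    if any(c < 1 for c in counts):
        raise ValueError("counts must be >= 1 per axis")
    n_points = len(gender_levels) * int(np.prod(counts))
    if total is not None and n_points != total:
        g = len(gender_levels)
        per_gender = total // g if total % g == 0 else None
        options = []
        if per_gender:
            for a, h in itertools.product(range(1, per_gender + 1), repeat=2):
                if per_gender % (a * h) == 0:
                    options.append((a, h, per_gender // (a * h)))
        raise ValueError(
            f"counts {counts} x {g} genders give {n_points} points, not {total}; "
            f"valid (age, height, bmi) factorizations: {options[:20]}"
        )

    def levels(lo: float, hi: float, c: int) -> np.ndarray:
        return np.array([(lo + hi) / 2.0]) if c == 1 else np.linspace(lo, hi, c)

    ages = levels(*ranges["age"], counts[0])
    heights = levels(*ranges["height"], counts[1])
    bmis = levels(*ranges["bmi"], counts[2])
    return [
        SubjectCharacteristics(gender=int(g), age=float(a), height=float(h), bmi=float(b))
        for g, a, h, b in itertools.product(gender_levels, ages, heights, bmis)
    ]
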