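"""Thin-plate-spline (radial basis function) mesh morphing.

The interpolant from m source landmarks s_i to targets t_i is

    f(x) = c + B x + sum_i w_i * phi(||x - s_i||),    phi(r) = r,

the standard 3-D biharmonic/TPS kernel, with the side conditions
sum_i w_i = 0 and sum_i w_i s_i^T = 0 that make the radial part orthogonal
to affine functions.  With regularization lambda = 0 the map interpolates
the landmarks exactly and reproduces any affine map exactly (w = 0); with
lambda > 0 the landmark fit is smoothed.

One global field morphs every node of the coupled skull+brain mesh, so the
brain geometry follows the skull landmarks; connectivity and ids are
untouched.  m is of order 69, so a dense symmetric solve is appropriate.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .io import FEMesh

logger = logging.getLogger(__name__)

__all__ = ["ThinPlateSpline", "solve_tps", "apply_tps", "morph_mesh"]


class ThinPlateSpline(BaseEstimator):
    """3-D thin-plate-spline transform, sklearn-style.

    Parameters
    ----------
    regularization : float, default 0.0
        Smoothing weight lambda added to the kernel matrix diagonal;
        0 gives exact landmark interpolation.

    Attributes (after ``fit``)
    --------------------------
    source_landmarks_ : (m, 3) source landmark array
    radial_weights_ : (m, 3) kernel weights w (columns sum to zero)
    affine_ : (3, 3) matrix B of the affine part
    translation_ : (3,) vector c of the affine part
    condition_number_ : condition number of the interpolation system
    """

    kernel = "biharmonic-3d"

    def __init__(self, regularization: float = 0.0):
        self.regularization = regularization

    def fit(self, source: np.ndarray, target: np.ndarray) -> "ThinPlateSpline":
        source = np.asarray(source, dtype=float)
        target = np.asarray(target, dtype=float)
        if source.ndim != 2 or source.shape[1] != 3:
            raise ValueError("source landmarks must be m x 3")
        if source.shape != target.shape:
            raise ValueError("source and target landmark arrays must share shape")
        m = source.shape[0]
        if m < 4:
            raise ValueError("need at least 4 landmarks")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

        D = cdist(source, source)
        dup = np.argwhere(np.triu(D < 1e-12, k=1))
        if len(dup):
            i, j = dup[0]
            raise np.linalg.LinAlgError(
                f"duplicate source landmarks at rows {i} and {j}; TPS system singular"
            )
        centered = source - source.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 3:
            raise np.linalg.LinAlgError(
                "source landmarks are coplanar; affine part under-determined"
            )

        K = D + self.regularization * np.eye(m)
        P = np.hstack([np.ones((m, 1)), source])
        A = np.zeros((m + 4, m + 4))
        A[:m, :m] = K
        A[:m, m:] = P
        A[m:, :m] = P.T
        rhs = np.zeros((m + 4, 3))
        rhs[:m] = target
        self.condition_number_ = float(np.linalg.cond(A))
        if self.condition_number_ > 1e12:
            logger.warning("TPS system ill-conditioned (cond=%.3g)", self.condition_number_)
        sol = np.linalg.solve(A, rhs)
        self.radial_weights_ = sol[:m]
        self.translation_ = sol[m]
        self.affine_ = sol[m + 1 :].T  # rows of sol are x,y,z coefficients
        self.source_landmarks_ = source.copy()
        return self

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != 3:
            raise ValueError("points must be p x 3")
        radial = cdist(points, self.source_landmarks_) @ self.radial_weights_
        return self.translation_ + points @ self.affine_.T + radial

    def landmark_residual(self, target: np.ndarray) -> float:
        """Max landmark misfit in mm (0 for lambda = 0 up to round-off)."""
        return float(
            np.linalg.norm(self.transform(self.source_landmarks_) - target, axis=1).max()
        )


def solve_tps(source: np.ndarray, target: np.ndarray, regularization: float = 0.0) -> ThinPlateSpline:
    """Solve the TPS interpolation problem source -> target."""
    return ThinPlateSpline(regularization=regularization).fit(source, target)


def apply_tps(transform: ThinPlateSpline, points: np.ndarray) -> np.ndarray:
    return transform.transform(points)


def morph_mesh(
    baseline: FEMesh, target_landmarks: np.ndarray, regularization: float = 0.0
) -> FEMesh:
    """Morph every node of the baseline mesh by one global TPS field.

    The TPS is solved from the baseline's landmark node positions to
    ``target_landmarks`` (row order must match the mesh landmark set) and
    applied to skull and brain nodes alike; connectivity, ids and part
    labels are preserved byte-identically.
    """
    target_landmarks = np.asarray(target_landmarks, dtype=float)
    m = len(baseline.landmark_set)
    if m == 0:
        raise ValueError("baseline mesh has no landmark set")
    if target_landmarks.shape != (m, 3):
        raise ValueError(
            f"target landmarks shape {target_landmarks.shape} != ({m}, 3)"
        )
    tps = solve_tps(baseline.landmark_coords, target_landmarks, regularization)
    return baseline.with_coords(tps.transform(baseline.node_coords))
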