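"""Rigid (rotation + translation) transforms and least-squares fitting.

Form analysis keeps size, so nothing in this module ever scales. Rotations
are proper (det = +1): a reflection would turn a right face into a left one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateGeometryError, ValidationError

__all__ = ["RigidTransform", "kabsch_pair", "centroid_size"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in mm coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValidationError("rotation is not orthonormal to 1e-9")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation has det -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of points."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def centroid_size(points: np.ndarray) -> float:
    """Root summed squared distance of points from their centroid (mm)."""
    P = np.asarray(points, dtype=float)
    return float(np.sqrt(((P - P.mean(axis=0)) ** 2).sum()))


def kabsch_pair(X: np.ndarray, Y: np.ndarray, *, allow_degenerate: bool = False) -> RigidTransform:
    """Least-squares proper rigid transform mapping point set X onto Y.

    Solves ``argmin_{R,t} sum_i ||R x_i + t - y_i||^2`` over rotations with
    det +1 (Kabsch/Umeyama without scaling). Point sets must be in
    one-to-one row correspondence.

    Parameters
    ----------
    X, Y : (N, 3) arrays, N >= 3.
    allow_degenerate : skip the collinearity check (used internally where
        the caller guarantees rank).

    Raises
    ------
    DegenerateGeometryError
        If the source points are collinear, leaving the rotation about the
        common axis undetermined.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValidationError(f"need matching (N>=3, 3) point sets, got {X.shape} and {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if not allow_degenerate:
        sv = np.linalg.svd(Xc, compute_uv=False)
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            raise DegenerateGeometryError("source points are (near-)collinear; rotation underdetermined")
    H = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Y.mean(axis=0) - R @ X.mean(axis=0)
    return RigidTransform(R, t)
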