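"""Dense correspondence: landmark pre-alignment, CPD registration, projection, pruning.

Raw surface scans carry arbitrary meshings, so vertex indices mean nothing
across scans. This module makes them mean something: an arbitrarily chosen
base (template) mesh is rigidly pre-aligned to each target scan using the
nine landmarks, deformed onto it by coherent point drift (CPD) non-rigid
registration, and its vertices are then snapped onto the target surface by
exact closest-point projection. The result is one quasi-landmark
configuration per scan with a shared vertex count and ordering. Vertices
that project far off-surface in *any* scan (holes, trimmed regions) are
pruned from the whole dataset so homology is preserved.

CPD here is the standard non-rigid formulation: the base points are
Gaussian-mixture centroids displaced by a field ``v(y) = sum_j G(y, y_j) w_j``
with Gaussian kernel ``G`` of width `beta`; EM alternates soft assignment
of targets to centroids (with a uniform outlier component of weight `w`)
and a ridge-regularised linear solve for the kernel weights, while the
mixture variance sigma^2 anneals toward the residual noise level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import DegenerateGeometryError, ValidationError
from .geometry import project_to_surface
from .mesh_io import LandmarkSet, LongitudinalSeries, SpecimenRecord, TriangleMesh
from .rigid import RigidTransform, kabsch_pair

__all__ = [
    "CpdParams",
    "CpdResult",
    "CorrespondedSample",
    "CorrespondenceResult",
    "rigid_prealign",
    "cpd_nonrigid",
    "prune_vertices",
    "build_correspondence",
]


@dataclass(frozen=True)
class CpdParams:
    """Hyper-parameters of non-rigid CPD.

    beta : Gaussian kernel width in mm (smoothness scale of the
        displacement field). `from_points` sets it to ``beta_rel`` times the
        base mesh bounding-box diagonal (default 0.1).
    lam : ridge weight on the kernel coefficients (higher = stiffer field).
    w : prior outlier fraction in [0, 1).
    max_iter, tol : EM stopping — relative change of sigma^2 below `tol`
        or `max_iter` iterations.
    low_rank_threshold / low_rank_k : above this base vertex count the
        kernel is replaced by its top-K eigenpair approximation.
    """

    beta: float
    lam: float = 10.0
    w: float = 0.1
    max_iter: int = 150
    tol: float = 1e-5
    low_rank_threshold: int = 5000
    low_rank_k: int = 100

    def __post_init__(self) -> None:
        if not (self.beta > 0 and self.lam > 0 and 0 <= self.w < 1
                and self.max_iter >= 1 and self.tol > 0):
            raise ValidationError("invalid CPD parameters")

    @staticmethod
    def from_points(base_points: np.ndarray, *, beta_rel: float = 0.1, **kwargs) -> "CpdParams":
        P = np.asarray(base_points, dtype=float)
        diag = float(np.linalg.norm(P.max(axis=0) - P.min(axis=0)))
        return CpdParams(beta=beta_rel * diag, **kwargs)


@dataclass
class CpdResult:
    displaced: np.ndarray
    sigma2: float
    n_iter: int
    converged: bool


@dataclass
class CorrespondedSample:
    """Quasi-landmark configuration of one scan (shared V across a dataset)."""

    subject_id: str
    age: float
    sex: str
    points: np.ndarray                  # (V, 3) mm, in the scan's own frame
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (len(self.points),):
                raise ValidationError("valid_mask length mismatch")
            if not np.isfinite(self.points[self.valid_mask]).all():
                raise ValidationError("non-finite corresponded point inside mask")


@dataclass
class CorrespondenceResult:
    """Output of the dataset-wide correspondence pipeline."""

    samples: list[CorrespondedSample]
    mask: np.ndarray                     # shared (V,) retained-vertex mask
    base_mesh: TriangleMesh
    base_index: int
    projection_distances: np.ndarray     # (n_samples, V) mm


def rigid_prealign(src: LandmarkSet, dst: LandmarkSet) -> RigidTransform:
    """Least-squares rigid transform taking `src` landmarks onto `dst`.

    Landmarks are matched by name. No scaling. Raises
    DegenerateGeometryError when the source landmarks are collinear.
    """
    return kabsch_pair(src.as_array(), dst.as_array())


def _gaussian_kernel(Y: np.ndarray, beta: float) -> np.ndarray:
    return np.exp(-cdist(Y, Y, "sqeuclidean") / (2.0 * beta * beta))


def _kernel_eigs(Y: np.ndarray, beta: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of the Gaussian kernel without densifying when huge."""
    from scipy.sparse.linalg import LinearOperator, eigsh

    V = len(Y)
    if V <= 8000:
        G = _gaussian_kernel(Y, beta)
        vals, vecs = eigsh(G, k=min(k, V - 1))
    else:
        b2 = 2.0 * beta * beta

        def matvec(x):
            out = np.empty(V)
            for s in range(0, V, 1024):
                block = np.exp(-cdist(Y[s:s + 1024], Y, "sqeuclidean") / b2)
                out[s:s + 1024] = block @ x
            return out

        op = LinearOperator((V, V), matvec=matvec, dtype=float)
        vals, vecs = eigsh(op, k=k)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def cpd_nonrigid(base_points: np.ndarray, target_points: np.ndarray,
                 params: CpdParams | None = None) -> CpdResult:
    """Register `base_points` onto `target_points` by non-rigid CPD.

    Both clouds should be rigidly pre-aligned. Returns the displaced base
    points together with the final mixture variance and iteration count.
    Non-convergence within `max_iter` returns the last iterate with
    ``converged=False`` and a warning; sigma^2 collapsing to machine
    tolerance stops early (exact overlap).
    """
    Y = np.asarray(base_points, dtype=float)
    X = np.asarray(target_points, dtype=float)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[1] != 3 or X.shape[1] != 3:
        raise ValidationError("point clouds must be (N, 3)")
    if len(Y) < 4 or len(X) < 4:
        raise ValidationError("need at least 4 points per cloud")
    if params is None:
        params = CpdParams.from_points(Y)
    M, N = len(Y), len(X)
    beta, lam, w = params.beta, params.lam, params.w

    low_rank = M > params.low_rank_threshold
    if low_rank:
        evals, Q = _kernel_eigs(Y, beta, params.low_rank_k)
        evals = np.clip(evals, 1e-12, None)
    else:
        G = _gaussian_kernel(Y, beta)

    scale2 = float(((X - X.mean(0)) ** 2).sum() / N + ((Y - Y.mean(0)) ** 2).sum() / M)
    sigma2_floor = 1e-12 * max(scale2, 1.0)
    T = Y.copy()
    # standard initialisation: average squared distance between the clouds
    sigma2 = float(cdist(Y, X, "sqeuclidean").sum() / (3.0 * M * N))
    W_coef = np.zeros((M, 3))
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        # E-step: posterior responsibilities with uniform outlier component
        D2 = cdist(T, X, "sqeuclidean")
        P = np.exp(-D2 / (2.0 * sigma2))
        c = (2.0 * np.pi * sigma2) ** 1.5 * (w / max(1.0 - w, 1e-12)) * (M / N)
        den = P.sum(axis=0) + c
        den[den < 1e-300] = 1e-300
        P /= den
        P1 = P.sum(axis=1)                       # (M,)
        Np = P1.sum()
        PX = P @ X

        # M-step: solve (diag(P1) G + lam sigma2 I) W = PX - diag(P1) Y
        rhs = PX - P1[:, None] * Y
        csig = lam * sigma2
        if low_rank:
            # Woodbury with G ~ Q diag(evals) Q^T
            DQ = P1[:, None] * Q
            K = np.diag(csig / evals) + Q.T * P1 @ Q
            W_coef = (rhs - DQ @ np.linalg.solve(K, Q.T @ rhs)) / csig
            GW = Q @ (evals[:, None] * (Q.T @ W_coef))
        else:
            A = P1[:, None] * G + csig * np.eye(M)
            W_coef = np.linalg.solve(A, rhs)
            GW = G @ W_coef
        T = Y + GW

        # sigma^2 update from the weighted residuals
        xPx = float((P.sum(axis=0) * (X * X).sum(axis=1)).sum())
        trPXT = float((PX * T).sum())  # note: PX uses old P but new T, standard CPD update
        tTT = float((P1 * (T * T).sum(axis=1)).sum())
        sigma2_new = (xPx - 2.0 * trPXT + tTT) / (3.0 * Np)
        sigma2_new = max(sigma2_new, sigma2_floor)
        rel = abs(sigma2 - sigma2_new) / max(sigma2, 1e-300)
        sigma2 = sigma2_new
        if sigma2 <= sigma2_floor:
            converged = True
            break
        if rel < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"CPD did not converge in {params.max_iter} iterations "
                      f"(sigma2={sigma2:.3g}); returning best iterate", stacklevel=2)
    return CpdResult(displaced=T, sigma2=sigma2, n_iter=it, converged=converged)


def prune_vertices(distances: np.ndarray, thresholds: np.ndarray | float,
                   *, max_prune_fraction: float = 0.5) -> np.ndarray:
    """Dataset-wide retained-vertex mask from per-scan projection distances.

    A vertex is discarded for the *whole* dataset when its projection
    distance exceeds the scan's threshold in any single scan — homology
    demands uniform removal. `distances` is (n_samples, V); `thresholds`
    is a scalar or per-sample vector, conventionally
    ``k * median edge length`` of each target mesh (default k = 3).

    Raises ValidationError if more than `max_prune_fraction` of vertices
    would be removed (a sign the registration failed outright).
    """
    D = np.atleast_2d(np.asarray(distances, dtype=float))
    thr = np.broadcast_to(np.asarray(thresholds, dtype=float).reshape(-1, 1)
                          if np.ndim(thresholds) else np.float64(thresholds), D.shape)
    mask = ~(D > thr).any(axis=0)
    frac = 1.0 - mask.mean()
    if frac > max_prune_fraction:
        raise ValidationError(
            f"pruning would remove {frac:.1%} of vertices (> {max_prune_fraction:.0%}); "
            "check registration quality or the pruning threshold"
        )
    return mask


def build_correspondence(series_list: list[LongitudinalSeries],
                         base_choice: int = 0,
                         cpd: CpdParams | None = None,
                         *, prune_k: float = 3.0,
                         beta_rel: float = 0.1) -> CorrespondenceResult:
    """Run the full correspondence pipeline over a dataset.

    Per specimen: rigidly pre-align the base mesh (specimen `base_choice`
    in flattened series order) to the specimen via landmarks, CPD-register
    the base vertices to the specimen's vertices, project onto the
    specimen's surface. Then prune vertices whose projection distance
    exceeds ``prune_k`` times the target's median edge length in any scan.

    Output order matches flattened input order; all samples share the base
    mesh's vertex count.
    """
    specimens: list[SpecimenRecord] = [r for s in series_list for r in s.records]
    if not specimens:
        raise ValidationError("empty dataset")
    if not (0 <= base_choice < len(specimens)):
        raise ValidationError(f"base_choice {base_choice} outside [0, {len(specimens)})")
    base = specimens[base_choice]
    base_vertices = base.mesh.vertices
    if cpd is None:
        cpd = CpdParams.from_points(base_vertices, beta_rel=beta_rel)

    samples: list[CorrespondedSample] = []
    distances = np.empty((len(specimens), len(base_vertices)))
    thresholds = np.empty(len(specimens))
    for i, specimen in enumerate(specimens):
        try:
            pre = rigid_prealign(base.landmarks, specimen.landmarks)
            moved = pre.apply(base_vertices)
            reg = cpd_nonrigid(moved, specimen.mesh.vertices, cpd)
            projected, dist, _ = project_to_surface(reg.displaced, specimen.mesh)
        except Exception as exc:
            raise type(exc)(
                f"correspondence failed for subject {specimen.subject_id} "
                f"age {specimen.age}: {exc}"
            ) from exc
        distances[i] = dist
        thresholds[i] = prune_k * specimen.mesh.median_edge_length()
        samples.append(CorrespondedSample(specimen.subject_id, specimen.age,
                                          specimen.sex, projected))

    mask = prune_vertices(distances, thresholds)
    for s in samples:
        s.valid_mask = mask.copy()
    return CorrespondenceResult(samples=samples, mask=mask, base_mesh=base.mesh,
                                base_index=base_choice, projection_distances=distances)
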