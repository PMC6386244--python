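"""Generalized Procrustes superimposition and the per-sex PCA form space.

Alignment is *rigid only* — no scaling step — so size differences between
ages are retained and the PCA operates on form, not shape. (Growing faces
are mostly getting bigger; removing size would discard the signal of
interest.) A `shape_mode` flag enables the classical unit-size scaling for
exploration.

The PCA is computed in snapshot space (n samples × 3V coordinates with
n ≪ 3V) via the thin SVD of the centred data matrix; eigenvalues equal
those of the full 3V × 3V sample covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .correspondence import CorrespondedSample
from .exceptions import ValidationError
from .rigid import RigidTransform, centroid_size, kabsch_pair

__all__ = [
    "AlignedSample",
    "ShapeSpace",
    "ScoreVector",
    "kabsch_pair",
    "gpa_align",
    "fit_pca",
    "to_scores",
    "from_scores",
    "save_space",
    "load_space",
]


@dataclass
class AlignedSample:
    """One specimen after GPA, restricted to the retained (masked-in) vertices."""

    subject_id: str
    age: float
    sex: str
    points: np.ndarray            # (Vr, 3) mm, aligned to the consensus


@dataclass
class ShapeSpace:
    """Per-sex PCA form space: mean form + orthonormal basis in R^(3Vr)."""

    mean_form: np.ndarray         # (3Vr,)
    basis: np.ndarray             # (3Vr, K), orthonormal columns
    eigenvalues: np.ndarray       # (K,), non-increasing
    explained_fraction: np.ndarray
    sex: str
    n_samples: int

    def __post_init__(self) -> None:
        B = self.basis
        if not np.allclose(B.T @ B, np.eye(B.shape[1]), atol=1e-9):
            raise ValidationError("basis columns not orthonormal to 1e-9")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValidationError("eigenvalues not sorted descending")

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    @property
    def n_vertices(self) -> int:
        return len(self.mean_form) // 3


@dataclass
class ScoreVector:
    subject_id: str
    age: float
    scores: np.ndarray            # (K,)


def _masked_points(sample, mask: np.ndarray | None) -> np.ndarray:
    pts = sample.points
    if mask is not None:
        pts = pts[mask]
    return np.asarray(pts, dtype=float)


def gpa_align(samples: list, mask: np.ndarray | None = None, *,
              shape_mode: bool = False, tol: float = 1e-7, max_iter: int = 100,
              ) -> tuple[list[AlignedSample], np.ndarray]:
    """Generalized Procrustes superimposition of corresponded samples.

    All configurations are translated to centroid origin, then iteratively
    rotated onto the evolving consensus (arithmetic mean), which is
    initialised from the first sample; iteration stops when the consensus
    moves less than `tol` mm RMS or after `max_iter` rounds. With
    `shape_mode=False` (the default, form analysis) centroid sizes are
    left untouched.

    Masked-out vertices are excluded from both fitting and output.
    Returns the aligned samples and the consensus configuration.
    """
    if len(samples) < 2:
        raise ValidationError("GPA needs at least 2 samples")
    if mask is None:
        mask = getattr(samples[0], "valid_mask", None)
    pts = [_masked_points(s, mask) for s in samples]
    V = {p.shape for p in pts}
    if len(V) != 1:
        raise ValidationError(f"inconsistent point shapes: {V}")

    X = [p - p.mean(axis=0) for p in pts]
    if shape_mode:
        X = [p / centroid_size(p) for p in X]
    consensus = X[0].copy()
    converged = False
    for _ in range(max_iter):
        for i in range(len(X)):
            R = kabsch_pair(X[i], consensus, allow_degenerate=True)
            X[i] = R.apply(X[i])
        new = np.mean(X, axis=0)
        change = float(np.sqrt(((new - consensus) ** 2).mean()))
        consensus = new
        if change < tol:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn("GPA did not converge; returning last iterate", stacklevel=2)
    aligned = [AlignedSample(s.subject_id, s.age, s.sex, x) for s, x in zip(samples, X)]
    return aligned, consensus


def fit_pca(aligned: list[AlignedSample], variance_target: float = 0.95,
            sex: str | None = None) -> ShapeSpace:
    """Fit the PCA form space of a set of aligned samples.

    Computed in snapshot space: the thin SVD of the centred n × 3V data
    matrix gives eigenvalues ``s^2 / (n - 1)`` of the sample covariance.
    K is the smallest component count whose cumulative explained variance
    reaches `variance_target`, capped at n − 1. Training scores have zero
    mean per component by construction.
    """
    n = len(aligned)
    if n < 3:
        raise ValidationError("PCA needs at least 3 samples")
    if sex is None:
        sexes = {s.sex for s in aligned}
        sex = sexes.pop() if len(sexes) == 1 else "mixed"
    X = np.stack([s.points.reshape(-1) for s in aligned])    # (n, 3V)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = svals ** 2 / (n - 1)
    total = eigvals.sum()
    if total <= 0:
        raise ValidationError("zero total variance: all samples identical")
    frac = eigvals / total
    cum = np.cumsum(frac)
    K = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    K = min(K, n - 1)
    return ShapeSpace(mean_form=mean, basis=Vt[:K].T, eigenvalues=eigvals[:K],
                      explained_fraction=frac[:K], sex=sex, n_samples=n)


def to_scores(sample: AlignedSample | np.ndarray, space: ShapeSpace) -> ScoreVector | np.ndarray:
    """Project a sample (or raw (V,3)/(3V,) array) into PC-score space."""
    if isinstance(sample, AlignedSample):
        s = space.basis.T @ (sample.points.reshape(-1) - space.mean_form)
        return ScoreVector(sample.subject_id, sample.age, s)
    x = np.asarray(sample, dtype=float).reshape(-1)
    if x.shape != space.mean_form.shape:
        raise ValidationError(f"dimension mismatch: {x.shape} vs {space.mean_form.shape}")
    return space.basis.T @ (x - space.mean_form)


def from_scores(scores: ScoreVector | np.ndarray, space: ShapeSpace) -> np.ndarray:
    """Reconstruct (V, 3) vertex coordinates from PC scores."""
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    if s.shape != (space.n_components,):
        raise ValidationError(f"expected {space.n_components} scores, got {s.shape}")
    return (space.mean_form + space.basis @ s).reshape(-1, 3)


def orient_by_age(space: ShapeSpace, aligned: list[AlignedSample]) -> ShapeSpace:
    """Flip PC signs so each component's training scores correlate
    positively with age (older faces toward positive PC values). A
    component uncorrelated with age keeps its largest-magnitude loading
    positive instead. Purely a sign convention; spans are unchanged."""
    ages = np.array([s.age for s in aligned])
    S = np.stack([to_scores(s, space).scores for s in aligned])   # (n, K)
    basis = space.basis.copy()
    ac = ages - ages.mean()
    for k in range(space.n_components):
        c = float(S[:, k] @ ac)
        if abs(c) > 1e-12 * (np.abs(S[:, k]).max() + 1e-300):
            flip = c < 0
        else:
            flip = basis[np.argmax(np.abs(basis[:, k])), k] < 0
        if flip:
            basis[:, k] = -basis[:, k]
    return ShapeSpace(space.mean_form, basis, space.eigenvalues,
                      space.explained_fraction, space.sex, space.n_samples)


def save_space(space: ShapeSpace, path: str | Path) -> None:
    """Serialize to <path>.npz plus a JSON sidecar with the summary."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), mean_form=space.mean_form, basis=space.basis,
             eigenvalues=space.eigenvalues, explained_fraction=space.explained_fraction)
    meta = {"sex": space.sex, "n_samples": space.n_samples,
            "n_components": space.n_components,
            "explained_fraction": [float(f) for f in space.explained_fraction]}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")


def load_space(path: str | Path) -> ShapeSpace:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ShapeSpace(mean_form=data["mean_form"], basis=data["basis"],
                      eigenvalues=data["eigenvalues"],
                      explained_fraction=data["explained_fraction"],
                      sex=meta["sex"], n_samples=meta["n_samples"])
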