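"""Year-to-year growth maps: motion vectors, magnitudes, Hotelling's T² significance.

For a transition age_a → age_b, every subject scanned at both ages
contributes one 3-D displacement ("motion vector") per quasi-landmark.
The mean magnitude map shows how far each point of the face moves in that
year; the significance map asks, per vertex, whether the mean motion
vector differs from zero using a one-sample Hotelling's T² test
(p = 3 coordinates), converted to an F statistic on (p, n − p) degrees of
freedom. p-values are thresholded at alpha per vertex with no
multiple-testing correction by default (a Benjamini–Hochberg option is
available but off).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .mesh_io import TriangleMesh, write_mesh
from .shape_space import AlignedSample

__all__ = [
    "MotionVectorSet",
    "VertexStatMap",
    "motion_vectors",
    "hotelling_map",
    "export_map",
    "read_map_colors",
]


@dataclass
class MotionVectorSet:
    """Per-subject vertex displacements for one age transition."""

    age_a: float
    age_b: float
    subject_ids: list[str]
    displacements: np.ndarray      # (n, V, 3) mm

    @property
    def n(self) -> int:
        return len(self.subject_ids)


@dataclass
class VertexStatMap:
    """Per-vertex mean motion magnitude and significance for one transition."""

    mean_magnitude: np.ndarray     # (V,) mm
    p_value: np.ndarray            # (V,) in [0, 1]
    significant: np.ndarray        # (V,) bool, p < alpha
    alpha: float
    mean_vector: np.ndarray | None = None  # (V, 3) mm
    t2: np.ndarray | None = None
    singular: np.ndarray | None = None   # vertices with singular covariance


def motion_vectors(aligned: list[AlignedSample], age_a: float, age_b: float,
                   *, age_tol: float = 0.25) -> MotionVectorSet:
    """Collect points(age_b) − points(age_a) for subjects scanned at both ages."""
    by_subject: dict[str, dict[str, AlignedSample]] = {}
    for s in aligned:
        slot = by_subject.setdefault(s.subject_id, {})
        if abs(s.age - age_a) <= age_tol:
            slot["a"] = s
        elif abs(s.age - age_b) <= age_tol:
            slot["b"] = s
    ids, disp = [], []
    for sid in sorted(by_subject):
        slot = by_subject[sid]
        if "a" in slot and "b" in slot:
            ids.append(sid)
            disp.append(slot["b"].points - slot["a"].points)
    if not ids:
        raise ValidationError(f"no subject scanned at both ages {age_a} and {age_b}")
    return MotionVectorSet(age_a, age_b, ids, np.stack(disp))


def hotelling_map(mv: MotionVectorSet, alpha: float = 0.05,
                  *, fdr: bool = False) -> VertexStatMap:
    """One-sample Hotelling's T² per vertex: did this vertex move?

    T² = n · x̄ᵀ S⁻¹ x̄ with the (3 × 3) sample covariance S over subjects;
    F = (n − p) / (p (n − 1)) · T² on (p, n − p) df, p = 3. Vertices with a
    singular covariance get p = 1 and are flagged. Requires n ≥ 5 so that
    n − p ≥ 2.
    """
    n = mv.n
    p = 3
    if n < 5:
        raise ValidationError(f"Hotelling map needs n >= 5 complete pairs, got {n}")
    D = mv.displacements                       # (n, V, 3)
    mean = D.mean(axis=0)                      # (V, 3)
    C = D - mean
    S = np.einsum("nvi,nvj->vij", C, C) / (n - 1)   # (V, 3, 3)

    # batch solve S x = mean; singular vertices handled separately
    dets = np.linalg.det(S)
    eps = np.finfo(float).eps
    scale = np.einsum("vii->v", S) / 3.0
    singular = dets <= (1e3 * eps * np.maximum(scale, eps)) ** 3
    t2 = np.zeros(mean.shape[0])
    ok = ~singular
    if ok.any():
        sol = np.linalg.solve(S[ok], mean[ok][..., None])[..., 0]
        t2[ok] = n * np.einsum("vi,vi->v", mean[ok], sol)
    F = (n - p) / (p * (n - 1.0)) * t2
    pval = np.ones(mean.shape[0])
    pval[ok] = stats.f.sf(F[ok], p, n - p)
    if fdr:
        from statsmodels.stats.multitest import multipletests
        pval = multipletests(pval, method="fdr_bh")[1]
    mag = np.linalg.norm(mean, axis=1)
    return VertexStatMap(mean_magnitude=mag, p_value=pval,
                         significant=pval < alpha, alpha=alpha,
                         mean_vector=mean, t2=t2, singular=singular)


def consensus_vertex_normals(mesh: TriangleMesh, points: np.ndarray | None = None) -> np.ndarray:
    """Area-weighted vertex normals of the consensus configuration.

    `points` overrides the mesh's own vertices (e.g. the GPA consensus on
    the base topology); normals are oriented by the mesh winding.
    """
    import trimesh
    verts = mesh.vertices if points is None else np.asarray(points, dtype=float)
    tm = trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
    return np.asarray(tm.vertex_normals, dtype=float)


def signed_normal_magnitude(mv: MotionVectorSet, normals: np.ndarray) -> np.ndarray:
    """Mean displacement projected on consensus vertex normals (mm).

    Positive = outward along the consensus normal, negative = inward; this
    sign convention is the package's own. Use with
    ``export_map(..., mode="magnitude")`` and symmetric vmin/vmax for a
    signed colour map.
    """
    N = np.asarray(normals, dtype=float)
    N = N / np.linalg.norm(N, axis=1, keepdims=True)
    mean = mv.displacements.mean(axis=0)
    if mean.shape != N.shape:
        raise ValidationError("normals shape does not match displacement field")
    return np.einsum("vi,vi->v", mean, N)


# ---------------------------------------------------------------------------
# export

#: colour scheme: continuous magnitude maps use this matplotlib colormap,
#: mapped linearly from vmin to vmax; significance maps are binary
#: blue (significant) / grey (not).
MAGNITUDE_CMAP = "viridis"
SIGNIFICANT_RGB = (40, 90, 200)
NOT_SIGNIFICANT_RGB = (150, 150, 150)


def _magnitude_colors(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    cmap = matplotlib.colormaps[MAGNITUDE_CMAP]
    span = vmax - vmin
    t = np.zeros_like(values) if span <= 0 else np.clip((values - vmin) / span, 0, 1)
    return (cmap(t)[:, :3] * 255).round().astype(np.uint8)


def invert_magnitude_colors(rgb: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Recover scalar values from exported colours by nearest LUT entry."""
    cmap = matplotlib.colormaps[MAGNITUDE_CMAP]
    lut = (cmap(np.linspace(0, 1, 256))[:, :3] * 255).round()
    idx = np.argmin(((rgb[:, None, :3].astype(float) - lut[None]) ** 2).sum(-1), axis=1)
    return vmin + idx / 255.0 * (vmax - vmin)


def export_map(stat_map: VertexStatMap | np.ndarray, mesh: TriangleMesh,
               path: str | Path, *, mode: str = "magnitude",
               vmin: float | None = None, vmax: float | None = None,
               csv_path: str | Path | None = None) -> dict:
    """Write a colour-mapped PLY (and optional per-vertex CSV) of a map.

    `mode` is "magnitude" (continuous colormap of mean magnitude, or of a
    raw scalar array) or "significance" (binary blue/grey). The vertex
    count must match the mesh. Returns the colour-scale metadata
    (colormap name, vmin, vmax) needed to invert the colours.
    """
    if isinstance(stat_map, VertexStatMap):
        values = stat_map.mean_magnitude if mode == "magnitude" else None
    else:
        values = np.asarray(stat_map, dtype=float)
        if mode == "significance":
            raise ValidationError("significance mode requires a VertexStatMap")
    if mode == "magnitude":
        if len(values) != mesh.n_vertices:
            raise ValidationError("map length does not match mesh vertex count")
        lo = float(values.min()) if vmin is None else vmin
        hi = float(values.max()) if vmax is None else vmax
        colors = _magnitude_colors(values, lo, hi)
        meta = {"mode": mode, "cmap": MAGNITUDE_CMAP, "vmin": lo, "vmax": hi}
    elif mode == "significance":
        sig = stat_map.significant
        if len(sig) != mesh.n_vertices:
            raise ValidationError("map length does not match mesh vertex count")
        colors = np.where(sig[:, None], np.array(SIGNIFICANT_RGB, dtype=np.uint8),
                          np.array(NOT_SIGNIFICANT_RGB, dtype=np.uint8)).astype(np.uint8)
        meta = {"mode": mode}
    else:
        raise ValidationError(f"unknown map mode {mode!r}")
    rgba = np.column_stack([colors, np.full(len(colors), 255, dtype=np.uint8)])
    write_mesh(mesh, Path(path), vertex_colors=rgba)

    if csv_path is not None and isinstance(stat_map, VertexStatMap):
        import pandas as pd
        sm = stat_map
        mvec = sm.mean_vector if sm.mean_vector is not None else np.full((len(sm.mean_magnitude), 3), np.nan)
        pd.DataFrame({
            "vertex_id": np.arange(len(sm.mean_magnitude)),
            "mean_dx": mvec[:, 0], "mean_dy": mvec[:, 1], "mean_dz": mvec[:, 2],
            "magnitude": sm.mean_magnitude,
            "T2": sm.t2 if sm.t2 is not None else np.nan,
            "p": sm.p_value,
        }).to_csv(csv_path, index=False)
    return meta


def read_map_colors(path: str | Path) -> np.ndarray:
    """Read back the per-vertex RGB colours of an exported PLY."""
    import trimesh
    tm = trimesh.load(path, process=False)
    return np.asarray(tm.visual.vertex_colors)[:, :3]
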