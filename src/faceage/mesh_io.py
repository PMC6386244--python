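"""Mesh, landmark and manifest I/O plus the canonical in-memory dataset.

All coordinates are millimetres throughout the package; files are assumed
to be in mm already and no unit autodetection is attempted. Vertex indices
are 0-based internally; OBJ's 1-based indices are converted at the I/O
boundary only. Vertex order is preserved exactly as stored, because after
dense correspondence the vertex *index* carries anatomical meaning.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

from .exceptions import MeshParseError, ValidationError

__all__ = [
    "LANDMARK_NAMES",
    "TriangleMesh",
    "LandmarkSet",
    "SpecimenRecord",
    "LongitudinalSeries",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_meshlab_picked_points",
    "read_manifest",
    "write_manifest",
]

#: The nine anatomical landmarks used for rigid pre-alignment, in canonical
#: order: right/left exocanthion, right/left endocanthion, nasion,
#: pronasale, right/left cheilion, pogonion.
LANDMARK_NAMES: tuple[str, ...] = (
    "exoR", "exoL", "enR", "enL", "N", "Pn", "chR", "chL", "Pg",
)


@dataclass
class TriangleMesh:
    """A triangle surface mesh: vertices (N, 3) in mm, faces (M, 3) 0-based."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        V, F = self.vertices, self.faces
        if V.ndim != 2 or V.shape[1] != 3 or V.shape[0] < 3:
            raise ValidationError(f"vertices must be (N>=3, 3), got {V.shape}")
        if F.ndim != 2 or F.shape[1] != 3 or F.shape[0] < 1:
            raise ValidationError(f"faces must be (M>=1, 3), got {F.shape}")
        if not np.isfinite(V).all():
            raise ValidationError("non-finite vertex coordinate")
        out = (F < 0) | (F >= len(V))
        if out.any():
            bad = int(np.flatnonzero(out.any(axis=1))[0])
            raise ValidationError(
                f"face index out of range [0, {len(V)}): face row {bad} = {F[bad]}"
            )
        degen = (F[:, 0] == F[:, 1]) | (F[:, 1] == F[:, 2]) | (F[:, 0] == F[:, 2])
        if degen.any():
            raise ValidationError(f"face {int(np.flatnonzero(degen)[0])} repeats a vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        # process=False keeps vertex order and duplicate vertices intact
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def median_edge_length(self) -> float:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        return float(np.median(d))

    def bounding_box_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0)))


@dataclass
class LandmarkSet:
    """The nine pre-alignment landmarks, name -> 3D point (mm)."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        pts = {str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        missing = set(LANDMARK_NAMES) - set(pts)
        extra = set(pts) - set(LANDMARK_NAMES)
        if missing:
            raise ValidationError(f"missing landmarks: {sorted(missing)}")
        if extra:
            raise ValidationError(f"unknown landmarks: {sorted(extra)}")
        arr = np.stack([pts[n] for n in LANDMARK_NAMES])
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite landmark coordinate")
        d = np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            i, j = np.unravel_index(int(d.argmin()), d.shape)
            raise ValidationError(
                f"landmarks {LANDMARK_NAMES[i]} and {LANDMARK_NAMES[j]} coincide"
            )
        self.points = pts

    def as_array(self) -> np.ndarray:
        """(9, 3) array in canonical landmark order."""
        return np.stack([self.points[n] for n in LANDMARK_NAMES])

    @staticmethod
    def from_array(arr: np.ndarray) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=float)
        return LandmarkSet({n: arr[i] for i, n in enumerate(LANDMARK_NAMES)})

    def transformed(self, transform) -> "LandmarkSet":
        return LandmarkSet.from_array(transform.apply(self.as_array()))


@dataclass
class SpecimenRecord:
    """One scan of one subject: mesh + landmarks + anthropometrics."""

    subject_id: str
    sex: str
    age: float
    height_m: float
    weight_kg: float
    mesh: TriangleMesh
    landmarks: LandmarkSet

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be F or M, got {self.sex!r}")
        if not (5.0 <= self.age <= 25.0):
            raise ValidationError(f"age {self.age} outside supported range [5, 25] years")
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise ValidationError("height and weight must be positive")


@dataclass
class LongitudinalSeries:
    """All scans of one subject, sorted by strictly increasing age."""

    subject_id: str
    sex: str
    records: list[SpecimenRecord]

    def __post_init__(self) -> None:
        if any(r.subject_id != self.subject_id or r.sex != self.sex for r in self.records):
            raise ValidationError(f"series {self.subject_id}: inconsistent subject/sex in records")
        self.records = sorted(self.records, key=lambda r: r.age)
        ages = [r.age for r in self.records]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError(f"series {self.subject_id}: duplicate age")

    @property
    def ages(self) -> list[float]:
        return [r.age for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# mesh files

def _read_obj(path: Path) -> TriangleMesh:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tag, *rest = line.split()
            if tag == "v":
                if len(rest) < 3:
                    raise MeshParseError(f"{path}:{lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(x) for x in rest[:3]])
                except ValueError as exc:
                    raise MeshParseError(f"{path}:{lineno}: bad vertex coordinate: {exc}") from exc
            elif tag == "f":
                if len(rest) != 3:
                    raise MeshParseError(
                        f"{path}:{lineno}: non-triangular face with {len(rest)} corners"
                    )
                try:
                    idx = [int(tok.split("/")[0]) for tok in rest]
                except ValueError as exc:
                    raise MeshParseError(f"{path}:{lineno}: bad face index: {exc}") from exc
                if any(i == 0 for i in idx):
                    raise MeshParseError(f"{path}:{lineno}: OBJ indices are 1-based, got 0")
                # negative OBJ indices count from the end of the vertex list
                idx = [i - 1 if i > 0 else len(vertices) + i for i in idx]
                if any(i < 0 or i >= len(vertices) for i in idx):
                    raise MeshParseError(f"{path}:{lineno}: face index out of range: {rest}")
                faces.append(idx)
            # other record types (vn, vt, usemtl, ...) are ignored
    if len(vertices) < 3 or not faces:
        raise MeshParseError(f"{path}: needs >= 3 vertices and >= 1 face")
    try:
        return TriangleMesh(np.array(vertices), np.array(faces))
    except ValidationError as exc:
        raise MeshParseError(f"{path}: {exc}") from exc


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read an OBJ or PLY triangle mesh, preserving vertex order.

    PLY may be ascii or binary-little-endian (handled by trimesh); only
    triangle faces are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".obj":
        return _read_obj(path)
    if suffix == ".ply":
        tm = trimesh.load(path, file_type="ply", process=False)
        faces = np.asarray(tm.faces)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise MeshParseError(f"{path}: non-triangular PLY faces")
        try:
            return TriangleMesh(np.asarray(tm.vertices, dtype=float), faces)
        except ValidationError as exc:
            raise MeshParseError(f"{path}: {exc}") from exc
    raise MeshParseError(f"{path}: unsupported mesh format {suffix!r} (OBJ or PLY)")


def write_mesh(mesh: TriangleMesh, path: str | Path, *,
               vertex_colors: np.ndarray | None = None) -> None:
    """Write OBJ (text) or PLY; optional per-vertex uchar RGB only for PLY."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".obj":
        if vertex_colors is not None:
            raise ValidationError("vertex colours are only supported for PLY output")
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif suffix == ".ply":
        # hand-written ascii PLY: double-precision coordinates (trimesh's
        # writer downcasts to float32, breaking 1e-6 mm round trips)
        colors = None
        if vertex_colors is not None:
            colors = np.asarray(vertex_colors, dtype=np.uint8)
            if colors.ndim != 2 or colors.shape[0] != mesh.n_vertices:
                raise ValidationError("vertex_colors must be (N, 3) or (N, 4) uint8")
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            if colors is not None:
                fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
                if colors.shape[1] == 4:
                    fh.write("property uchar alpha\n")
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for i, v in enumerate(mesh.vertices):
                row = f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}"
                if colors is not None:
                    row += " " + " ".join(str(int(c)) for c in colors[i])
                fh.write(row + "\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise ValidationError(f"unsupported mesh format {suffix!r}")


# ---------------------------------------------------------------------------
# landmark files

def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read the canonical JSON landmark file: ``{"exoR": [x, y, z], ...}``."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: landmark file must be a JSON object")
    try:
        return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in data.items()})
    except (ValidationError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: [float(x) for x in v] for k, v in landmarks.points.items()}, fh, indent=1)
        fh.write("\n")


def read_meshlab_picked_points(path: str | Path) -> LandmarkSet:
    """Convenience import of MeshLab *.pp picked-points XML (not canonical)."""
    tree = ET.parse(path)
    pts = {}
    for p in tree.getroot().iter("point"):
        name = p.get("name")
        pts[name] = np.array([float(p.get(ax)) for ax in ("x", "y", "z")])
    try:
        return LandmarkSet(pts)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# manifest

MANIFEST_COLUMNS = [
    "subject_id", "sex", "age", "height_m", "weight_kg", "mesh_path", "landmark_path",
]


def submesh(mesh: TriangleMesh, vertex_mask: np.ndarray) -> TriangleMesh:
    """Restrict a mesh to the masked-in vertices (faces fully inside kept)."""
    vertex_mask = np.asarray(vertex_mask, dtype=bool)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[vertex_mask] = np.arange(int(vertex_mask.sum()))
    keep = vertex_mask[mesh.faces].all(axis=1)
    return TriangleMesh(mesh.vertices[vertex_mask], remap[mesh.faces[keep]])


def read_manifest(path: str | Path) -> list[LongitudinalSeries]:
    """Read a dataset manifest CSV and load every referenced scan.

    Rows are grouped by subject and sorted by age; relative mesh/landmark
    paths are resolved against the manifest's directory. Row order in the
    file is irrelevant.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "age"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (subject, age) row: {row.subject_id} @ {row.age}"
        )
    base = path.parent
    series: list[LongitudinalSeries] = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        records = []
        for _, row in grp.sort_values("age").iterrows():
            mesh = read_mesh(base / str(row.mesh_path))
            lms = read_landmarks(base / str(row.landmark_path))
            records.append(SpecimenRecord(
                subject_id=str(subject_id), sex=str(row.sex), age=float(row.age),
                height_m=float(row.height_m), weight_kg=float(row.weight_kg),
                mesh=mesh, landmarks=lms,
            ))
        series.append(LongitudinalSeries(str(subject_id), records[0].sex, records))
    return series


def write_manifest(rows: Iterable[Mapping], path: str | Path) -> None:
    df = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
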