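"""Synthetic longitudinal 3D face datasets with known ground truth.

The study design this emulates: two longitudinal cohorts per sex (scanned
once a year at ages 7–12 and 12–17), each subject carrying a smooth
identity deformation, plus a sex-specific growth displacement field whose
velocity is flat in childhood, peaks at puberty (earlier in girls) and
decays to near zero by 17. Each scan then gets a rigid pose jitter,
i.i.d. vertex noise, and — optionally — an independent re-meshing that
destroys native vertex correspondence, exactly the nuisance the
correspondence pipeline exists to undo.

Everything is an analytic function of the template's (x, y)
parameterisation, so a re-meshed scan and its ground-truth homologous
positions are evaluations of the same surface at different parameter
grids. All randomness flows from a single seed through a documented
`SeedSequence` spawning scheme (fields, subjects, scans, anthropometry).

Faces are face-*like* (a half-ellipsoid dome with Gaussian features), not
photorealistic; growth magnitudes are configurable, not anatomically
validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .anthropometrics import LmsReference, lms_bmi_from_percentile, synthetic_lms_reference, write_lms_reference
from .exceptions import ValidationError
from .mesh_io import (LANDMARK_NAMES, LandmarkSet, LongitudinalSeries, SpecimenRecord,
                      TriangleMesh, write_landmarks, write_manifest, write_mesh)
from .rigid import RigidTransform

__all__ = ["SynthConfig", "GroundTruth", "make_template", "build_dataset", "generate_dataset"]

# face patch extent, mm
FACE_W = 130.0
FACE_H = 170.0

#: analytic landmark parameter positions (x, y) on the template surface.
#: x > 0 is the subject's anatomical left, so "R" landmarks sit at x < 0.
LANDMARK_XY = {
    "exoR": (-42.0, 25.0), "exoL": (42.0, 25.0),
    "enR": (-18.0, 25.0), "enL": (18.0, 25.0),
    "N": (0.0, 30.0), "Pn": (0.0, -5.0),
    "chR": (-22.0, -45.0), "chL": (22.0, -45.0),
    "Pg": (0.0, -75.0),
}


def _gauss2(x, y, cx, cy, sx, sy):
    return np.exp(-((x - cx) ** 2 / (2 * sx * sx) + (y - cy) ** 2 / (2 * sy * sy)))


def face_depth(x, y):
    """Analytic template depth z(x, y) in mm: dome + nose, brow, lips, chin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dome = 38.0 * np.sqrt(np.clip(1.0 - (x / 115.0) ** 2 - (y / 165.0) ** 2, 0.0, None))
    nose = 16.0 * _gauss2(x, y, 0, -8.0, 8.0, 16.0)
    brow = 4.0 * (_gauss2(x, y, -28.0, 38.0, 11.0, 7.0) + _gauss2(x, y, 28.0, 38.0, 11.0, 7.0))
    lips = 5.0 * _gauss2(x, y, 0, -45.0, 16.0, 5.0)
    chin = 7.0 * _gauss2(x, y, 0, -75.0, 14.0, 9.0)
    return dome + nose + brow + lips + chin


def _grid(nx: int, ny: int, jitter_rng: np.random.Generator | None = None,
          jitter_frac: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular parameter grid over the face patch with triangulation."""
    xs = np.linspace(-FACE_W / 2, FACE_W / 2, nx)
    ys = np.linspace(-FACE_H / 2, FACE_H / 2, ny)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    if jitter_rng is not None and jitter_frac > 0:
        cell = np.array([xs[1] - xs[0], ys[1] - ys[0]])
        jit = jitter_rng.uniform(-jitter_frac, jitter_frac, xy.shape) * cell
        interior = ((np.abs(xy[:, 0]) < FACE_W / 2 - 1e-9)
                    & (np.abs(xy[:, 1]) < FACE_H / 2 - 1e-9))
        xy[interior] += jit[interior]
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            v0 = j * nx + i
            v1 = v0 + 1
            v2 = v0 + nx
            v3 = v2 + 1
            faces.append((v0, v1, v3))
            faces.append((v0, v3, v2))
    return xy, np.array(faces, dtype=np.int64)


def _grid_shape(n_vertices: int) -> tuple[int, int]:
    nx = max(4, int(round(np.sqrt(n_vertices * FACE_W / FACE_H))))
    ny = max(4, int(round(n_vertices / nx)))
    return nx, ny


def make_template(n_vertices: int = 1500) -> tuple[TriangleMesh, LandmarkSet]:
    """Template face mesh (~`n_vertices` grid points) + the nine landmarks.

    The surface is bilaterally symmetric: mirroring across x = 0 permutes
    the left/right landmarks exactly.
    """
    nx, ny = _grid_shape(n_vertices)
    xy, faces = _grid(nx, ny)
    verts = np.column_stack([xy, face_depth(xy[:, 0], xy[:, 1])])
    lms = LandmarkSet({name: np.array([x, y, float(face_depth(x, y))])
                       for name, (x, y) in LANDMARK_XY.items()})
    return TriangleMesh(verts, faces), lms


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic cohorts.

    Defaults are the emulated study conditions: 20 subjects per sex per
    cohort scanned annually over 7–12 and 12–17 years (480 scans),
    ~1500-vertex template, 1.5 mm identity variation per basis field,
    10 mm total pubertal growth at the fastest-moving vertex with the
    velocity peak at 11.5 y (girls) / 12.5 y (boys), 0.2 mm vertex noise,
    modest rigid pose jitter, and independent re-meshing of every scan.
    """

    n_subjects: int = 20                       # per sex per cohort
    cohorts: tuple = ((7, 12), (12, 17))
    template_vertices: int = 1500
    n_identity_fields: int = 8
    identity_sd_mm: float = 1.5
    growth_amplitude_mm: float = 10.0
    peak_age_f: float = 11.5
    peak_age_m: float = 12.5
    noise_sd_mm: float = 0.2
    jitter_rot_deg: float = 5.0
    jitter_trans_mm: float = 10.0
    remesh: bool = True
    remesh_jitter_frac: float = 0.25
    hole_fraction: float = 0.0                 # fraction of patch area removed per scan
    bmi_drift_sd: float = 2.0                  # percentile drift per year, SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.template_vertices < 16:
            raise ValidationError("invalid cohort size or template resolution")
        if not (7.0 <= self.peak_age_f <= 17.0 and 7.0 <= self.peak_age_m <= 17.0):
            raise ValidationError("velocity peak ages must lie in [7, 17]")
        if min(self.identity_sd_mm, self.growth_amplitude_mm, self.noise_sd_mm,
               self.hole_fraction, self.bmi_drift_sd) < 0:
            raise ValidationError("variances/amplitudes must be >= 0")

    def peak_age(self, sex: str) -> float:
        return self.peak_age_f if sex == "F" else self.peak_age_m


class GrowthSchedule:
    """Cumulative growth fraction S(age) with a piecewise-linear velocity.

    Velocity is flat from 7 to 10, rises linearly to its peak, declines to
    near zero by 16.5 and stays there; S integrates it, normalised to
    S(7) = 0, S(17) = 1.
    """

    def __init__(self, peak_age: float):
        self.peak_age = peak_age
        knots_a = np.array([7.0, 10.0, peak_age, 16.5, 17.0])
        knots_v = np.array([0.35, 0.35, 1.0, 0.05, 0.05])
        grid = np.linspace(7.0, 17.0, 2001)
        v = np.interp(grid, knots_a, knots_v)
        S = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2 * np.diff(grid))])
        self._grid = grid
        self._S = S / S[-1]
        self._v = v / S[-1]

    def __call__(self, age) -> np.ndarray | float:
        out = np.interp(age, self._grid, self._S)
        return float(out) if np.ndim(age) == 0 else out

    def velocity(self, age) -> np.ndarray | float:
        out = np.interp(age, self._grid, self._v)
        return float(out) if np.ndim(age) == 0 else out


class _IdentityFields:
    """Fixed smooth radial-basis displacement fields shared by a dataset."""

    def __init__(self, rng: np.random.Generator, n_fields: int):
        self.centers = np.column_stack([
            rng.uniform(-FACE_W / 2 * 0.8, FACE_W / 2 * 0.8, n_fields),
            rng.uniform(-FACE_H / 2 * 0.8, FACE_H / 2 * 0.8, n_fields),
        ])
        self.widths = rng.uniform(25.0, 45.0, n_fields)
        d = rng.normal(size=(n_fields, 3))
        self.directions = d / np.linalg.norm(d, axis=1, keepdims=True)

    def displacement(self, xy: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        d2 = ((xy[:, None, :] - self.centers[None]) ** 2).sum(-1)
        phi = np.exp(-d2 / (2 * self.widths**2))          # (n, K)
        return phi @ (coeffs[:, None] * self.directions)   # (n, 3)


def _growth_direction(xy: np.ndarray) -> np.ndarray:
    """Un-normalised growth displacement pattern at parameters xy.

    Depth gain concentrated at nose, chin, brow and forehead plus a
    vertical elongation term (the face gets longer as well as more
    protrusive).
    """
    x, y = xy[:, 0], xy[:, 1]
    profile = 0.25 + 0.75 * np.clip(
        _gauss2(x, y, 0, -8.0, 10.0, 18.0)          # nose
        + _gauss2(x, y, 0, -75.0, 16.0, 12.0)       # chin
        + _gauss2(x, y, 0, 60.0, 35.0, 25.0)        # forehead
        + 0.7 * (_gauss2(x, y, -28.0, 38.0, 12.0, 8.0)
                 + _gauss2(x, y, 28.0, 38.0, 12.0, 8.0)),  # brow ridges
        0.0, 1.0)
    d = np.zeros((len(xy), 3))
    d[:, 2] = profile
    d[:, 1] = 0.35 * (y / (FACE_H / 2))
    return d


@dataclass
class _Subject:
    subject_id: str
    sex: str
    cohort: tuple[int, int]
    identity_coeffs: np.ndarray
    height_offset_m: float
    start_percentile: float
    percentile_drift: float


class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    def __init__(self, config: SynthConfig, template: TriangleMesh,
                 landmarks: LandmarkSet, template_xy: np.ndarray,
                 growth_scale: float, schedules: dict[str, GrowthSchedule],
                 identity: _IdentityFields):
        self.config = config
        self.template = template
        self.template_landmarks = landmarks
        self.template_xy = template_xy
        self.growth_scale = growth_scale          # mm per unit S at the fastest vertex
        self.schedules = schedules
        self.identity = identity
        self.true_points: dict[tuple[str, float], np.ndarray] = {}
        self.jitters: dict[tuple[str, float], RigidTransform] = {}
        self.hole_vertex_mask: dict[tuple[str, float], np.ndarray] = {}
        self.hole_discs: dict[tuple[str, float], tuple[np.ndarray, float]] = {}
        self.scan_vertex_counts: dict[tuple[str, float], int] = {}
        self.scan_xy: dict[tuple[str, float], np.ndarray] = {}
        self.subject_coeffs: dict[str, np.ndarray] = {}
        self.subject_sex: dict[str, str] = {}

    # -- analytic truths ---------------------------------------------------
    def growth_field(self, xy: np.ndarray | None = None) -> np.ndarray:
        """Full (S = 1) growth displacement, (V, 3) mm, at template params."""
        xy = self.template_xy if xy is None else xy
        return self.growth_scale * _growth_direction(xy)

    def mean_shape(self, sex: str, age: float) -> np.ndarray:
        """Population mean surface at an age (identity fields average to zero)."""
        base = self.template.vertices
        return base + self.schedules[sex](age) * self.growth_field()

    def transition_norms(self, sex: str, age_a: float, age_b: float) -> np.ndarray:
        """Programmed per-vertex displacement magnitude for a transition."""
        dS = abs(self.schedules[sex](age_b) - self.schedules[sex](age_a))
        return dS * np.linalg.norm(self.growth_field(), axis=1)

    def surface(self, subject_id: str, xy: np.ndarray, age: float) -> np.ndarray:
        """Subject's noise-free, un-jittered surface at parameters xy and an age.

        Because every deformation is an analytic function of the template
        parameterisation, this gives the true homologous position of *any*
        surface point at any age — the oracle for correspondence and
        prediction accuracy.
        """
        sex = self.subject_sex[subject_id]
        base = np.column_stack([xy[:, 0], xy[:, 1], face_depth(xy[:, 0], xy[:, 1])])
        ident = self.identity.displacement(xy, self.subject_coeffs[subject_id])
        growth = self.schedules[sex](age) * self.growth_scale * _growth_direction(xy)
        return base + ident + growth

    def velocity_peak_age(self, sex: str) -> float:
        grid = np.linspace(7.5, 16.5, 1801)
        return float(grid[np.argmax(self.schedules[sex].velocity(grid))])


def _make_rigid_jitter(rng: np.random.Generator, cfg: SynthConfig) -> RigidTransform:
    ang = np.deg2rad(rng.uniform(-cfg.jitter_rot_deg, cfg.jitter_rot_deg, 3))
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    t = rng.uniform(-cfg.jitter_trans_mm, cfg.jitter_trans_mm, 3)
    return RigidTransform(Rz @ Ry @ Rx, t)


#: girls'/boys' stature in metres at knot ages, linearly interpolated
_HEIGHT_KNOTS = {
    "F": (np.array([5.0, 7, 11, 13, 17, 25.0]), np.array([1.10, 1.23, 1.45, 1.58, 1.66, 1.67])),
    "M": (np.array([5.0, 7, 12, 14, 17, 25.0]), np.array([1.12, 1.25, 1.50, 1.65, 1.77, 1.78])),
}


def _height_m(sex: str, age: float, offset: float) -> float:
    a, h = _HEIGHT_KNOTS[sex]
    return float(np.interp(age, a, h)) + offset


def build_dataset(cfg: SynthConfig,
                  lms_ref: LmsReference | None = None,
                  ) -> tuple[list[LongitudinalSeries], GroundTruth]:
    """Generate the dataset in memory.

    Returns the longitudinal series (ready for the pipeline) and the
    GroundTruth. Deterministic in `cfg.seed`: the master SeedSequence is
    spawned into (identity-fields, subjects, scans, anthropometrics)
    streams in that fixed order.
    """
    if lms_ref is None:
        lms_ref = synthetic_lms_reference()
    master = np.random.SeedSequence(cfg.seed)
    ss_fields, ss_subjects, ss_scans, ss_anthro = master.spawn(4)
    rng_fields = np.random.default_rng(ss_fields)
    rng_subjects = np.random.default_rng(ss_subjects)
    rng_anthro = np.random.default_rng(ss_anthro)

    template, lms = make_template(cfg.template_vertices)
    template_xy = template.vertices[:, :2].copy()
    identity = _IdentityFields(rng_fields, cfg.n_identity_fields)
    raw = _growth_direction(template_xy)
    growth_scale = cfg.growth_amplitude_mm / float(np.linalg.norm(raw, axis=1).max())
    schedules = {"F": GrowthSchedule(cfg.peak_age_f), "M": GrowthSchedule(cfg.peak_age_m)}
    truth = GroundTruth(cfg, template, lms, template_xy, growth_scale, schedules, identity)

    subjects: list[_Subject] = []
    for ci, cohort in enumerate(cfg.cohorts):
        for sex in ("F", "M"):
            for i in range(cfg.n_subjects):
                subjects.append(_Subject(
                    subject_id=f"{sex}{ci + 1}{i + 1:02d}",
                    sex=sex, cohort=tuple(cohort),
                    identity_coeffs=rng_subjects.normal(0.0, cfg.identity_sd_mm,
                                                        cfg.n_identity_fields),
                    height_offset_m=rng_anthro.normal(0.0, 0.04),
                    start_percentile=rng_anthro.uniform(15.0, 85.0),
                    percentile_drift=rng_anthro.normal(0.0, cfg.bmi_drift_sd),
                ))

    nx0, ny0 = _grid_shape(cfg.template_vertices)
    series_list: list[LongitudinalSeries] = []
    lm_arr = np.array([LANDMARK_XY[n] for n in LANDMARK_NAMES])

    def surface_points(xy: np.ndarray, subj: _Subject, age: float) -> np.ndarray:
        base = np.column_stack([xy, face_depth(xy[:, 0], xy[:, 1])])
        ident = identity.displacement(xy, subj.identity_coeffs)
        growth = schedules[subj.sex](age) * growth_scale * _growth_direction(xy)
        return base + ident + growth

    for subj in subjects:
        rng_scan = np.random.default_rng(ss_scans.spawn(1)[0])
        truth.subject_coeffs[subj.subject_id] = subj.identity_coeffs
        truth.subject_sex[subj.subject_id] = subj.sex
        records = []
        ages = list(range(subj.cohort[0], subj.cohort[1] + 1))
        for age in ages:
            key = (subj.subject_id, float(age))
            truth.true_points[key] = surface_points(template_xy, subj, age)

            if cfg.remesh:
                nx = nx0 + int(rng_scan.integers(-2, 3))
                ny = ny0 + int(rng_scan.integers(-2, 3))
                xy, faces = _grid(nx, ny, rng_scan, cfg.remesh_jitter_frac)
            else:
                xy, faces = template_xy.copy(), template.faces.copy()
            verts = surface_points(xy, subj, float(age))

            if cfg.hole_fraction > 0:
                r = np.sqrt(cfg.hole_fraction * FACE_W * FACE_H / np.pi)
                c = np.array([rng_scan.uniform(-FACE_W / 4, FACE_W / 4),
                              rng_scan.uniform(-FACE_H / 4, FACE_H / 4)])
                inside = ((xy - c) ** 2).sum(1) < r * r
                keep = ~inside
                remap = -np.ones(len(xy), dtype=np.int64)
                remap[keep] = np.arange(keep.sum())
                faces = remap[faces[keep[faces].all(axis=1)]]
                verts = verts[keep]
                xy = xy[keep]
                truth.hole_vertex_mask[key] = ((template_xy - c) ** 2).sum(1) < r * r
                truth.hole_discs[key] = (c, r)
            else:
                truth.hole_vertex_mask[key] = np.zeros(len(template_xy), dtype=bool)

            truth.scan_xy[key] = xy.copy()
            jitter = _make_rigid_jitter(rng_scan, cfg)
            truth.jitters[key] = jitter
            verts = jitter.apply(verts)
            if cfg.noise_sd_mm > 0:
                verts = verts + rng_scan.normal(0.0, cfg.noise_sd_mm, verts.shape)

            lm_pts = surface_points(lm_arr, subj, float(age))
            lm_set = LandmarkSet.from_array(jitter.apply(lm_pts))

            truth.scan_vertex_counts[key] = len(verts)
            height = _height_m(subj.sex, age, subj.height_offset_m)
            pct = float(np.clip(subj.start_percentile
                                + subj.percentile_drift * (age - ages[0])
                                + rng_anthro.normal(0.0, 1.0), 2.0, 98.0))
            bmi_val = lms_bmi_from_percentile(pct, float(age), subj.sex, lms_ref)
            records.append(SpecimenRecord(
                subject_id=subj.subject_id, sex=subj.sex, age=float(age),
                height_m=height, weight_kg=bmi_val * height * height,
                mesh=TriangleMesh(verts, faces), landmarks=lm_set,
            ))
        series_list.append(LongitudinalSeries(subj.subject_id, subj.sex, records))
    return series_list, truth


def generate_dataset(cfg: SynthConfig, out_dir: str | Path,
                     lms_ref: LmsReference | None = None) -> GroundTruth:
    """Generate and write a dataset: OBJ scans, landmark JSON, manifest CSV,
    the LMS reference used, and a ground-truth archive.

    Same seed → byte-identical output tree (meshes are text OBJ with fixed
    formatting; arrays are raw .npy).
    """
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    if lms_ref is None:
        lms_ref = synthetic_lms_reference()
    series_list, truth = build_dataset(cfg, lms_ref)
    rows = []
    for series in series_list:
        for rec in series.records:
            stem = f"scans/{rec.subject_id}_{int(round(rec.age)):02d}"
            write_mesh(rec.mesh, out / f"{stem}.obj")
            write_landmarks(rec.landmarks, out / f"{stem}.json")
            rows.append({
                "subject_id": rec.subject_id, "sex": rec.sex, "age": rec.age,
                "height_m": round(rec.height_m, 4), "weight_kg": round(rec.weight_kg, 3),
                "mesh_path": f"{stem}.obj", "landmark_path": f"{stem}.json",
            })
    write_manifest(rows, out / "manifest.csv")
    write_lms_reference(lms_ref, out / "lms_reference.csv")

    gt_dir = out / "groundtruth"
    gt_dir.mkdir(exist_ok=True)
    keys = sorted(truth.true_points)
    np.save(gt_dir / "true_points.npy", np.stack([truth.true_points[k] for k in keys]))
    np.save(gt_dir / "template_xy.npy", truth.template_xy)
    meta = {
        "keys": [[k[0], k[1]] for k in keys],
        "growth_scale": truth.growth_scale,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "velocity_peak_age": {s: truth.velocity_peak_age(s) for s in ("F", "M")},
    }
    (gt_dir / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    return truth
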