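"""End-to-end pipeline orchestration with content-hash stage caching.

Stage order: correspondence → GPA/PCA per sex → growth maps per
adjacent-age transition → trajectory per sex → cohort prediction
evaluation + baseline comparison → BMI analysis. Every stage writes its
artifacts into the run directory and records a content hash of its
inputs; re-running with unchanged inputs reloads the serialized artifacts
verbatim (hence bit-for-bit equality with a fresh run). All resolved
parameters are appended to ``pipeline.log``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import anthropometrics as anthro
from .correspondence import CpdParams, build_correspondence
from .exceptions import PipelineStageError, ValidationError
from .growth_maps import export_map, hotelling_map, motion_vectors
from .mesh_io import TriangleMesh, read_manifest, submesh, write_mesh
from .plots import plot_bmi_scatter, plot_trajectories
from .prediction import baseline_comparison, cohort_evaluation, prediction_error
from .shape_space import (AlignedSample, fit_pca, gpa_align, load_space,
                          orient_by_age, save_space, to_scores)
from .trajectory import fit_global_trajectory, load_trajectory, save_trajectory

__all__ = ["PipelineConfig", "CorrespondedDataset", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    manifest: str
    out_dir: str
    sex_filter: str | None = None          # None = both sexes
    split_age: float = 12.0                # cohort split; the split-age scan is shared
    variance_target: float = 0.95
    alpha: float = 0.05
    beta_rel: float = 0.1                  # CPD kernel width / bbox diagonal
    cpd_lam: float = 10.0
    cpd_w: float = 0.1
    cpd_max_iter: int = 150
    cpd_tol: float = 1e-5
    prune_k: float = 3.0                   # pruning threshold in median edge lengths
    base_index: int = 0                    # which specimen provides the base mesh
    shape_mode: bool = False               # True = classical (size-removed) GPA
    allow_extrapolation: bool = False
    bmi_regressor: str = "delta"           # "delta" (canonical) or "raw"
    lms_reference: str | None = None       # CSV path; None = packaged synthetic reference
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.sex_filter not in (None, "F", "M"):
            raise ValidationError("sex_filter must be None, 'F' or 'M'")
        if self.bmi_regressor not in ("delta", "raw"):
            raise ValidationError("bmi_regressor must be 'delta' or 'raw'")


@dataclass
class CorrespondedDataset:
    """Array-of-struct view of stage-1 output used by downstream stages."""

    subject_ids: np.ndarray       # (S,) str
    ages: np.ndarray              # (S,)
    sexes: np.ndarray             # (S,) str
    points: np.ndarray            # (S, V, 3)
    mask: np.ndarray              # (V,)
    base_mesh: TriangleMesh


def _sha(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p if isinstance(p, bytes) else str(p).encode())
        h.update(b"\x00")
    return h.hexdigest()


class _Cache:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "cache.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, key: str, artifacts: list[Path]) -> bool:
        return self.data.get(stage) == key and all(a.exists() for a in artifacts)

    def update(self, stage: str, key: str) -> None:
        self.data[stage] = key
        self.path.write_text(json.dumps(self.data, indent=1) + "\n")


def _log(out: Path, msg: str) -> None:
    with open(out / "pipeline.log", "a") as fh:
        fh.write(msg.rstrip() + "\n")


# ---------------------------------------------------------------------------
# stages

def _stage_correspond(cfg: PipelineConfig, out: Path, cache: _Cache) -> tuple[CorrespondedDataset, str]:
    manifest = Path(cfg.manifest)
    key = _sha("correspond", manifest.read_bytes(), cfg.sex_filter, cfg.beta_rel,
               cfg.cpd_lam, cfg.cpd_w, cfg.cpd_max_iter, cfg.cpd_tol,
               cfg.prune_k, cfg.base_index)
    npz = out / "corresponded.npz"
    meta_p = out / "corresponded_meta.json"
    base_p = out / "base_mesh.obj"
    if cache.fresh("correspond", key, [npz, meta_p, base_p]):
        from .mesh_io import read_mesh
        data = np.load(npz)
        meta = json.loads(meta_p.read_text())
        ds = CorrespondedDataset(np.array(meta["subject_ids"]), np.array(meta["ages"]),
                                 np.array(meta["sexes"]), data["points"], data["mask"],
                                 read_mesh(base_p))
        _log(out, "[correspond] cache hit")
        return ds, key

    series = read_manifest(manifest)
    if cfg.sex_filter:
        series = [s for s in series if s.sex == cfg.sex_filter]
    if not series:
        raise PipelineStageError("correspond: no series after sex filtering")
    specimens = [r for s in series for r in s.records]
    base = specimens[cfg.base_index]
    params = CpdParams.from_points(base.mesh.vertices, beta_rel=cfg.beta_rel,
                                   lam=cfg.cpd_lam, w=cfg.cpd_w,
                                   max_iter=cfg.cpd_max_iter, tol=cfg.cpd_tol)
    _log(out, f"[correspond] {len(specimens)} scans, base={base.subject_id}@{base.age}, "
              f"beta={params.beta:.2f}mm lam={params.lam} w={params.w} prune_k={cfg.prune_k}")
    result = build_correspondence(series, cfg.base_index, params, prune_k=cfg.prune_k)

    pts = np.stack([s.points for s in result.samples])
    np.savez(npz, points=pts, mask=result.mask, distances=result.projection_distances)
    meta = {"subject_ids": [s.subject_id for s in result.samples],
            "ages": [s.age for s in result.samples],
            "sexes": [s.sex for s in result.samples]}
    meta_p.write_text(json.dumps(meta, indent=1) + "\n")
    write_mesh(result.base_mesh, base_p)
    np.savetxt(out / "retained_vertices.txt", np.flatnonzero(result.mask), fmt="%d")
    ply_dir = out / "corresponded"
    ply_dir.mkdir(exist_ok=True)
    for s in result.samples:
        write_mesh(TriangleMesh(s.points, result.base_mesh.faces),
                   ply_dir / f"{s.subject_id}_{int(round(s.age)):02d}.ply")
    cache.update("correspond", key)
    _log(out, f"[correspond] retained {int(result.mask.sum())}/{len(result.mask)} vertices")
    return CorrespondedDataset(np.array(meta["subject_ids"]), np.array(meta["ages"]),
                               np.array(meta["sexes"]), pts, result.mask,
                               result.base_mesh), key


def _stage_space(cfg: PipelineConfig, out: Path, cache: _Cache,
                 ds: CorrespondedDataset, up_key: str, sex: str):
    key = _sha("space", up_key, sex, cfg.variance_target, cfg.shape_mode)
    npz = out / f"aligned_{sex}.npz"
    space_p = out / f"space_{sex}"
    if cache.fresh(f"space_{sex}", key, [npz, space_p.with_suffix(".npz")]):
        data = np.load(npz)
        aligned = [AlignedSample(str(i), float(a), sex, p)
                   for i, a, p in zip(data["subject_ids"], data["ages"], data["points"])]
        _log(out, f"[space:{sex}] cache hit")
        return aligned, load_space(space_p), data["consensus"], key

    sel = np.flatnonzero(ds.sexes == sex)
    if len(sel) < 3:
        raise PipelineStageError(f"space: fewer than 3 scans for sex {sex}")
    from .correspondence import CorrespondedSample
    samples = [CorrespondedSample(str(ds.subject_ids[i]), float(ds.ages[i]), sex,
                                  ds.points[i], ds.mask) for i in sel]
    aligned, consensus = gpa_align(samples, ds.mask, shape_mode=cfg.shape_mode)
    space = fit_pca(aligned, cfg.variance_target, sex=sex)
    space = orient_by_age(space, aligned)
    np.savez(npz, subject_ids=np.array([a.subject_id for a in aligned]),
             ages=np.array([a.age for a in aligned]),
             points=np.stack([a.points for a in aligned]), consensus=consensus)
    save_space(space, space_p)
    cache.update(f"space_{sex}", key)
    _log(out, f"[space:{sex}] n={len(aligned)} K={space.n_components} "
              f"PC1={space.explained_fraction[0]:.1%}")
    return aligned, space, consensus, key


def _stage_maps(cfg: PipelineConfig, out: Path, cache: _Cache, ds: CorrespondedDataset,
                aligned: list[AlignedSample], sex: str, up_key: str) -> str:
    key = _sha("maps", up_key, cfg.alpha)
    maps_dir = out / "maps"
    done = maps_dir / f".done_{sex}"
    if cache.fresh(f"maps_{sex}", key, [done]):
        _log(out, f"[maps:{sex}] cache hit")
        return key
    maps_dir.mkdir(exist_ok=True)
    mesh = submesh(ds.base_mesh, ds.mask)
    ages = sorted({int(round(a.age)) for a in aligned})
    written = []
    for a, b in zip(ages, ages[1:]):
        try:
            mv = motion_vectors(aligned, a, b)
        except ValidationError:
            _log(out, f"[maps:{sex}] {a}->{b}: no complete pairs, skipped")
            continue
        if mv.n < 5:
            _log(out, f"[maps:{sex}] {a}->{b}: only {mv.n} pairs (<5), skipped")
            continue
        sm = hotelling_map(mv, cfg.alpha)
        stem = maps_dir / f"{sex}_{a:02d}to{b:02d}"
        meta = export_map(sm, mesh, stem.with_suffix(".ply"), mode="magnitude",
                          csv_path=stem.with_suffix(".csv"))
        export_map(sm, mesh, Path(str(stem) + "_sig.ply"), mode="significance")
        stem.with_suffix(".meta.json").write_text(json.dumps(meta) + "\n")
        written.append(stem.name)
        _log(out, f"[maps:{sex}] {a}->{b}: n={mv.n}, "
                  f"{sm.significant.mean():.1%} vertices significant at {cfg.alpha}")
    done.write_text("\n".join(written) + "\n")
    cache.update(f"maps_{sex}", key)
    return key


def _stage_trajectory(cfg: PipelineConfig, out: Path, cache: _Cache,
                      aligned: list[AlignedSample], space, sex: str, up_key: str):
    key = _sha("trajectory", up_key, cfg.split_age)
    traj_p = out / f"trajectory_{sex}.json"
    if cache.fresh(f"trajectory_{sex}", key, [traj_p]):
        _log(out, f"[trajectory:{sex}] cache hit")
        return load_trajectory(traj_p), key
    scores: dict[str, list] = {}
    for s in aligned:
        scores.setdefault(s.subject_id, []).append((s.age, to_scores(s, space).scores))
    traj, young_models, old_models = fit_global_trajectory(scores, cfg.split_age, sex)
    save_trajectory(traj, traj_p)
    plot_trajectories(traj, young_models, old_models, out / f"trajectory_{sex}.png")
    cache.update(f"trajectory_{sex}", key)
    _log(out, f"[trajectory:{sex}] young n={traj.young.n_subjects} "
              f"old n={traj.old.n_subjects} knots={traj.knots}")
    return traj, key


def _cohort_subsets(aligned: list[AlignedSample], split_age: float):
    """Split each subject's scans at the cohort boundary (shared split scan)."""
    by_subject: dict[str, list[AlignedSample]] = {}
    for s in aligned:
        by_subject.setdefault(s.subject_id, []).append(s)
    young, old = [], []
    for sid, scans in by_subject.items():
        young += [s for s in scans if s.age <= split_age]
        old += [s for s in scans if s.age >= split_age]
    return {"young": young, "old": old}


def _stage_evaluate(cfg: PipelineConfig, out: Path, cache: _Cache,
                    ds: CorrespondedDataset, aligned, space, traj, sex: str, up_key: str):
    key = _sha("evaluate", up_key)
    csv_p = out / f"evaluation_{sex}.csv"
    cmp_p = out / f"comparison_{sex}.json"
    if cache.fresh(f"evaluate_{sex}", key, [csv_p, cmp_p]):
        _log(out, f"[evaluate:{sex}] cache hit")
        return pd.read_csv(csv_p), json.loads(cmp_p.read_text()), key
    mesh = submesh(ds.base_mesh, ds.mask)
    rows = []
    comparisons = {}
    for cohort, subset in _cohort_subsets(aligned, cfg.split_age).items():
        counts: dict[str, int] = {}
        for s in subset:
            counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
        usable = [s for s in subset if counts[s.subject_id] >= 2]
        skipped = sorted(set(counts) - {s.subject_id for s in usable})
        if skipped:
            _log(out, f"[evaluate:{sex}:{cohort}] skipped single-scan subjects: {skipped}")
        if not usable:
            continue
        results, group_map = cohort_evaluation(usable, traj, space,
                                               allow_extrapolation=cfg.allow_extrapolation)
        export_map(group_map, mesh, out / f"errmap_{sex}_{cohort}.ply", mode="magnitude")
        # non-aged baseline: the untransformed youngest face vs the oldest
        by_subj: dict[str, list[AlignedSample]] = {}
        for s in usable:
            by_subj.setdefault(s.subject_id, []).append(s)
        baselines = []
        for sid in sorted(by_subj):
            scans = sorted(by_subj[sid], key=lambda s: s.age)
            baselines.append(prediction_error(scans[0].points, scans[-1],
                                              subject_id=sid, age_from=scans[0].age))
        comp = baseline_comparison(results, baselines)
        comparisons[cohort] = {
            "mean_improvement_mm": comp.mean_improvement,
            "t": comp.t_statistic, "p": comp.p_value, "n": comp.n,
            "degenerate": comp.degenerate,
            "mean_error_mm": float(np.mean([r.mean_error for r in results])),
            "baseline_error_mm": float(np.mean([r.mean_error for r in baselines])),
        }
        base_by_id = {r.subject_id: r for r in baselines}
        for r in results:
            rows.append({"sex": sex, "cohort": cohort, "subject_id": r.subject_id,
                         "age_from": r.age_from, "age_to": r.age_to,
                         "mean_error_mm": r.mean_error,
                         "baseline_error_mm": base_by_id[r.subject_id].mean_error})
        _log(out, f"[evaluate:{sex}:{cohort}] n={comp.n} "
                  f"err={comparisons[cohort]['mean_error_mm']:.2f}mm "
                  f"baseline={comparisons[cohort]['baseline_error_mm']:.2f}mm p={comp.p_value:.2g}")
    df = pd.DataFrame(rows)
    df.to_csv(csv_p, index=False)
    cmp_p.write_text(json.dumps(comparisons, indent=1) + "\n")
    cache.update(f"evaluate_{sex}", key)
    return df, comparisons, key


def _stage_bmi(cfg: PipelineConfig, out: Path, cache: _Cache, manifest_df: pd.DataFrame,
               eval_df: pd.DataFrame, sex: str, up_key: str):
    key = _sha("bmi", up_key, cfg.bmi_regressor, cfg.lms_reference or "synthetic")
    csv_p = out / f"bmi_{sex}.csv"
    json_p = out / f"bmi_{sex}.json"
    if cache.fresh(f"bmi_{sex}", key, [csv_p, json_p]):
        _log(out, f"[bmi:{sex}] cache hit")
        return pd.read_csv(csv_p), json.loads(json_p.read_text()), key
    ref = (anthro.read_lms_reference(cfg.lms_reference) if cfg.lms_reference
           else anthro.synthetic_lms_reference())
    sub = manifest_df[manifest_df.sex == sex]
    rows = []
    err_by_subject = (eval_df.groupby("subject_id").mean_error_mm.mean()
                      if len(eval_df) else pd.Series(dtype=float))
    for sid, grp in sub.groupby("subject_id"):
        grp = grp.sort_values("age")
        pcts = [anthro.lms_percentile(anthro.bmi(r.weight_kg, r.height_m), r.age, sex, ref)
                for r in grp.itertuples()]
        if sid not in err_by_subject.index:
            continue
        rows.append({"subject_id": sid,
                     "start_percentile": pcts[0], "end_percentile": pcts[-1],
                     "delta_percentile": pcts[-1] - pcts[0],
                     "mean_error_mm": float(err_by_subject[sid]),
                     "group": anthro.weight_group(pcts[0])})
    df = pd.DataFrame(rows)
    df.to_csv(csv_p, index=False)
    if len(df) >= 3:
        x = df.delta_percentile.to_numpy() if cfg.bmi_regressor == "delta" \
            else df.start_percentile.to_numpy()
        model = anthro.error_vs_bmi_change(x, df.mean_error_mm.to_numpy())
        json_p.write_text(json.dumps(asdict(model), indent=1) + "\n")
        plot_bmi_scatter(df.delta_percentile.to_numpy(), df.mean_error_mm.to_numpy(),
                         df.start_percentile.to_numpy(), model, out / f"bmi_{sex}.png",
                         title=f"sex {sex}")
        result = asdict(model)
        _log(out, f"[bmi:{sex}] slope={model.slope:.4g} F={model.F:.3g} p={model.p_value:.3g}")
    else:
        result = {}
        json_p.write_text("{}\n")
        _log(out, f"[bmi:{sex}] fewer than 3 subjects with errors; regression skipped")
    cache.update(f"bmi_{sex}", key)
    return df, result, key


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict (also written to summary.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _Cache(out)
    _log(out, f"[run] config: {json.dumps(asdict(cfg))}")
    ds, k1 = _stage_correspond(cfg, out, cache)
    manifest_df = pd.read_csv(cfg.manifest)
    sexes = [cfg.sex_filter] if cfg.sex_filter else sorted(set(ds.sexes))
    summary: dict = {"config": asdict(cfg), "sexes": {}}
    for sex in sexes:
        try:
            aligned, space, consensus, k2 = _stage_space(cfg, out, cache, ds, k1, sex)
            k3 = _stage_maps(cfg, out, cache, ds, aligned, sex, k2)
            traj, k4 = _stage_trajectory(cfg, out, cache, aligned, space, sex, k2)
            eval_df, comparisons, k5 = _stage_evaluate(cfg, out, cache, ds, aligned,
                                                       space, traj, sex, k4)
            bmi_df, bmi_model, k6 = _stage_bmi(cfg, out, cache, manifest_df, eval_df, sex, k5)
        except (ValidationError, PipelineStageError) as exc:
            raise PipelineStageError(f"sex {sex}: {exc}") from exc
        summary["sexes"][sex] = {
            "n_scans": int((ds.sexes == sex).sum()),
            "n_components": space.n_components,
            "explained_fraction": [float(f) for f in space.explained_fraction],
            "knots": list(traj.knots),
            "comparisons": comparisons,
            "bmi_anova": bmi_model,
        }
    summary["retained_vertices"] = int(ds.mask.sum())
    (out / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    return summary
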