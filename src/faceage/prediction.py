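"""Age progression/regression of specimens and evaluation against ground truth.

A specimen is aged by moving its PC scores along the global trajectory:
``s' = s + T(age_to) − T(age_from)``, then reconstructing the surface from
``s'``. The subject's individual deviation from the mean face travels with
them unchanged; only the population ageing displacement is added, so the
same formula runs backwards for age regression. Prediction error is the
per-vertex Euclidean distance to the known (GPA-aligned) surface at the
target age, and the non-aged baseline simply reuses the young face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .shape_space import AlignedSample, ShapeSpace, from_scores, to_scores
from .trajectory import GlobalTrajectory, evaluate_trajectory

__all__ = [
    "PredictionResult",
    "BaselineComparison",
    "age_transform",
    "prediction_error",
    "cohort_evaluation",
    "baseline_comparison",
]


@dataclass
class PredictionResult:
    subject_id: str
    age_from: float
    age_to: float
    predicted_points: np.ndarray       # (Vr, 3) mm
    per_vertex_error: np.ndarray | None = None
    mean_error: float | None = None


@dataclass
class BaselineComparison:
    mean_improvement: float            # mm, mean(baseline − aged)
    t_statistic: float
    p_value: float                     # two-sided
    n: int
    degenerate: bool = False           # zero variance of paired differences


def age_transform(sample: AlignedSample, age_to: float, traj: GlobalTrajectory,
                  space: ShapeSpace, *, allow_extrapolation: bool = False) -> np.ndarray:
    """Predict the subject's surface at `age_to` (forward or retrospective)."""
    if traj.sex and space.sex and traj.sex != space.sex:
        raise ValidationError(f"trajectory sex {traj.sex} != space sex {space.sex}")
    if space.sex and sample.sex and sample.sex != space.sex:
        raise ValidationError(f"sample sex {sample.sex} != space sex {space.sex}")
    s = to_scores(sample, space).scores
    delta = (evaluate_trajectory(traj, age_to, allow_extrapolation=allow_extrapolation)
             - evaluate_trajectory(traj, sample.age, allow_extrapolation=allow_extrapolation))
    return from_scores(s + delta, space)


def prediction_error(predicted: np.ndarray, actual: AlignedSample,
                     *, subject_id: str | None = None,
                     age_from: float | None = None) -> PredictionResult:
    """Per-vertex Euclidean distances between prediction and known face."""
    P = np.asarray(predicted, dtype=float)
    A = actual.points
    if P.shape != A.shape:
        raise ValidationError(f"shape mismatch: predicted {P.shape} vs actual {A.shape}")
    d = np.linalg.norm(P - A, axis=1)
    return PredictionResult(
        subject_id=subject_id or actual.subject_id,
        age_from=actual.age if age_from is None else age_from,
        age_to=actual.age,
        predicted_points=P, per_vertex_error=d, mean_error=float(d.mean()),
    )


def cohort_evaluation(aligned: list[AlignedSample], traj: GlobalTrajectory,
                      space: ShapeSpace, *, allow_extrapolation: bool = False,
                      ) -> tuple[list[PredictionResult], np.ndarray]:
    """Youngest → oldest prediction for every subject; plus the group error map.

    Subjects with a single scan are skipped. The group map is the
    per-vertex mean of the per-subject error maps (subject-first
    averaging, the canonical order; the scalar group mean error is the
    mean of per-subject mean errors).
    """
    by_subject: dict[str, list[AlignedSample]] = {}
    for s in aligned:
        by_subject.setdefault(s.subject_id, []).append(s)
    results: list[PredictionResult] = []
    maps = []
    for sid in sorted(by_subject):
        scans = sorted(by_subject[sid], key=lambda s: s.age)
        if len(scans) < 2:
            continue
        youngest, oldest = scans[0], scans[-1]
        pred = age_transform(youngest, oldest.age, traj, space,
                             allow_extrapolation=allow_extrapolation)
        res = prediction_error(pred, oldest, subject_id=sid, age_from=youngest.age)
        results.append(res)
        maps.append(res.per_vertex_error)
    if not results:
        raise ValidationError("no subject has >= 2 scans")
    return results, np.mean(maps, axis=0)


def baseline_comparison(results_aged: list[PredictionResult],
                        results_baseline: list[PredictionResult]) -> BaselineComparison:
    """Paired t-test of aged vs non-aged per-subject mean errors.

    Positive `mean_improvement` means the ageing model beats the non-aged
    baseline. A zero-variance set of paired differences is flagged
    `degenerate`: p = 1 if the differences are all zero, else p = 0 with
    an infinite t in the direction of the shift.
    """
    a = {r.subject_id: r.mean_error for r in results_aged}
    b = {r.subject_id: r.mean_error for r in results_baseline}
    if set(a) != set(b):
        raise ValidationError("aged and baseline results cover different subjects")
    if len(a) < 3:
        raise ValidationError("paired t-test needs n >= 3 subjects")
    ids = sorted(a)
    diff = np.array([b[i] - a[i] for i in ids])
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return BaselineComparison(0.0, 0.0, 1.0, len(ids), degenerate=True)
        return BaselineComparison(mean, float(np.sign(mean)) * np.inf, 0.0,
                                  len(ids), degenerate=True)
    t, p = stats.ttest_rel([b[i] for i in ids], [a[i] for i in ids])
    return BaselineComparison(mean, float(t), float(p), len(ids))
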