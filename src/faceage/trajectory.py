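"""Ageing trajectories in PC-score space.

Each subject's PC scores are modelled as a straight line in age; cohort
models average the per-subject intercepts and slopes; the two cohort
lines (roughly 7–12 and 12–17 years) are joined by a cubic Hermite
segment between the cohort centres, yielding a single C¹ trajectory
``T(age)`` per sex. Translating a specimen's scores by
``T(age_to) − T(age_from)`` ages (or rejuvenates) it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "LinearAgeModel",
    "GlobalTrajectory",
    "fit_series_linear",
    "group_mean_model",
    "hermite_glue",
    "evaluate_trajectory",
    "trajectory_speed",
    "save_trajectory",
    "load_trajectory",
]


@dataclass
class LinearAgeModel:
    """Scores ≈ intercept + slope · age (componentwise), over one age range."""

    intercept: np.ndarray         # (K,)
    slope: np.ndarray             # (K,) per year
    age_range: tuple[float, float]
    n_subjects: int = 1

    def __post_init__(self) -> None:
        self.intercept = np.asarray(self.intercept, dtype=float).reshape(-1)
        self.slope = np.asarray(self.slope, dtype=float).reshape(-1)
        if self.intercept.shape != self.slope.shape:
            raise ValidationError("intercept/slope dimension mismatch")
        a, b = self.age_range
        if not a < b:
            raise ValidationError(f"degenerate age range {self.age_range}")

    @property
    def centre(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def __call__(self, age: float) -> np.ndarray:
        return self.intercept + self.slope * age


@dataclass
class GlobalTrajectory:
    """Two cohort lines glued by a cubic Hermite segment between their centres."""

    young: LinearAgeModel
    old: LinearAgeModel
    sex: str = ""

    def __post_init__(self) -> None:
        if self.young.centre >= self.old.centre:
            raise ValidationError("young cohort centre must precede old cohort centre")
        if len(self.young.intercept) != len(self.old.intercept):
            raise ValidationError("cohort models have different K")

    @property
    def knots(self) -> tuple[float, float]:
        return (self.young.centre, self.old.centre)


def fit_series_linear(series_scores: list[tuple[float, np.ndarray]]) -> LinearAgeModel:
    """OLS line through one subject's (age, score-vector) observations."""
    if len(series_scores) < 2:
        raise ValidationError("need at least 2 observations")
    ages = np.array([a for a, _ in series_scores], dtype=float)
    Y = np.stack([np.asarray(s, dtype=float) for _, s in series_scores])   # (n, K)
    if np.ptp(ages) <= 0:
        raise ValidationError("all ages equal; cannot fit a line")
    A = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return LinearAgeModel(intercept=coef[0], slope=coef[1],
                          age_range=(float(ages.min()), float(ages.max())))


def group_mean_model(models: list[LinearAgeModel]) -> LinearAgeModel:
    """Cohort model: arithmetic mean of per-subject intercepts and slopes."""
    if not models:
        raise ValidationError("empty model list")
    K = {len(m.intercept) for m in models}
    if len(K) != 1:
        raise ValidationError("models have inconsistent K")
    return LinearAgeModel(
        intercept=np.mean([m.intercept for m in models], axis=0),
        slope=np.mean([m.slope for m in models], axis=0),
        age_range=(min(m.age_range[0] for m in models),
                   max(m.age_range[1] for m in models)),
        n_subjects=len(models),
    )


def hermite_glue(young: LinearAgeModel, old: LinearAgeModel, sex: str = "") -> GlobalTrajectory:
    """Join two cohort lines with the unique C¹ cubic between their centres.

    Knots sit at the cohort age-range midpoints; on [c_y, c_o] the
    trajectory is the componentwise cubic Hermite interpolant with
    endpoint values young(c_y), old(c_o) and endpoint derivatives equal to
    the cohort slopes. Outside the knots it follows the respective line.
    """
    return GlobalTrajectory(young=young, old=old, sex=sex)


def evaluate_trajectory(traj: GlobalTrajectory, age, *,
                        allow_extrapolation: bool = False,
                        guard: tuple[float, float] = (6.0, 18.0)) -> np.ndarray:
    """Evaluate the global trajectory at one age or an array of ages.

    Ages outside the guard band raise unless `allow_extrapolation` is set.
    Returns (K,) for a scalar age, (len(ages), K) for an array.
    """
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    if not allow_extrapolation and ((ages < guard[0]).any() or (ages > guard[1]).any()):
        raise ValidationError(
            f"age outside guard band {guard}; pass allow_extrapolation=True to override"
        )
    c_y, c_o = traj.knots
    h = c_o - c_y
    out = np.empty((len(ages), len(traj.young.intercept)))
    for i, a in enumerate(ages):
        if a <= c_y:
            out[i] = traj.young(a)
        elif a >= c_o:
            out[i] = traj.old(a)
        else:
            t = (a - c_y) / h
            h00 = 2 * t**3 - 3 * t**2 + 1
            h10 = t**3 - 2 * t**2 + t
            h01 = -2 * t**3 + 3 * t**2
            h11 = t**3 - t**2
            out[i] = (h00 * traj.young(c_y) + h10 * h * traj.young.slope
                      + h01 * traj.old(c_o) + h11 * h * traj.old.slope)
    return out[0] if np.isscalar(age) or np.ndim(age) == 0 else out


def trajectory_speed(traj: GlobalTrajectory, age, *, h: float = 1e-3,
                     allow_extrapolation: bool = True) -> np.ndarray:
    """Central-difference speed ‖dT/dage‖ (score units per year)."""
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    lo = evaluate_trajectory(traj, ages - h, allow_extrapolation=allow_extrapolation)
    hi = evaluate_trajectory(traj, ages + h, allow_extrapolation=allow_extrapolation)
    speed = np.linalg.norm(hi - lo, axis=-1) / (2 * h)
    return speed[0] if np.ndim(age) == 0 else speed


def fit_global_trajectory(subject_scores: dict[str, list[tuple[float, np.ndarray]]],
                          split_age: float = 12.0, sex: str = "",
                          ) -> tuple[GlobalTrajectory, list[LinearAgeModel], list[LinearAgeModel]]:
    """Fit the full per-sex trajectory from per-subject score series.

    Each subject's observations are split at `split_age` into a young
    (age <= split) and an old (age >= split) sub-series — a subject
    spanning the split contributes one series to each cohort, and the
    split-age scan belongs to both. Sub-series with fewer than two
    observations are ignored. Per-subject lines are averaged into cohort
    models, which are then Hermite-glued.
    """
    young_models, old_models = [], []
    for sid in sorted(subject_scores):
        obs = sorted(subject_scores[sid], key=lambda t: t[0])
        young = [(a, s) for a, s in obs if a <= split_age]
        old = [(a, s) for a, s in obs if a >= split_age]
        if len(young) >= 2:
            young_models.append(fit_series_linear(young))
        if len(old) >= 2:
            old_models.append(fit_series_linear(old))
    if not young_models or not old_models:
        raise ValidationError("need at least one subject series per cohort")
    return (hermite_glue(group_mean_model(young_models), group_mean_model(old_models), sex),
            young_models, old_models)


def save_trajectory(traj: GlobalTrajectory, path: str | Path) -> None:
    data = {
        "sex": traj.sex,
        "knots": list(traj.knots),
        "young": {"intercept": traj.young.intercept.tolist(),
                  "slope": traj.young.slope.tolist(),
                  "age_range": list(traj.young.age_range),
                  "n_subjects": traj.young.n_subjects},
        "old": {"intercept": traj.old.intercept.tolist(),
                "slope": traj.old.slope.tolist(),
                "age_range": list(traj.old.age_range),
                "n_subjects": traj.old.n_subjects},
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def load_trajectory(path: str | Path) -> GlobalTrajectory:
    d = json.loads(Path(path).read_text())

    def _model(m):
        return LinearAgeModel(np.array(m["intercept"]), np.array(m["slope"]),
                              tuple(m["age_range"]), m.get("n_subjects", 1))

    return GlobalTrajectory(young=_model(d["young"]), old=_model(d["old"]), sex=d["sex"])
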