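"""BMI, LMS/Box-Cox growth percentiles, and prediction-error-vs-BMI ANOVA.

The LMS method summarises a growth reference (here: BMI-for-age, per sex)
by three age-varying curves — the Box-Cox power L, the median M and the
coefficient of variation S. A measurement x at a given age maps to

    z = ((x / M)^L − 1) / (L · S)   if L != 0
    z = ln(x / M) / S               if L == 0

and percentile = 100 · Phi(z). National reference tables are proprietary
in many countries; this package ships a clearly-labelled *synthetic*
reference (see :func:`synthetic_lms_reference`) and reads user-supplied
CSV references with columns ``sex,age,L,M,S``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "LmsReference",
    "BmiRecord",
    "BmiAnova",
    "bmi",
    "lms_percentile",
    "lms_bmi_from_percentile",
    "error_vs_bmi_change",
    "synthetic_lms_reference",
    "read_lms_reference",
    "write_lms_reference",
    "weight_group",
    "WEIGHT_GROUP_CUTS",
]

#: BMI-percentile cut points used for weight classification: below 25 =
#: reduced weight, 25–75 normal, 75–90 overweight signal, above 90
#: overweight, above 97 obese. Only <25 / 25–75 / >75 are used for the
#: three-group scatter plots.
WEIGHT_GROUP_CUTS = (25.0, 75.0, 90.0, 97.0)


@dataclass
class LmsReference:
    """Per-sex grids of (age → L, M, S), linearly interpolated in age."""

    tables: dict[str, pd.DataFrame]    # sex -> DataFrame[age, L, M, S]

    def __post_init__(self) -> None:
        for sex, df in self.tables.items():
            for col in ("age", "L", "M", "S"):
                if col not in df.columns:
                    raise ValidationError(f"LMS table for {sex} missing column {col}")
            ages = df["age"].to_numpy()
            if not (np.diff(ages) > 0).all():
                raise ValidationError(f"LMS ages for {sex} not strictly increasing")
            if (df["M"] <= 0).any() or (df["S"] <= 0).any():
                raise ValidationError(f"LMS M and S must be positive ({sex})")
            if ages.min() > 6.0 or ages.max() < 18.0:
                raise ValidationError(f"LMS grid for {sex} must cover [6, 18] years")

    def lms_at(self, age: float, sex: str) -> tuple[float, float, float]:
        df = self.tables[sex]
        ages = df["age"].to_numpy()
        if not (ages[0] <= age <= ages[-1]):
            raise ValidationError(f"age {age} outside LMS grid [{ages[0]}, {ages[-1]}]")
        return tuple(float(np.interp(age, ages, df[c].to_numpy())) for c in ("L", "M", "S"))


@dataclass
class BmiRecord:
    subject_id: str
    age: float
    bmi: float
    percentile: float

    def __post_init__(self) -> None:
        if self.bmi <= 0:
            raise ValidationError("BMI must be positive")


@dataclass
class BmiAnova:
    """Simple regression of prediction error on ΔBMI percentile + its ANOVA."""

    slope: float
    intercept: float
    F: float
    p_value: float
    r_squared: float
    n: int


def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index: weight (kg) / height^2 (m^2)."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValidationError("weight and height must be positive")
    return weight_kg / (height_m * height_m)


def lms_percentile(value: float, age: float, sex: str, ref: LmsReference) -> float:
    """BMI percentile in [0, 100] via the LMS/Box-Cox z-score."""
    if value <= 0:
        raise ValidationError("measurement must be positive")
    L, M, S = ref.lms_at(age, sex)
    if abs(L) < 1e-12:
        z = np.log(value / M) / S
    else:
        z = ((value / M) ** L - 1.0) / (L * S)
    return float(100.0 * stats.norm.cdf(z))


def lms_bmi_from_percentile(percentile: float, age: float, sex: str, ref: LmsReference) -> float:
    """Inverse of :func:`lms_percentile` (used by the synthetic generator)."""
    if not (0 < percentile < 100):
        raise ValidationError("percentile must be in (0, 100)")
    L, M, S = ref.lms_at(age, sex)
    z = stats.norm.ppf(percentile / 100.0)
    if abs(L) < 1e-12:
        return float(M * np.exp(S * z))
    return float(M * (1.0 + L * S * z) ** (1.0 / L))


def weight_group(percentile: float) -> str:
    """Three-way grouping used in the scatter plots: <25, 25-75, >75."""
    if percentile < WEIGHT_GROUP_CUTS[0]:
        return "<25"
    if percentile <= WEIGHT_GROUP_CUTS[1]:
        return "25-75"
    return ">75"


def error_vs_bmi_change(delta_percentile: np.ndarray, mean_error: np.ndarray) -> BmiAnova:
    """OLS of per-subject mean prediction error on ΔBMI percentile, with ANOVA.

    The F test (regression vs residual, df 1 and n − 2) decides whether
    BMI-percentile change explains prediction error. Fitted with
    statsmodels OLS.
    """
    x = np.asarray(delta_percentile, dtype=float)
    y = np.asarray(mean_error, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need >= 3 paired (delta_percentile, mean_error) values")
    if np.ptp(x) <= 0:
        raise ValidationError("zero variance in delta_percentile")
    import statsmodels.api as sm
    model = sm.OLS(y, sm.add_constant(x)).fit()
    F = float(model.fvalue) if np.isfinite(model.fvalue) else 0.0
    p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 1.0
    return BmiAnova(slope=float(model.params[1]), intercept=float(model.params[0]),
                    F=F, p_value=p, r_squared=float(model.rsquared), n=len(x))


# ---------------------------------------------------------------------------
# references

def synthetic_lms_reference() -> LmsReference:
    """SYNTHETIC BMI-for-age LMS reference (not any national standard).

    Smooth curves with plausible magnitudes for ages 5–19: the median BMI
    rises from ~15.4 kg/m² at age 6 to ~21 kg/m² at 18, the coefficient
    of variation grows slightly with age and the Box-Cox power is
    negative (right-skewed BMI distributions). Girls and boys differ by a
    small offset of the median. Intended for tests and synthetic-cohort
    generation only; real analyses should load a national table via
    :func:`read_lms_reference`.
    """
    ages = np.arange(5.0, 19.5, 0.5)
    u = (ages - 6.0) / 12.0
    tables = {}
    for sex, off in (("F", 0.0), ("M", 0.25)):
        M = 15.4 + 5.6 * np.clip(u, 0, None) ** 1.3 + off * np.clip(u, 0, None)
        L = -1.2 - 0.6 * u
        S = 0.10 + 0.02 * u
        tables[sex] = pd.DataFrame({"age": ages, "L": L, "M": M, "S": S})
    return LmsReference(tables)


def read_lms_reference(path: str | Path) -> LmsReference:
    """Read an LMS reference CSV with columns ``sex,age,L,M,S``."""
    df = pd.read_csv(path)
    missing = {"sex", "age", "L", "M", "S"} - set(df.columns)
    if missing:
        raise ValidationError(f"LMS reference missing columns {sorted(missing)}")
    tables = {sex: grp.sort_values("age").reset_index(drop=True)
              for sex, grp in df.groupby("sex")}
    return LmsReference(tables)


def write_lms_reference(ref: LmsReference, path: str | Path) -> None:
    rows = []
    for sex, df in ref.tables.items():
        out = df[["age", "L", "M", "S"]].copy()
        out.insert(0, "sex", sex)
        rows.append(out)
    pd.concat(rows).to_csv(path, index=False)
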