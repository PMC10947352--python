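"""Study-level data model, CSV I/O, summary-statistic imputation and
eligibility screening.

Each row of the study table is one study arm reporting aggregate axial-length
(AL, mm) and age (years) summaries for its emmetropic subsample.  Studies may
report mean +/- SD directly or only order statistics (median, quartiles,
range); in the latter case the mean and SD are imputed with the Wan et al.
(2014) estimators before any downstream analysis.

Screening applies the meta-regression eligibility rules: optical biometry,
an emmetropia window contained in [-0.50, +1.25] D spherical equivalent,
cycloplegic refraction unless mean age >= 20 years, mean age within 6-30
years, and emmetrope-specific AL summaries.  Rules are applied in a fixed
order so the recorded exclusion reason is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import norm

__all__ = [
    "ReportedDistribution",
    "StudyRecord",
    "ScreeningCriteria",
    "ScreeningDecision",
    "ScreeningReason",
    "SchemaError",
    "ImputationError",
    "read_studies",
    "write_studies",
    "impute_mean_sd",
    "resolve_age",
    "screen_study",
    "screen_corpus",
    "STUDY_COLUMNS",
]

# Plausibility window for axial length means (mm); rejects unit errors at read
# time (e.g., values entered in cm).
AL_PLAUSIBLE = (18.0, 28.0)
AGE_PLAUSIBLE = (0.0, 40.0)


class SchemaError(ValueError):
    """The study table is missing a mandatory column or value."""


class ImputationError(ValueError):
    """Reported summaries are insufficient to impute mean and SD."""


@dataclass(frozen=True)
class ReportedDistribution:
    """Aggregate summaries a study reports for one continuous variable."""

    n: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    min: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        order = [("min", self.min), ("q1", self.q1), ("median", self.median),
                 ("q3", self.q3), ("max", self.max)]
        present = [(name, v) for name, v in order if v is not None]
        for (n1, v1), (n2, v2) in zip(present, present[1:]):
            if v1 > v2:
                raise ValueError(f"order statistics violated: {n1}={v1} > {n2}={v2}")

    @property
    def has_moments(self) -> bool:
        return self.mean is not None and self.sd is not None


class ScreeningReason(str, Enum):
    OK = "ok"
    NO_EMMETROPE_AL = "no_emmetrope_al"
    NONCYCLO_YOUNG = "noncyclo_young"
    ULTRASOUND_AL = "ultrasound_al"
    SER_WINDOW_VIOLATION = "ser_window_violation"
    AGE_OUT_OF_RANGE = "age_out_of_range"
    AGE_IMPUTATION_REFUSED = "age_imputation_refused"


@dataclass(frozen=True)
class ScreeningDecision:
    eligible: bool
    reason: ScreeningReason

    def __post_init__(self) -> None:
        if self.eligible != (self.reason is ScreeningReason.OK):
            raise ValueError("reason must be 'ok' exactly when eligible")


@dataclass(frozen=True)
class ScreeningCriteria:
    """Eligibility thresholds; defaults are the meta-regression's rules."""

    ser_window: tuple[float, float] = (-0.50, 1.25)
    cycloplegia_age_cutoff: float = 20.0
    age_range: tuple[float, float] = (6.0, 30.0)
    require_optical: bool = True
    require_emmetrope_al: bool = True


@dataclass(frozen=True)
class StudyRecord:
    """One study arm's reported emmetrope summaries and eligibility metadata."""

    study_id: str
    region: str
    group: str  # "EA" | "nonEA"
    n_emmetropes: int
    age: ReportedDistribution  # years
    al: ReportedDistribution  # mm
    ser_lower: float  # D
    ser_upper: float  # D
    cycloplegia: bool
    biometry: str  # "optical" | "ultrasound" | "other"
    age_is_whole_sample: bool = False
    whole_sample_age_range: float | None = None
    al_is_emmetrope_specific: bool = True
    prop_male: float | None = None

    def __post_init__(self) -> None:
        if self.n_emmetropes < 1:
            raise ValueError("n_emmetropes must be >= 1")
        if self.group not in ("EA", "nonEA"):
            raise ValueError(f"group must be 'EA' or 'nonEA', got {self.group!r}")
        if not self.ser_lower < self.ser_upper:
            raise ValueError("ser_lower must be < ser_upper")
        if self.biometry not in ("optical", "ultrasound", "other"):
            raise ValueError(f"unknown biometry {self.biometry!r}")
        if self.prop_male is not None and not 0 <= self.prop_male <= 1:
            raise ValueError("prop_male must lie in [0, 1]")


# CSV schema: one study arm per row, empty cell = absent.
STUDY_COLUMNS = [
    "study_id", "region", "group", "n",
    "age_mean", "age_sd", "age_median", "age_q1", "age_q3", "age_min", "age_max",
    "age_is_whole_sample", "whole_sample_age_range",
    "al_mean", "al_sd", "al_median", "al_q1", "al_q3", "al_min", "al_max",
    "ser_lower", "ser_upper", "cycloplegia", "biometry", "prop_male",
]
_MANDATORY = ["study_id", "group", "n", "ser_lower", "ser_upper",
              "cycloplegia", "biometry"]


def _num(value, col: str, idx: int) -> float:
    """Parse a signed numeric cell, accepting the Unicode minus sign."""
    if isinstance(value, str):
        value = value.replace("−", "-").strip()
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"row {idx}: unparseable numeric in column {col!r}: "
                          f"{value!r}") from exc


def read_studies(path, schema: dict[str, str] | None = None) -> list[StudyRecord]:
    """Read a study table CSV into StudyRecords.

    ``schema`` optionally maps canonical column names to the file's column
    names.  Missing optional summaries come back as None, never zero.
    Raises SchemaError naming the first missing mandatory column, or the row
    index of the first unparseable numeric cell.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    has_al_center = any(c in df.columns for c in ("al_mean", "al_median"))
    if not has_al_center:
        raise SchemaError("mandatory column 'al_mean' (or 'al_median') missing "
                          f"from {path}")
    records: list[StudyRecord] = []
    for idx, raw in df.iterrows():
        row = {c: (raw[c] if c in df.columns and raw[c] != "" else None)
               for c in STUDY_COLUMNS}

        def opt(col: str) -> float | None:
            v = row.get(col)
            return None if v is None else _num(v, col, idx)

        n = int(_num(row["n"], "n", idx))
        age = ReportedDistribution(
            n=n, mean=opt("age_mean"), sd=opt("age_sd"), median=opt("age_median"),
            q1=opt("age_q1"), q3=opt("age_q3"), min=opt("age_min"),
            max=opt("age_max"))
        al = ReportedDistribution(
            n=n, mean=opt("al_mean"), sd=opt("al_sd"), median=opt("al_median"),
            q1=opt("al_q1"), q3=opt("al_q3"), min=opt("al_min"), max=opt("al_max"))
        for label, dist, (lo, hi) in (("al", al, AL_PLAUSIBLE),
                                      ("age", age, AGE_PLAUSIBLE)):
            center = dist.mean if dist.mean is not None else dist.median
            if center is not None and not lo <= center <= hi:
                raise SchemaError(
                    f"row {idx}: {label} center {center} outside plausibility "
                    f"window [{lo}, {hi}]")
        records.append(StudyRecord(
            study_id=str(row["study_id"]),
            region=str(row["region"] or ""),
            group=str(row["group"]),
            n_emmetropes=n,
            age=age,
            al=al,
            age_is_whole_sample=bool(int(row["age_is_whole_sample"] or 0)),
            whole_sample_age_range=opt("whole_sample_age_range"),
            ser_lower=_num(row["ser_lower"], "ser_lower", idx),
            ser_upper=_num(row["ser_upper"], "ser_upper", idx),
            cycloplegia=bool(int(row["cycloplegia"])),
            biometry=str(row["biometry"]),
            prop_male=opt("prop_male"),
        ))
    return records


def write_studies(records: Iterable[StudyRecord], path) -> None:
    """Write StudyRecords to the canonical CSV schema (empty cell = absent)."""
    rows = []
    for r in records:
        rows.append({
            "study_id": r.study_id, "region": r.region, "group": r.group,
            "n": r.n_emmetropes,
            "age_mean": r.age.mean, "age_sd": r.age.sd, "age_median": r.age.median,
            "age_q1": r.age.q1, "age_q3": r.age.q3, "age_min": r.age.min,
            "age_max": r.age.max,
            "age_is_whole_sample": int(r.age_is_whole_sample),
            "whole_sample_age_range": r.whole_sample_age_range,
            "al_mean": r.al.mean, "al_sd": r.al.sd, "al_median": r.al.median,
            "al_q1": r.al.q1, "al_q3": r.al.q3, "al_min": r.al.min,
            "al_max": r.al.max,
            "ser_lower": r.ser_lower, "ser_upper": r.ser_upper,
            "cycloplegia": int(r.cycloplegia), "biometry": r.biometry,
            "prop_male": r.prop_male,
        })
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, index=False)


def impute_mean_sd(dist: ReportedDistribution) -> tuple[float, float]:
    """Mean and SD, imputed from order statistics when not reported.

    Reported mean and SD pass through unchanged.  Otherwise the Wan et al.
    (2014) estimators apply, by scenario:

    * median + range:      mean = (min + 2*median + max) / 4,
                           sd = (max - min) / (2 * Phi^-1((n - 0.375)/(n + 0.25)))
    * median + IQR:        mean = (q1 + median + q3) / 3,
                           sd = (q3 - q1) / (2 * Phi^-1((0.75n - 0.125)/(n + 0.25)))
    * all five numbers:    mean = (min + 2*q1 + 2*median + 2*q3 + max) / 8,
                           sd = average of the two SD estimators above.
    """
    if dist.has_moments:
        return float(dist.mean), float(dist.sd)
    if dist.median is None:
        raise ImputationError(
            "cannot impute: need mean+sd, or median with quartiles and/or range; "
            "missing: median")
    have_iqr = dist.q1 is not None and dist.q3 is not None
    have_range = dist.min is not None and dist.max is not None
    if not (have_iqr or have_range):
        missing = []
        if not have_iqr:
            missing.append("q1/q3")
        if not have_range:
            missing.append("min/max")
        raise ImputationError(
            "cannot impute sd from median alone; missing: " + " and ".join(missing))
    n = dist.n
    if n < 2:
        raise ImputationError("sd undefined for n < 2 with only spread statistics")

    def sd_from_range() -> float:
        return (dist.max - dist.min) / (2 * norm.ppf((n - 0.375) / (n + 0.25)))

    def sd_from_iqr() -> float:
        return (dist.q3 - dist.q1) / (2 * norm.ppf((0.75 * n - 0.125) / (n + 0.25)))

    if have_iqr and have_range:
        mean = (dist.min + 2 * dist.q1 + 2 * dist.median + 2 * dist.q3
                + dist.max) / 8
        sd = (sd_from_range() + sd_from_iqr()) / 2
    elif have_iqr:
        mean = (dist.q1 + dist.median + dist.q3) / 3
        sd = sd_from_iqr()
    else:
        mean = (dist.min + 2 * dist.median + dist.max) / 4
        sd = sd_from_range()
    return float(mean), float(sd)


def resolve_age(record: StudyRecord) -> tuple[float, float] | ScreeningDecision:
    """Resolve the emmetrope age mean/SD, or refuse.

    Emmetrope-specific ages pass through (imputed if needed).  Whole-sample
    ages stand in only when the whole-sample age range is known and no larger
    than 3 years; otherwise a refusal decision is returned.
    """
    if record.age_is_whole_sample:
        if (record.whole_sample_age_range is None
                or record.whole_sample_age_range > 3.0):
            return ScreeningDecision(
                eligible=False, reason=ScreeningReason.AGE_IMPUTATION_REFUSED)
    return impute_mean_sd(record.age)


def screen_study(record: StudyRecord,
                 criteria: ScreeningCriteria = ScreeningCriteria()
                 ) -> ScreeningDecision:
    """Apply the eligibility rules in fixed order; first failure wins.

    Order: optical biometry; emmetropia window containment; resolvable age;
    cycloplegia (unless mean age at or above the cutoff); mean age within the
    target window; emmetrope-specific AL.
    """
    if criteria.require_optical and record.biometry != "optical":
        return ScreeningDecision(False, ScreeningReason.ULTRASOUND_AL)
    lo, hi = criteria.ser_window
    if record.ser_lower < lo or record.ser_upper > hi:
        return ScreeningDecision(False, ScreeningReason.SER_WINDOW_VIOLATION)
    age_res = resolve_age(record)
    if isinstance(age_res, ScreeningDecision):
        return age_res
    age_mean = age_res[0]
    if not record.cycloplegia and age_mean < criteria.cycloplegia_age_cutoff:
        return ScreeningDecision(False, ScreeningReason.NONCYCLO_YOUNG)
    a_lo, a_hi = criteria.age_range
    if not a_lo <= age_mean <= a_hi:
        return ScreeningDecision(False, ScreeningReason.AGE_OUT_OF_RANGE)
    if criteria.require_emmetrope_al and not record.al_is_emmetrope_specific:
        return ScreeningDecision(False, ScreeningReason.NO_EMMETROPE_AL)
    return ScreeningDecision(True, ScreeningReason.OK)


def screen_corpus(records: Sequence[StudyRecord],
                  criteria: ScreeningCriteria = ScreeningCriteria()
                  ) -> pd.DataFrame:
    """Screen every record; returns study_id, eligible, reason rows."""
    rows = [{"study_id": r.study_id,
             "eligible": (d := screen_study(r, criteria)).eligible,
             "reason": d.reason.value}
            for r in records]
    return pd.DataFrame(rows, columns=["study_id", "eligible", "reason"])
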