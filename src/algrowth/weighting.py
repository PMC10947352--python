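"""Precision weighting of study-level observations.

Each study entering a fit gets the weight

    W_i = 1 / (norm(SE of AL)_i + norm(SE of age)_i + 0.2)

where norm is min-max normalisation of each standard-error list to [0, 1]
over the cohort of studies entering that fit, and the 0.2 term stabilises
the denominator (preventing division by zero for the most precise study).
Weights therefore lie in [1/2.2, 5]: exactly 5 for a study that minimises
both standard errors, 1/2.2 for one that maximises both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .study_io import StudyRecord, impute_mean_sd, resolve_age

__all__ = [
    "WeightedObservation",
    "standard_error",
    "minmax_normalize",
    "compute_weights",
    "build_observations",
    "observations_frame",
    "STABILIZER",
]

STABILIZER = 0.2
WEIGHT_MAX = 1.0 / STABILIZER           # 5.0
WEIGHT_MIN = 1.0 / (2.0 + STABILIZER)   # 1/2.2


@dataclass(frozen=True)
class WeightedObservation:
    """One study's point on the mean-AL-vs-mean-age plane, with its weight."""

    study_id: str
    group: str
    age_mean: float   # years
    al_mean: float    # mm
    se_al: float      # mm
    se_age: float     # years
    weight: float

    def __post_init__(self) -> None:
        if self.se_al < 0 or self.se_age < 0:
            raise ValueError("standard errors must be non-negative")
        if not WEIGHT_MIN - 1e-12 <= self.weight <= WEIGHT_MAX + 1e-12:
            raise ValueError(
                f"weight {self.weight} outside [{WEIGHT_MIN}, {WEIGHT_MAX}]")


def standard_error(sd: float, n: int) -> float:
    """Standard error of a mean, sd / sqrt(n)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    return sd / math.sqrt(n)


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Rescale to [0, 1] as (v - min) / (max - min).

    A degenerate range (all values equal) maps everything to 0: equally
    precise studies all receive the maximal weight, which the stabiliser
    keeps finite.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalise an empty list")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def compute_weights(se_al: Sequence[float], se_age: Sequence[float]) -> np.ndarray:
    """Study weights from the two standard-error lists (same cohort)."""
    se_al = np.asarray(se_al, dtype=float)
    se_age = np.asarray(se_age, dtype=float)
    if se_al.shape != se_age.shape:
        raise ValueError(
            f"length mismatch: {se_al.size} se_al vs {se_age.size} se_age")
    return 1.0 / (minmax_normalize(se_al) + minmax_normalize(se_age) + STABILIZER)


def build_observations(records: Sequence[StudyRecord]) -> list[WeightedObservation]:
    """Impute summaries, compute standard errors and weights for a cohort.

    Normalisation is over exactly the records passed in, so the cohort
    entering a fit defines its own weight scale.  Records whose age cannot
    be resolved raise; screen first.
    """
    if not records:
        raise ValueError("no records to weight")
    rows = []
    for r in records:
        age_res = resolve_age(r)
        if not isinstance(age_res, tuple):
            raise ValueError(
                f"study {r.study_id}: age not resolvable "
                f"({age_res.reason.value}); screen before weighting")
        age_mean, age_sd = age_res
        al_mean, al_sd = impute_mean_sd(r.al)
        rows.append((r, age_mean, al_mean,
                     standard_error(al_sd, r.n_emmetropes),
                     standard_error(age_sd, r.n_emmetropes)))
    w = compute_weights([t[3] for t in rows], [t[4] for t in rows])
    return [
        WeightedObservation(
            study_id=r.study_id, group=r.group, age_mean=age_mean,
            al_mean=al_mean, se_al=se_al, se_age=se_age, weight=float(wi))
        for (r, age_mean, al_mean, se_al, se_age), wi in zip(rows, w)
    ]


def observations_frame(obs: Sequence[WeightedObservation]) -> pd.DataFrame:
    """Tabular view (study_id, group, age_mean, al_mean, se_al, se_age, weight)."""
    return pd.DataFrame([o.__dict__ for o in obs])
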