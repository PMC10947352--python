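"""Asymptotic (monoexponential) axial-length growth curve.

The mean model is

    AL(age) = a + b * exp(-c * age)

with ``a`` the final axial length in mm (horizontal asymptote), ``b`` the
offset from the asymptote at age 0 (negative for a growing eye, so the
y-intercept is ``a + b``) and ``c`` a rate constant per year controlling
curve steepness.  Two-group analyses use a reference level (non-East-Asian)
plus per-parameter offsets, so the East-Asian curve is the elementwise sum
of reference and offset triples.

The annual growth rate is defined as the forward one-year difference
``AL(age + 1) - AL(age)``, the convention used in published age-specific
growth tables; the instantaneous derivative is exposed separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np

__all__ = [
    "GrowthParams",
    "GroupedGrowthParams",
    "predict_al",
    "annual_growth_rate",
    "instantaneous_rate",
    "params_for_group",
    "PUBLISHED_COMBINED",
    "PUBLISHED_EA",
    "PUBLISHED_NONEA",
    "PUBLISHED_CURVES",
]

GROUPS = ("EA", "nonEA")


@dataclass(frozen=True)
class GrowthParams:
    """Parameter triple of the asymptotic growth curve.

    Attributes
    ----------
    a : float
        Final axial length (mm); horizontal asymptote.
    b : float
        Offset such that AL at age 0 equals ``a + b`` (mm); negative for
        growing eyes.
    c : float
        Rate constant (per year); larger means earlier plateau.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"final AL a must be positive, got {self.a}")
        if not self.a + self.b > 0:
            raise ValueError(
                f"y-intercept a + b must be positive, got {self.a + self.b}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    def to_dict(self, group: str | None = None) -> dict:
        d = {"a_mm": self.a, "b_mm": self.b, "c_per_year": self.c}
        if group is not None:
            d = {"group": group, **d}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParams":
        return cls(a=float(d["a_mm"]), b=float(d["b_mm"]), c=float(d["c_per_year"]))


@dataclass(frozen=True)
class GroupedGrowthParams:
    """Reference-level curve plus between-group offsets.

    ``reference`` holds the non-EA triple; ``delta`` holds the EA-minus-nonEA
    offsets (same shape, not constrained to be a valid curve on its own).
    """

    reference: GrowthParams
    delta_a: float
    delta_b: float
    delta_c: float

    @property
    def delta(self) -> tuple[float, float, float]:
        return (self.delta_a, self.delta_b, self.delta_c)


def predict_al(params: GrowthParams, age) -> float | np.ndarray:
    """Predicted mean axial length (mm) at ``age`` years.

    ``age`` may be a scalar or array; all values must be non-negative.
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise ValueError("age must be non-negative")
    out = params.a + params.b * np.exp(-params.c * age_arr)
    return float(out) if np.isscalar(age) or age_arr.ndim == 0 else out


def annual_growth_rate(params: GrowthParams, age) -> float | np.ndarray:
    """Annual growth rate (mm/year) as the forward one-year difference.

    rate(age) = AL(age + 1) - AL(age).  Successive rates shrink by the
    factor exp(-c) exactly.
    """
    return predict_al(params, np.asarray(age, dtype=float) + 1.0) - predict_al(
        params, age
    )


def instantaneous_rate(params: GrowthParams, age) -> float | np.ndarray:
    """Instantaneous derivative dAL/dage = -b*c*exp(-c*age) (mm/year)."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise ValueError("age must be non-negative")
    out = -params.b * params.c * np.exp(-params.c * age_arr)
    return float(out) if np.isscalar(age) or age_arr.ndim == 0 else out


def params_for_group(grouped: GroupedGrowthParams, group: str) -> GrowthParams:
    """Resolve the parameter triple for one group.

    The reference level (non-EA) returns the reference triple unchanged;
    the EA triple is the elementwise sum of reference and offsets.
    """
    if group == "nonEA":
        return grouped.reference
    if group == "EA":
        r = grouped.reference
        return GrowthParams(
            a=r.a + grouped.delta_a,
            b=r.b + grouped.delta_b,
            c=r.c + grouped.delta_c,
        )
    raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


def gradient_wrt_params(params: GrowthParams, age) -> np.ndarray:
    """Gradient of predict_al with respect to (a, b, c); rows follow ages."""
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    e = np.exp(-params.c * age_arr)
    return np.column_stack([np.ones_like(age_arr), e, -params.b * age_arr * e])


def dump_params(params: GrowthParams, group: str | None = None) -> str:
    return json.dumps(params.to_dict(group))


def load_params(text_or_dict) -> GrowthParams:
    d = json.loads(text_or_dict) if isinstance(text_or_dict, str) else text_or_dict
    return GrowthParams.from_dict(d)


# Published reference curves (fitted to a 28-study meta-regression corpus of
# emmetrope-specific optical-biometry axial lengths).  These triples are the
# fixture surface for printed-value checks; b is stored signed.
PUBLISHED_COMBINED = GrowthParams(a=23.60, b=-5.60, c=0.30)
PUBLISHED_EA = GrowthParams(a=23.69, b=-6.91, c=0.33)
PUBLISHED_NONEA = GrowthParams(a=23.54, b=-4.15, c=0.24)

PUBLISHED_CURVES: dict[str, GrowthParams] = {
    "combined": PUBLISHED_COMBINED,
    "EA": PUBLISHED_EA,
    "nonEA": PUBLISHED_NONEA,
}


def published_grouped() -> GroupedGrowthParams:
    """Published two-group parametrisation: non-EA reference plus offsets
    recomputed from the two printed group curves."""
    ref = PUBLISHED_NONEA
    ea = PUBLISHED_EA
    return GroupedGrowthParams(
        reference=ref,
        delta_a=round(ea.a - ref.a, 10),
        delta_b=round(ea.b - ref.b, 10),
        delta_c=round(ea.c - ref.c, 10),
    )
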