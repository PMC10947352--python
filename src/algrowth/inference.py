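"""Wald tests on parameter contrasts, delta-method confidence bands and
age-specific growth tables.

Between-group parameter offsets are tested with z = estimate / SE against a
standard normal; 95% confidence intervals use the quantile 1.959964
throughout.  Prediction bands propagate the fitted parameter covariance
through the growth curve to first order (delta method): var(AL_hat) =
g' Sigma g with g the gradient of the curve in the fit's parametrisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimation import FitResult
from .growth_model import annual_growth_rate, gradient_wrt_params, predict_al

__all__ = [
    "Z_95",
    "WaldResult",
    "wald_test",
    "group_contrasts",
    "predict_with_ci",
    "growth_table",
    "round_half_away",
    "format_contrast",
]

Z_95 = 1.959964


@dataclass(frozen=True)
class WaldResult:
    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def wald_test(estimate: float, se: float, name: str = "") -> WaldResult:
    """Two-sided Wald test of estimate = 0 with normal reference."""
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = estimate / se
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return WaldResult(name=name, estimate=float(estimate), se=float(se),
                      ci_low=float(estimate - Z_95 * se),
                      ci_high=float(estimate + Z_95 * se),
                      z=float(z), p=float(p))


def group_contrasts(fit: FitResult) -> list[WaldResult]:
    """Wald tests on the three EA-minus-nonEA parameter offsets.

    The covariance of the offsets comes straight from the Hessian in the
    reference-plus-offset parametrisation, so no delta-method step is needed.
    No multiplicity correction is applied across the three contrasts.
    """
    if fit.model != "grouped":
        raise ValueError("contrasts require a grouped fit")
    return [wald_test(fit.parameters[n], fit.se(n), name=n)
            for n in ("delta_a", "delta_b", "delta_c")]


def _prediction_gradient(fit: FitResult, group: str, age) -> np.ndarray:
    """Gradient of the predicted AL w.r.t. the fit's full parameter vector
    (zeros over the log-variance entries)."""
    params = fit.growth_params(group)
    g3 = gradient_wrt_params(params, age)  # rows: ages, cols: (a, b, c)
    n_ages = g3.shape[0]
    names = list(fit.covariance.columns)
    g = np.zeros((n_ages, len(names)))
    if fit.model == "combined":
        for j, n in enumerate(("a", "b", "c")):
            g[:, names.index(n)] = g3[:, j]
    else:
        for j, n in enumerate(("a_nonEA", "b_nonEA", "c_nonEA")):
            g[:, names.index(n)] = g3[:, j]
        if group == "EA":  # EA params = reference + offsets: chain rule
            for j, n in enumerate(("delta_a", "delta_b", "delta_c")):
                g[:, names.index(n)] = g3[:, j]
    return g


def predict_with_ci(fit: FitResult, group: str, age):
    """Point prediction with a 95% delta-method confidence band.

    Returns (al, ci_low, ci_high); arrays when ``age`` is an array.
    """
    cov = fit.covariance.to_numpy()
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariance unavailable; refit the model")
    params = fit.growth_params(group)
    al = predict_al(params, age)
    g = _prediction_gradient(fit, group, age)
    var = np.einsum("ij,jk,ik->i", g, cov, g)
    var = np.clip(var, 0.0, None)
    half = Z_95 * np.sqrt(var)
    al_arr = np.atleast_1d(np.asarray(al, dtype=float))
    lo, hi = al_arr - half, al_arr + half
    if np.isscalar(age) or np.asarray(age).ndim == 0:
        return float(al_arr[0]), float(lo[0]), float(hi[0])
    return al_arr, lo, hi


def growth_table(fit: FitResult, ages: Sequence[int],
                 groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Age-specific predicted AL, 95% CI and annual growth rate per group.

    Rows are emitted sorted by group then ascending age; values are kept at
    full precision (round only when serialising).
    """
    if groups is None:
        groups = ["combined"] if fit.model == "combined" else ["EA", "nonEA"]
    ages = sorted(int(a) for a in ages)
    if any(a < 0 or a > 40 for a in ages):
        raise ValueError("ages must lie within [0, 40] years")
    rows = []
    for group in groups:
        params = fit.growth_params(group)
        if ages:
            age_arr = np.array(ages, dtype=float)
            al, lo, hi = predict_with_ci(fit, group, age_arr)
            rate = annual_growth_rate(params, age_arr)
            for i, a in enumerate(ages):
                rows.append({"age": a, "group": group, "al": al[i],
                             "ci_low": lo[i], "ci_high": hi[i],
                             "rate": rate[i]})
    return pd.DataFrame(rows, columns=["age", "group", "al", "ci_low",
                                       "ci_high", "rate"])


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round halves away from zero (presentation convention for tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def format_table(table: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    out = table.copy()
    for col in ("al", "ci_low", "ci_high", "rate"):
        out[col] = out[col].map(lambda v: round_half_away(v, ndigits))
    return out


def format_contrast(w: WaldResult, ndigits: int = 2) -> str:
    r = lambda v: round_half_away(v, ndigits)
    return (f"{w.name} difference: {r(w.estimate)}, 95% CI: {r(w.ci_low)} to "
            f"{r(w.ci_high)}, p = {r(w.p)}")
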