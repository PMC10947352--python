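"""Weighted nonlinear mixed-effects fitting of the growth curve.

With one aggregate observation per study, a study-level random intercept on
the asymptote collapses to a marginal normal model for each study mean:

    AL_i ~ Normal( f(age_i; theta_group(i)),  v_i ),
    v_i  = tau^2 + sigma^2 / W_i

where f is the asymptotic growth curve, tau^2 is between-study variance,
sigma^2 a residual scale and W_i the precision weight, entering as a
residual variance function in the usual weighted-NLME way.  Parameters are
estimated by maximum likelihood (not REML) so AIC comparisons and Wald
tests on the grouped parametrisation are coherent.

The exponential mean surface has likelihood ridges that aggregate corpora
with ages starting around 6 years cannot resolve: the curve's age-0 value
``a + b`` is an extrapolation, and trading it against the rate constant
changes the fit over the observed ages by less than the between-study
noise.  The search is therefore confined to physiologically admissible
curves — final AL inside the 18-28 mm plausibility window, age-0 AL
(neonatal axial length) inside 14-21 mm, rate constant in 0.05-1.5 per
year — by optimising internally over (a, y0, c) with box constraints,
where y0 = a + b is the age-0 intercept.  Results are reported in the
(a, b, c) parametrisation (grouped: reference plus offsets), with the
covariance mapped through the exact linear transform, so Wald tests on the
offsets read their standard errors straight from the reported covariance.

Variance components are optimised on the log scale.  The covariance matrix
is the inverse of the numerical Hessian of the negative log-likelihood at
the optimum, regularised through its eigendecomposition (absolute values,
floored): at an active admissibility bound the Hessian can have flat or
negative-curvature directions, and the regularised inverse then reports the
near-flat ridge direction as large — not zero or negative — variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess

from .growth_model import GroupedGrowthParams, GrowthParams, params_for_group
from .weighting import WeightedObservation

__all__ = [
    "FitOptions",
    "FitResult",
    "negative_log_marginal_likelihood",
    "fit_combined",
    "fit_grouped",
]

_LOGV_LO, _LOGV_HI = math.log(1e-10), math.log(1e4)
_TAU_BOUNDARY = 1e-8

# Admissibility box (final AL, age-0 AL, rate constant); see module docstring.
_BOUNDS_A = (18.0, 28.0)
_BOUNDS_Y0 = (14.0, 21.0)
_BOUNDS_C = (0.05, 1.5)

COMBINED_NAMES = ["a", "b", "c"]
GROUPED_NAMES = ["a_nonEA", "b_nonEA", "c_nonEA", "delta_a", "delta_b", "delta_c"]


@dataclass(frozen=True)
class FitOptions:
    """Optimiser configuration.

    starts: number of multi-start initial points (a deterministic grid over
    intercept and rate initials, extra points jittered from ``seed``).
    tol: convergence tolerance on the objective.  random_effects: when
    False, tau^2 is fixed at zero and the model reduces to weighted
    nonlinear regression.
    """

    starts: int = 8
    tol: float = 1e-9
    seed: int = 0
    random_effects: bool = True
    max_iter: int = 2000


@dataclass
class FitResult:
    model: str                       # "combined" | "grouped"
    parameters: dict[str, float]     # mean parameters, reported scale
    sigma2: float                    # residual variance scale (mm^2)
    tau2: float                      # between-study variance (mm^2)
    tau2_boundary: bool
    covariance: pd.DataFrame         # mean params + log-variance terms
    loglik: float
    aic: float
    converged: bool
    n_studies: int
    options: FitOptions
    method: str = "ML"
    optimizer_trace: list = field(default_factory=list)

    @property
    def n_free_parameters(self) -> int:
        k = len(self.parameters) + 1  # sigma2 always free
        if self.options.random_effects:
            k += 1
        return k

    def growth_params(self, group: str = "combined") -> GrowthParams:
        """Resolve a parameter triple for prediction."""
        p = self.parameters
        if self.model == "combined":
            if group not in ("combined", None):
                raise ValueError("combined fit has no group-specific curves")
            return GrowthParams(p["a"], p["b"], p["c"])
        grouped = GroupedGrowthParams(
            reference=GrowthParams(p["a_nonEA"], p["b_nonEA"], p["c_nonEA"]),
            delta_a=p["delta_a"], delta_b=p["delta_b"], delta_c=p["delta_c"])
        return params_for_group(grouped, group)

    def se(self, name: str) -> float:
        return float(np.sqrt(self.covariance.loc[name, name]))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "method": self.method,
            "parameters": self.parameters,
            "sigma2": self.sigma2,
            "tau2": self.tau2,
            "tau2_boundary": self.tau2_boundary,
            "covariance": {
                "names": list(self.covariance.columns),
                "matrix": self.covariance.to_numpy().tolist(),
            },
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_studies": self.n_studies,
            "seed": self.options.seed,
            "optimizer_trace": self.optimizer_trace,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        names = d["covariance"]["names"]
        cov = pd.DataFrame(np.asarray(d["covariance"]["matrix"]),
                           index=names, columns=names)
        return cls(
            model=d["model"], parameters=d["parameters"], sigma2=d["sigma2"],
            tau2=d["tau2"], tau2_boundary=d["tau2_boundary"], covariance=cov,
            loglik=d["loglik"], aic=d["aic"], converged=d["converged"],
            n_studies=d["n_studies"],
            options=FitOptions(seed=d.get("seed", 0)),
            optimizer_trace=d.get("optimizer_trace", []))


def _design(obs: Sequence[WeightedObservation], grouped: bool):
    age = np.array([o.age_mean for o in obs])
    al = np.array([o.al_mean for o in obs])
    w = np.array([o.weight for o in obs])
    ea = np.array([1.0 if o.group == "EA" else 0.0 for o in obs]) if grouped else None
    return age, al, w, ea


def _mean_and_grad_internal(theta_mean: np.ndarray, age: np.ndarray, ea):
    """Fitted means and gradient w.r.t. the internal (a, y0, c) blocks.

    Internal layout: combined (a, y0, c); grouped (a_n, y0_n, c_n, a_e,
    y0_e, c_e), one full triple per group.
    """
    if ea is None:
        a, y0, c = theta_mean
        b = y0 - a
        e = np.exp(-c * age)
        f = a + b * e
        grad = np.column_stack([1.0 - e, e, -b * age * e])
        return f, grad
    a = np.where(ea == 1.0, theta_mean[3], theta_mean[0])
    y0 = np.where(ea == 1.0, theta_mean[4], theta_mean[1])
    c = np.where(ea == 1.0, theta_mean[5], theta_mean[2])
    b = y0 - a
    e = np.exp(-c * age)
    f = a + b * e
    non = 1.0 - ea
    grad = np.column_stack([
        (1.0 - e) * non, e * non, -b * age * e * non,
        (1.0 - e) * ea, e * ea, -b * age * e * ea,
    ])
    return f, grad


def _nll_and_grad(theta, age, al, w, ea, random_effects):
    p = 6 if ea is not None else 3
    sigma2 = math.exp(theta[p])
    tau2 = math.exp(theta[p + 1]) if random_effects else 0.0
    f, grad_f = _mean_and_grad_internal(theta[:p], age, ea)
    r = al - f
    v = tau2 + sigma2 / w
    nll = 0.5 * np.sum(np.log(2 * math.pi * v) + r**2 / v)
    g_mean = -grad_f.T @ (r / v)  # r = al - f, so dNLL/dtheta = -sum(r/v * df)
    dv_common = 0.5 * (1.0 / v - r**2 / v**2)
    g = [*g_mean, float(np.sum(dv_common * sigma2 / w))]
    if random_effects:
        g.append(float(np.sum(dv_common * tau2)))
    return float(nll), np.array(g)


def _internal_from_reported(theta_mean: np.ndarray, grouped: bool) -> np.ndarray:
    if not grouped:
        a, b, c = theta_mean
        return np.array([a, a + b, c])
    an, bn, cn, da, db, dc = theta_mean
    ae, be, ce = an + da, bn + db, cn + dc
    return np.array([an, an + bn, cn, ae, ae + be, ce])


def negative_log_marginal_likelihood(
    theta: np.ndarray,
    obs: Sequence[WeightedObservation],
    grouped: bool = False,
    random_effects: bool = True,
) -> float:
    """Negative marginal log-likelihood at ``theta``.

    ``theta`` stacks the mean parameters in the reported parametrisation
    (combined: a, b, c; grouped: reference a, b, c then the three offsets),
    then log(sigma^2) and, when random effects are on, log(tau^2).
    """
    if len(obs) == 0:
        raise ValueError("no observations")
    theta = np.asarray(theta, dtype=float)
    age, al, w, ea = _design(obs, grouped)
    p = 6 if grouped else 3
    internal = np.concatenate([_internal_from_reported(theta[:p], grouped),
                               theta[p:]])
    return _nll_and_grad(internal, age, al, w, ea, random_effects)[0]


def _report_transform(grouped: bool) -> np.ndarray:
    """Linear map from internal (per-group a, y0, c) to the reported
    (reference a, b, c plus offsets) parametrisation."""
    if not grouped:
        # (a, b, c) = (a, y0 - a, c)
        return np.array([[1.0, 0.0, 0.0],
                         [-1.0, 1.0, 0.0],
                         [0.0, 0.0, 1.0]])
    T = np.zeros((6, 6))
    T[0, 0] = 1.0                       # a_nonEA = a_n
    T[1, 0], T[1, 1] = -1.0, 1.0        # b_nonEA = y0_n - a_n
    T[2, 2] = 1.0                       # c_nonEA = c_n
    T[3, 0], T[3, 3] = -1.0, 1.0        # delta_a = a_e - a_n
    T[4, 0], T[4, 1] = 1.0, -1.0        # delta_b = (y0_e - a_e) - (y0_n - a_n)
    T[4, 3], T[4, 4] = -1.0, 1.0
    T[5, 2], T[5, 5] = -1.0, 1.0        # delta_c = c_e - c_n
    return T


# A direction the data leave flat still cannot vary more than the admissible
# box permits: a uniform distribution over the widest box dimension (final AL,
# 10 mm wide) has variance 10^2/12 = 8.33 mm^2, so no direction is reported
# with more variance than that.  The corresponding curvature floor is its
# reciprocal.
_EIG_FLOOR = 0.12


def _regularised_inverse(hess: np.ndarray) -> np.ndarray:
    """Invert through the eigendecomposition with absolute, floored
    eigenvalues: flat or negative-curvature directions at an active
    admissibility bound surface as large — capped at the box's own uniform
    variance — rather than zero or negative variances."""
    h = 0.5 * (hess + hess.T)
    lam, vec = np.linalg.eigh(h)
    lam = np.abs(lam)
    lam[lam < _EIG_FLOOR] = _EIG_FLOOR
    return (vec / lam) @ vec.T


def _initial_points(age, al, w, ea, options: FitOptions):
    """Deterministic grid over intercept/rate initials plus seeded jitter."""
    a0 = min(float(al.max()) + 0.1, _BOUNDS_A[1])
    a0 = max(a0, _BOUNDS_A[0])
    rng = np.random.default_rng(options.seed)
    grouped = ea is not None
    mean_starts = []
    for c0 in (0.1, 0.3, 0.6):
        for y00 in (16.5, 18.5):
            triple = [a0, y00, c0]
            mean_starts.append(triple * 2 if grouped else list(triple))
            if len(mean_starts) >= options.starts:
                break
        if len(mean_starts) >= options.starts:
            break
    while len(mean_starts) < options.starts:
        triple = [float(np.clip(a0 + rng.normal(0, 0.3), *_BOUNDS_A)),
                  float(rng.uniform(15.0, 20.5)),
                  float(rng.uniform(0.07, 0.7))]
        if grouped:
            other = [float(np.clip(triple[0] + rng.normal(0, 0.2), *_BOUNDS_A)),
                     float(rng.uniform(15.0, 20.5)),
                     float(rng.uniform(0.07, 0.7))]
            mean_starts.append(triple + other)
        else:
            mean_starts.append(triple)
    out = []
    for mean in mean_starts:
        mean = np.asarray(mean, dtype=float)
        f, _ = _mean_and_grad_internal(mean, age, ea)
        r = al - f
        s2 = max(float(np.mean(w * r**2)), 1e-4)
        theta = list(mean) + [math.log(s2)]
        if options.random_effects:
            theta.append(math.log(max(0.25 * float(np.var(r)), 1e-4)))
        out.append(np.array(theta))
    return out


def _run_fit(obs, grouped: bool, options: FitOptions) -> FitResult:
    age, al, w, ea = _design(obs, grouped)
    if np.unique(age).size < 3:
        raise ValueError("degenerate design: need at least 3 distinct mean ages")
    p = 6 if grouped else 3
    names = GROUPED_NAMES if grouped else COMBINED_NAMES

    def obj(theta):
        return _nll_and_grad(theta, age, al, w, ea, options.random_effects)

    nvar = 2 if options.random_effects else 1
    triple_bounds = [_BOUNDS_A, _BOUNDS_Y0, _BOUNDS_C]
    bounds = triple_bounds * (2 if grouped else 1) + [(_LOGV_LO, _LOGV_HI)] * nvar
    best, trace = None, []
    for i, x0 in enumerate(_initial_points(age, al, w, ea, options)):
        res = minimize(obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": options.tol * 1e-3,
                                "gtol": 1e-10, "maxiter": options.max_iter})
        trace.append({"start": i, "x0": np.round(x0, 4).tolist(),
                      "nll": float(res.fun), "success": bool(res.success),
                      "nit": int(res.nit), "message": str(res.message)})
        if best is None or res.fun < best.fun:
            best = res
    # polish from the best optimum with tight tolerances
    res = minimize(obj, best.x, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"ftol": 1e-15, "gtol": 1e-12,
                            "maxiter": options.max_iter})
    if res.fun <= best.fun:
        best = res
    theta = best.x
    converged = bool(best.success or any(t["success"] for t in trace))

    sigma2 = math.exp(theta[p])
    tau2 = math.exp(theta[p + 1]) if options.random_effects else 0.0
    tau2_boundary = options.random_effects and tau2 <= _TAU_BOUNDARY
    if tau2_boundary:
        tau2 = 0.0

    hess = approx_hess(theta, lambda t: obj(t)[0])
    cov_internal = _regularised_inverse(hess)
    # map the mean-parameter block through the exact linear transform to the
    # reported (reference + offsets) parametrisation
    T = np.eye(p + nvar)
    T[:p, :p] = _report_transform(grouped)
    cov = T @ cov_internal @ T.T
    theta_names = names + ["log_sigma2"] + (
        ["log_tau2"] if options.random_effects else [])
    cov_df = pd.DataFrame(cov, index=theta_names, columns=theta_names)
    reported_mean = _report_transform(grouped) @ theta[:p]

    loglik = -float(best.fun)
    k = p + nvar
    return FitResult(
        model="grouped" if grouped else "combined",
        parameters={n: float(v) for n, v in zip(names, reported_mean)},
        sigma2=float(sigma2), tau2=float(tau2), tau2_boundary=tau2_boundary,
        covariance=cov_df, loglik=loglik, aic=2 * k - 2 * loglik,
        converged=converged, n_studies=len(obs), options=options,
        optimizer_trace=trace)


def fit_combined(obs: Sequence[WeightedObservation],
                 options: FitOptions = FitOptions()) -> FitResult:
    """Fit the single growth curve to all studies, ignoring group labels."""
    if len(obs) < 3:
        raise ValueError("need at least 3 studies to identify (a, b, c)")
    return _run_fit(obs, grouped=False, options=options)


def fit_grouped(obs: Sequence[WeightedObservation],
                options: FitOptions = FitOptions()) -> FitResult:
    """Fit reference (non-EA) parameters plus EA offsets with shared
    variance components."""
    groups = {o.group for o in obs}
    for g in ("EA", "nonEA"):
        if g not in groups:
            raise ValueError(f"group {g!r} absent from the observations")
    return _run_fit(obs, grouped=True, options=options)
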