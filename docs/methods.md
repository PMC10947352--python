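# Methods

## The model

`algrowth` fits an asymptotic (monoexponential) growth curve to study-level
summaries of axial length (AL) in emmetropes:

    AL(age) = a + b · exp(−c · age)

* `a` — final AL (mm), the horizontal asymptote approached in adulthood;
* `b` — offset (mm) such that the curve's value at age 0 is `a + b`;
  negative for a growing eye;
* `c` — rate constant (per year) controlling how quickly the curve
  plateaus.

The *annual growth rate* reported in growth tables is the forward one-year
difference `AL(age+1) − AL(age)`, not the instantaneous derivative
`−b·c·exp(−c·age)`: at the published combined parameters the derivative at
age 6 is ≈ 0.28 mm/yr while the forward difference is 0.24 mm/yr, which is
the tabulated convention. The derivative is exposed separately as
`instantaneous_rate`. Successive annual rates decay by the factor
`exp(−c)` exactly.

Two-group (East-Asian vs non-East-Asian) analyses reparametrise the curve
as a non-EA reference triple plus per-parameter offsets; the EA curve is
the elementwise sum. Wald tests on the offsets read their standard errors
directly from the covariance in that parametrisation.

## Data model, imputation and screening

Each observation is one study arm reporting its emmetropic subsample's
sample size, mean ± SD (or median/IQR/range) of age and AL, the emmetropia
definition bounds in dioptres of spherical equivalent refraction (SER),
whether refraction was cycloplegic, and the biometry method. When only
order statistics are reported, mean and SD are imputed with the Wan et
al. (2014) estimators (three scenarios: median+range, median+IQR, all five
numbers; the five-number SD averages the two spread estimators). Imputed
and reported moments are treated identically downstream.

Eligibility screening applies, in fixed order: optical biometry; emmetropia
window contained in [−0.50, +1.25] D; a resolvable emmetrope age (a
whole-sample age may stand in only when the whole-sample age range is ≤ 3
years); cycloplegia unless mean age ≥ 20 years; mean age in [6, 30] years;
emmetrope-specific AL. The first failing rule sets the recorded reason
code, so screening reports are reproducible. AL centres outside 18–28 mm
are rejected at read time as unit errors.

## Weighting

Each study entering a fit receives

    W = 1 / ( norm(SE of AL) + norm(SE of age) + 0.2 )

where `norm` is min–max normalisation over exactly the cohort entering that
fit and SE = SD/√n. Weights lie in [1/2.2, 5]; the study minimising both
standard errors gets exactly 5. The 0.2 stabiliser keeps the most precise
study's weight finite; when all SEs are equal the normalised values are
defined as 0, so equally precise studies share the maximal weight.
Normalisation is cohort-relative by construction, so a subset re-analysis
re-normalises within the subset.

## Estimation

With one aggregate observation per study, a study-level random intercept on
`a` collapses to the marginal model

    AL_i ~ Normal( f(age_i; θ_group(i)),  v_i ),   v_i = τ² + σ²/W_i

with between-study variance τ² and a residual scale σ² divided by the
study weight (a residual variance function, as in standard weighted NLME
practice). Estimation is by maximum likelihood — not REML — so that AIC
comparisons and Wald tests are coherent; τ² and σ² are optimised on the
log scale and a τ̂² below 1e−8 is reported as 0 with a boundary flag.

### Admissibility constraints

Aggregate corpora whose ages start around 6 years do not identify the
curve's age-0 behaviour: the likelihood has ridges along which the
intercept `a + b` runs to physically impossible values (or `c` to 0 with
`a` diverging) while the fit over the observed ages changes by less than
the between-study noise. The optimiser therefore searches internally over
`(a, y0, c)` with `y0 = a + b` and box constraints

* `a` ∈ [18, 28] mm — the same plausibility window applied at read time;
* `y0` ∈ [14, 21] mm — a generous neonatal axial-length window (both
  published group intercepts, 16.78 and 19.39 mm, lie inside it);
* `c` ∈ [0.05, 1.5] /yr — growth must plateau within a human lifetime but
  not before the data begin.

Results are reported in the `(a, b, c)` (grouped: reference + offsets)
parametrisation via the exact linear transform, covariance included.

### Optimisation and covariance

Multi-start L-BFGS-B with an analytic gradient: a deterministic grid of
initial intercepts {16.5, 18.5} mm × rate constants {0.1, 0.3, 0.6} /yr
with `a₀ = max(AL) + 0.1`, plus seed-derived jittered starts up to the
configured count (default 8), followed by a tight polish from the best
optimum. All stochastic restarts derive from a single user-supplied seed
recorded in the result.

The covariance matrix is the inverse of the numerical Hessian of the
negative log-likelihood at the optimum, taken through its
eigendecomposition with absolute values, floored at 0.12: directions the
data leave flat (which occur at active admissibility bounds) are reported
with large variance, capped at the variance of a uniform distribution over
the widest box dimension (10²/12 ≈ 8.33 mm²), rather than the zero or
negative values a raw pseudo-inverse can produce there. Prediction bands
use the first-order delta method with the normal quantile 1.959964; a
parametric-bootstrap check in the test suite guards the delta method on a
well-identified fit.

## Synthetic corpora

The generator emulates the structure the meta-regression assumes:
per-study age centres uniform on 6–24 years, a study intercept
`u ~ N(0, 0.2² mm²)` added to `a`, eyes with ages
`N(centre, 1 yr²)` truncated at 0 by resampling, and individual AL noise
`N(0, 0.6² mm²)` around the group curve. Defaults produce 16 EA and 12
non-EA studies of 20–600 eyes each, the published group curves as truth,
and mean ± SD reporting; median+IQR and median+range styles exercise the
imputation path. A study whose realised mean age falls outside [6, 30]
years is redrawn, mirroring eligibility conditioning on the observed mean
age, so default corpora pass screening in full.

What the generator does *not* emulate: unequal emmetropia definitions
across studies (all synthetic studies use ±0.50 D), reporting
heterogeneity within a corpus, non-normal AL distributions, sex structure,
and overlap between cohorts. Passing recovery tests therefore demonstrate
correctness of the pipeline under its own assumptions, not robustness to
every feature of real extracted corpora.

## Measured operating characteristics

All experiments derive their randomness from fixed master seeds and run in
the test suite at the sizes below (chosen to exercise the stated
properties at meaningful precision).

* **Closed form.** Evaluating the model at the published parameter triples
  reproduces the printed final AL (23.60 mm), annual rates at ages 6 and
  11 (0.24, 0.05 mm/yr), age-24 group values (23.69, 23.53 mm), the
  combined age-12 value (23.45 mm) and the ethnic offsets Δa = 0.15,
  Δc = 0.09 to two decimals. Known printed-table cells that disagree with
  the closed form (the EA age-6 value, one non-EA confidence bound with
  transposed digits, and the intercept offset −2.77 vs −2.76 recomputed
  from rounded curves) are excluded as documented rounding/typo artefacts.
* **Oracle equivalence.** With τ² = 0 the optimiser's mean parameters agree
  with an independent bounded weighted least-squares solve
  (`scipy.optimize.least_squares`, trust-region reflective) to ≲ 3e−7
  relative error.
* **Recovery.** Over 100 replicate 28-study corpora at the published
  combined truth: bias(â) ≈ +0.03 mm, bias(ĉ) ≈ −0.01 /yr; 95% Wald CI
  coverage 97/92/92% for a/b/c. The estimate of `b` is strongly
  non-normal (sampling SD ≈ 2.3 mm, mean bias ≈ −0.7 mm): the corpus
  carries little information on the age-0 extrapolation, consistent with
  the ±8 mm width of the published intercept-offset confidence interval.
  This is a known limitation, not a defect the constraints can remove.
* **Null calibration.** Over 1000 zero-difference grouped corpora the Wald
  test on Δc rejects at the 5% level in 3.8% of corpora — slightly
  conservative, a consequence of the variance floor at admissibility
  bounds.
* **Imputation.** Wan-formula means land within 1% and SDs within 5% of
  truth averaged over 1000 simulated normal studies per scenario at
  n ∈ {15, 50, 200}.

## Numerical conventions

Internal computation keeps full precision; presentation layers round
halves away from zero to two decimals. The normal quantile 1.959964 is
used for every 95% interval. Two-sided Wald p-values are reported without
multiplicity correction across the three group contrasts. Ages are
continuous; growth tables use an integer grid (default 6–24 years).

## Known limitations

The extracted 28-study corpus behind the published curves is not shipped,
so the exact published fitted parameters are anchored as fixtures rather
than re-derived from data. The confidence-interval method behind the published age-specific
table is unstated; this package uses the delta method and does not attempt
cell-by-cell reproduction of those intervals. Random-effects placement is a
single intercept on `a`; with one observation per study, richer structures
are not identifiable.
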