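# algrowth

Weighted nonlinear mixed-effects meta-regression of axial-length (AL)
growth in emmetropes.

Axial length is the principal biometric determinant of refractive error,
and normative AL growth charts let clinicians compare a child's AL
trajectory against age-expected values when judging myopia risk. This
package implements an aggregate-data meta-regression of emmetrope-specific
AL summaries from published studies: it screens study records against
eligibility rules (optical biometry, cycloplegic refraction in children, an
emmetropia window of −0.50 to +1.25 D spherical equivalent), imputes means
and SDs from medians/IQRs/ranges where needed (Wan et al. 2014), weights
studies by the precision of their AL and age estimates, fits asymptotic
growth curves — pooled, and by East-Asian (EA) vs non-EA group — tests
between-group parameter contrasts with Wald tests, and emits age-specific
growth tables with confidence bands. A synthetic-corpus generator with the
same statistical structure makes the whole pipeline testable without any
external data.

## Model

The mean curve is the asymptotic exponential

    AL(age) = a + b · e^(−c · age)

with final AL `a` (mm, horizontal asymptote), offset `b` (mm; AL at age 0
is `a + b`) and rate constant `c` (per year). Study `i` receives weight

    W_i = 1 / ( norm(SE of AL)_i + norm(SE of age)_i + 0.2 )

(min–max normalisation over the fitted cohort), and study means follow

    AL_i ~ Normal( f(age_i), τ² + σ²/W_i )

— a study-level random intercept plus a weight-driven residual variance,
estimated by maximum likelihood. The two-group fit parametrises non-EA as
the reference level plus EA offsets (Δa, Δb, Δc), whose Wald tests come
straight from the fitted covariance. Annual growth rate is the forward
one-year difference of the curve. See `docs/methods.md` for estimation
details (admissibility constraints, multi-start optimisation, covariance
regularisation).

## Worked example

Simulate a corpus shaped like the published one (16 EA + 12 non-EA studies)
and run the full pipeline:

```
$ algrowth simulate --seed 42 --out corpus.csv
wrote 28 studies to corpus.csv

$ algrowth fit --in corpus.csv --out fit --seed 1
combined fit (n=28): a=23.6213, b=-4.5028, c=0.2377
delta_a difference: 0.01, 95% CI: -0.51 to 0.53, p = 0.98
delta_b difference: -2.17, 95% CI: -8.47 to 4.13, p = 0.5
delta_c difference: 0.1, 95% CI: -0.19 to 0.39, p = 0.49
```

The combined fit recovers a curve close to the generator's truth: final AL
≈ 23.62 mm and a rate constant ≈ 0.24/yr. The three contrast lines test
the EA-minus-nonEA parameter offsets; here (as in the published analysis)
none approaches significance, i.e. the two groups share a growth curve
within uncertainty. `fit/growth_table.csv` holds the age-specific table:

```
age,group,al,ci_low,ci_high,rate
6,combined,22.54,22.25,22.83,0.23
7,combined,22.77,22.58,22.95,0.18
8,combined,22.95,22.76,23.13,0.14
...
```

`al` is the predicted mean AL (mm) with a 95% delta-method band, and
`rate` the annual growth increment (mm/yr), which decays by the factor
`e^(−c)` each year. Other subcommands: `algrowth screen` writes per-study
eligibility decisions with reason codes, and `algrowth table` rebuilds a
growth table from a saved fit JSON. Every run writes a manifest (seed,
config, version) sufficient to reproduce it.

As a library:

```python
import algrowth as ag

records = ag.simulate_corpus(ag.SyntheticConfig(seed=42))
obs = ag.build_observations(records)          # impute, SE, weight
fit = ag.fit_grouped(obs, ag.FitOptions(seed=1))
print(ag.growth_table(fit, range(6, 25)))
```

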