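# Methods

## Model

`aftid` fits an illness-death model for semi-competing risks by Bayesian
accelerated failure time (AFT) regression.  Each of the three transitions
— health → recurrence, health → death without recurrence, recurrence →
death — gets its own log-normal AFT equation:

```
log T_i1       = x_i' β₁ + γ_i + ε_i1,   ε_i1 ~ N(μ₁, σ₁²)
log T_i2       = x_i' β₂ + γ_i + ε_i2,   ε_i2 ~ N(μ₂, σ₂²)
log(T_i2−T_i1) = x_i' β₃ + γ_i + ε_i3,   ε_i3 ~ N(μ₃, σ₃²)
```

The third equation operates on the sojourn scale: the clock restarts at
recurrence, and only subjects with an observed recurrence contribute to
it.  The subject-specific frailty `γ_i ~ N(0, θ)` is shared across the
three equations and induces positive dependence between the recurrence
and death processes.  Given `γ_i`, the latent recurrence and
death-without-recurrence times are independent log-normals; whichever is
smaller determines the path the subject takes.  The intercept of each
equation lives in the error location `μ_g`, so design matrices carry no
constant column; all three transitions share one design matrix by
default.

Assumptions worth stating plainly: log-normal errors (no Weibull or
semiparametric baseline), one shared frailty acting additively on all
three log-time scales (no transition-specific loadings), independent
administrative right-censoring, and no left truncation.

### Likelihood

With `f_g`/`S_g` the log-normal density/survival at location
`μ_g + x'β_g + γ_i`, a record `(y1, d1, y2, d2)` contributes,
conditionally on `γ_i`:

| pattern              | contribution                              |
|----------------------|-------------------------------------------|
| recurrence + death   | `f₁(y1) · S₂(y1) · f₃(y2−y1)`             |
| recurrence, censored | `f₁(y1) · S₂(y1) · S₃(y2−y1)`             |
| death, no recurrence | `S₁(y2) · f₂(y2)`                         |
| doubly censored      | `S₁(y1) · S₂(y1)`                         |

A death recorded at the recurrence time would give a zero sojourn; the
sojourn is replaced by 0.01 months with a one-time warning.

### Priors and propriety

Improper flat priors on each `(μ_g, β_g)`; conjugate IG(a, b) on each
`σ_g²` and on `θ`.  The default `a = b = 0.7` everywhere is weakly
informative and fully configurable; nothing in the analysis is sensitive
to it at the cohort sizes exercised here except the frailty variance at
very small n.  Posterior propriety under the flat priors requires at
least one observed event per transition and a full-rank design — the
fitter refuses to run otherwise.

## Posterior computation

A data-augmentation Gibbs sampler.  Each sweep:

1. **Augment.**  Every censored piece of the likelihood is a truncated
   log-normal; its latent log-time is drawn from the corresponding
   truncated normal (`z > log y1` for censored recurrence and for the
   survival factor of transition 2, `z > log(y2−y1)` for a censored
   sojourn).  Observed events keep their exact log-times.
2. **Coefficients.**  With complete data, each transition is a normal
   linear model; `(μ_g, β_g)` is drawn jointly from
   `N(coef_LS, σ_g² (A'A)⁻¹)` where `A` is the design with an intercept
   column and the response is `z_g − γ`.
3. **Scales.**  `σ_g² ~ IG(a_g + m_g/2, b_g + RSS_g/2)`.
4. **Frailties.**  Each `γ_i` pools its transitions' residuals:
   precision `Σ_g 1/σ_g² + 1/θ`, mean = precision-weighted residual sum.
5. **Frailty variance.**  `θ ~ IG(a_θ + n/2, b_θ + Σγ_i²/2)`.

Truncated normals are sampled by inversion through the survival
function — `Φ̄⁻¹(u·Φ̄(a))` — which is exact and stable to standardized
bounds around 37; beyond that an asymptotic tail sampler
(`a + Exp(1)/a`) takes over.  This matters because augmentation bounds
many standard deviations above the current location do occur early in a
chain.

Defaults: 2 chains × 20 000 iterations, 10 000 burn-in, thinning 5; the
seed must always be given explicitly, and identical seeds give
bit-identical chains.  Split-R̂ and bulk ESS are computed per scalar
parameter (via arviz) and a warning is emitted when R̂ > 1.05.  The test
and acceptance studies use much shorter chains (hundreds to a few
thousand iterations), chosen per study and stated there; they trade
Monte-Carlo precision for breadth, which is why tolerance choices below
matter.

Per-subject log-likelihoods are recorded **conditionally on the sampled
frailty**.  Consequently DIC is the conditional version (the plug-in
deviance evaluates posterior means of `β, μ, σ², γ`, so `p_D` counts the
frailty vector among the effective parameters), and CPO/LPML are
conditional predictive ordinates given the frailty.  A marginal DIC
would need integrating each subject over `γ_i`; it is deliberately not
the default and not implemented, because the conditional form is what
the per-draw bookkeeping supports exactly.  LPML uses the log-sum-exp
trick; per-subject log-likelihood draws below −700 are clipped with a
warning rather than silently underflowing.

**A caution observed during validation:** conditional DIC differences
between nested variants carry noise from the frailty plug-in of the same
order as the parsimony penalty itself.  A single spurious continuous
covariate (~3 effective parameters across transitions, expected penalty
≈ +3) is *not* reliably rejected at n = 200; a spurious 3-level
categorical (~6 effective parameters) is.  The comparison study is
therefore formulated with the categorical spurious covariate.

## Nonparametric stages

Kaplan–Meier estimation groups tied events, counts censorings tied with
an event as still at risk (events first), uses Greenwood's variance and
log(−log)-transformed 95% pointwise bands.  The median is the smallest
time with `S(t) ≤ 0.5`; its confidence bounds are where the lower/upper
bands cross 0.5, NaN when never ("not reached").  Fixed-horizon survival
is evaluated right-continuously; horizons beyond follow-up are flagged
as extrapolated.  The k-sample log-rank test accumulates hypergeometric
observed-minus-expected counts with the full covariance, and the
statistic is the quadratic form over k−1 groups against a chi-square
reference; no permutation or weighted variants.  Cause-specific
convention: the recurrence outcome uses `(y1, d1)`, so death without
recurrence censors the recurrence process at `y1`.  Univariate screening
runs the cause-specific log-rank per outcome and admits a covariate when
either p-value is below α = 0.1; note the union of two correlated
α-level tests has a family rate above α (~0.17 in calibration runs) —
per-outcome p-values are what is calibrated at α.

## Synthetic cohorts

The generator emulates a single-centre surgical colorectal-cancer cohort
of 284 patients: covariate categories are drawn independently with the
published marginal frequencies (stage and site derived from the joint
stage-by-site draw so the three stay consistent, chemotherapy yes/no
derived from the session-count group); event histories follow the
generative model above; administrative censoring is uniform on
[12, 192] months, a stand-in for 2001–2017 accrual with end-of-study
cut-off — the source setting names no censoring mechanism, so this
window is a modelling choice.  Default truth: stage-site dummy
coefficients set to the logs of published time ratios (fixture effect
sizes, not ground truth of any real cohort), all other coefficients
zero, `σ = (1.0, 1.0, 0.8)`, `θ = 0.75`, and `μ = (4.15, 5.05, 3.3)`
calibrated once at n = 30 000 so the realized event mix reproduces the
published profile (~46% recurrence, ~43% death).  pT stage, pN stage and
metastasis frequencies are not in the published profile; plausible
surgical-cohort values are used (they are read, validated and carried
but enter no default model).

What the generator does **not** emulate: covariate dependence beyond
stage-site (draws are independent; real cohorts correlate age, stage and
treatment), informative censoring, measurement error in dates, or
centre-level effects.  Passing recovery tests therefore demonstrate
correctness of the fitting machinery under the model's own assumptions —
not robustness to their violation.

## Numerical and design choices

- Times are months at four decimal places in the CSV dialect; the
  canonical convention `d1 = 0 ⟹ y1 = y2` is enforced on read, and
  rows with missing fields are rejected rather than imputed.
- Reported percentages round half-up to one decimal.
- Ordinal covariates enter as trend scores 1..K; the stage-by-site
  composite uses three dummies against the Early_RC referent; the
  interaction variant uses trend-coded stage, site and their product.
- Time ratios are `exp(posterior median β)` with equal-tailed 2.5/97.5%
  exponentiated quantiles; "significant" flags an interval excluding 1.
  The posterior-median convention (rather than mean) keeps TR equivariant
  under reciprocal recoding of a binary covariate.
- Initialization: `β = 0`, `μ_g` = mean observed log-time of transition
  g, `σ_g² = 1`, `γ = 0`, `θ = 1`.  Chains are seeded from a
  SeedSequence spawn per chain.
- Degenerate inputs: empty datasets, single-group log-rank calls,
  nonpositive evaluation times and invalid configurations raise
  immediately with the offending field named; non-finite sampler states
  abort with a state dump.

## Validation studies and their sizes

The acceptance studies (test suite and `scripts/acceptance.py`) use
problem sizes chosen to make each property decidable in minutes on one
CPU: quadrature calibration on a 3-subject toy against a 601×601 grid
(50 000 sweeps); credible-interval coverage pooled per transition over
20 replicates of n = 1000 (2500-iteration chains); frailty-variance
recovery at n = 2000; DIC preference over 10 replicates of n = 200
(4000-iteration, 2-chain fits); screening calibration over 500
replicates of n = 150.  Coverage is asserted per transition vector
(pooled over that transition's coefficients) because per-scalar
18-of-20 thresholds are not jointly attainable by a calibrated sampler
across 27 coefficients.

## Known limitations

- Log-normal errors only; no proportional-hazards variant.
- One shared frailty; no transition-specific frailty loadings or
  copula-based dependence.
- Conditional (not marginal) DIC and CPO, with the instability noted
  above for near-nested comparisons.
- The univariate screen uses log-rank tests; trend-aware alternatives
  for ordinal covariates would have more power.
- Credible intervals at n ≈ 284 are wide for subgroup effects (the
  8%-frequency stage-site group especially); single-cohort point
  estimates should be read accordingly.
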