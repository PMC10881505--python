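# aftid — Bayesian AFT illness-death modelling for semi-competing risks

`aftid` analyses cohorts in which a non-terminal event (disease
recurrence) can be censored by a terminal event (death) but not the other
way around — the *semi-competing risks* setting that arises naturally in
surgical cancer follow-up.  It was built around a colorectal-cancer use
case (time from surgery to recurrence and to cancer death, in months,
with stage, tumour site, age, grade, tumour size and chemotherapy
exposure as covariates), but any cohort in the same CSV schema can be
analysed.

## The model

The three transitions of the illness-death structure each get an
accelerated-failure-time (AFT) equation with log-normal errors:

```
log T_i1       = x_i' β₁ + γ_i + ε_i1        (health → recurrence)
log T_i2       = x_i' β₂ + γ_i + ε_i2        (health → death, no recurrence)
log(T_i2−T_i1) = x_i' β₃ + γ_i + ε_i3        (recurrence → death)
```

with `ε_ig ~ N(μ_g, σ_g²)` and a shared subject-specific frailty
`γ_i ~ N(0, θ)` that induces positive dependence between recurrence and
death.  `exp(β)` is a **time ratio** (TR): TR > 1 means multiplicatively
*longer* time to the event.  Priors are flat on each `(μ_g, β_g)` and
inverse-gamma IG(a, b) on each `σ_g²` and on `θ` (default a = b = 0.7).

Posterior sampling is a data-augmentation Gibbs sampler: censored
log-times are imputed from truncated normals, after which every full
conditional is conjugate (normal regression updates, inverse-gamma scale
updates, normal frailty updates).  Model variants are compared by DIC
(lower better) and LPML (higher better, from per-subject conditional
predictive ordinates).  Kaplan–Meier curves, median survival with
log(−log) Greenwood bands, cause-specific log-rank tests and p < 0.1
univariate screening cover the nonparametric side, and a synthetic-cohort
generator draws event histories from the generative form of the model so
the whole pipeline is testable without patient data.

## Worked example

```python
from aftid import (MCMCConfig, PriorSpec, SimulationConfig, fit_model,
                   km_estimate, median_survival, simulate_cohort,
                   time_ratio_table)

ds, truth = simulate_cohort(SimulationConfig(n=284), seed=7)
y1, d1, y2, d2 = ds.arrays()
print(f"recurrences: {d1.sum()}  deaths: {d2.sum()}")

curve = km_estimate(y2, d2)
med, (lo, hi) = median_survival(curve)
print(f"median survival {med:.1f} months (95% CI {lo:.1f}-{hi:.1f})")

mcmc = MCMCConfig(seed=8, n_iter=4000, n_burnin=2000, thin=2, n_chains=2)
samples = fit_model(ds, PriorSpec(), mcmc)
tr = time_ratio_table(samples, referents={"stage_site": "Early_RC", "grade": "well"})
row = tr.set_index(["covariate", "transition"]).loc[
    ("stage_site_Early_CC", "recurrence")]
print(f"Early_CC recurrence TR {row.TR:.3f} ({row.ci_low:.3f}-{row.ci_high:.3f})")
```

prints

```
recurrences: 138  deaths: 140
median survival 96.9 months (95% CI 86.1-108.9)
Early_CC recurrence TR 1.222 (0.792-1.876)
```

The cohort was simulated with an Early_CC recurrence coefficient of
ln 1.712 ≈ 0.54; at n = 284 the posterior interval is wide, and it
covers the generating value — single cohorts of this size locate
stage-site effects only coarsely, which is why the recovery studies in
the test suite average over many replicates at n = 1000.  The median
survival is the product-limit estimate on the death outcome of this
particular synthetic cohort.

A command line mirrors the library (`aftid simulate|describe|km|logrank|
fit|compare|run`); `aftid run --config cfg.yaml` executes the whole
sequence — descriptives, Kaplan–Meier with 12/36/60-month survival,
cause-specific log-rank by stage-site group, screening, model fit(s),
time-ratio tables and DIC/LPML — and writes a plain-text report bundle.

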