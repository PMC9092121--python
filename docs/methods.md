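# Methods

This note documents the statistical model, the numerical choices, what the
synthetic-data generator does and does not emulate, and the design decisions
taken where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Mortality model

All-cause mortality follows a Gompertz proportional-hazards law on the age
scale,

    h(a | x) = λ · exp(γ (a − 40)) · exp(x'β),

with age origin 40 (so λ is the hazard per year at age 40 and γ the
log-hazard slope per year of age). Covariates act log-linearly; exp(β) is a
hazard ratio constant over age. Because age is the time axis, "age
adjustment" is intrinsic: a single-covariate fit is already age-adjusted,
and the multivariable fit adds the remaining components or the score bands
plus education and family history of CVD. Subjects enter observation at
their baseline age, so the likelihood is left-truncated:

    ℓ = Σᵢ [ δᵢ log h(tᵢ|xᵢ) − (λ/γ) e^{xᵢ'β} (e^{γ(tᵢ−40)} − e^{γ(eᵢ−40)}) ],

with entry age eᵢ, exit age tᵢ and death indicator δᵢ; the γ → 0 limit is
the exponential model and is taken analytically (via `expm1`), not by
perturbation. Ignoring the entry ages on a cohort recruited at ages 40–79
biases the age slope badly; the test suite demonstrates this on simulated
data.

**Fitting.** The parameterisation is (log λ, γ, β) so the optimisation is
unconstrained. Starting values: γ = 0.09 (a typical adult mortality slope),
log λ from the stratum's crude death rate shifted to the age origin, β = 0.
BFGS with the analytic gradient is followed by Newton polishing (finite-
difference Hessian of the analytic score) until the gradient max-norm is
≤ 1e−6, with an iteration cap; failure raises a `ConvergenceError` naming
the stratum. The covariance matrix is the inverse observed information at
the optimum; Wald intervals use the normal quantile. Degenerate designs
(constant or collinear columns) and zero-event strata are rejected up
front; |β| > 10 triggers a separation warning, and γ̂ < 0 a defective-
survival warning. γ may be fixed (e.g. `fix_gamma=0` for the exponential
special case).

**Bayesian variant.** Independent normal priors — N(0, 10) on log λ and
each β, N(0, 1) on γ (weakly informative; an adult-mortality slope is a
small number). The default method is a Laplace approximation at the
posterior mode (fast and deterministic); a random-walk Metropolis sampler
with proposal covariance calibrated from the Laplace covariance
(scale 2.38/√d) is available, reports its acceptance rate and warns outside
[0.1, 0.6]. The sampler choice, priors and draw count are deliberately
exposed because no single convention exists for this model.

## Life tables

Single-year period tables run from age 40 to 102 with radix l₄₀ = 100,000.
For each interval [x, x+1): qx = 1 − S(x+1 | alive at x) from the model's
closed-form conditional survival; dx = lx·qx; Lx = l_{x+1} + a·dx with
separation factor a = 0.5 (deaths mid-interval, the standard choice for
single-year adult tables); Tx is the tail sum of Lx and ex = Tx/lx.

**Terminal interval.** The open interval at 102 is closed with model-based
tail person-years L₁₀₂ = l₁₀₂ · ê(102), where ê is the analytic Gompertz
mean residual life

    ê(a) = e^z E₁(z) / γ,   z = (λ/γ) e^{x'β} e^{γ(a−40)},

(E₁ the exponential integral; the γ = 0 limit is 1/(λe^{x'β})). This makes
the tabulated e₄₀ agree with the analytic mean instead of truncating at
102; a hard close-out (q₁₀₂ = 1, half-interval person-years) is available
via `terminal="close"` for the stricter reading of "ending at 102". The
scaled product e^z E₁(z) is evaluated directly below z = 50 and by the
classical continued fraction above, so extreme hazards do not overflow.

Score-band tables are built from one sex-specific model with band-indicator
covariates (profile = the band's indicator), not stratified refits — one
model, six profiles; adjustment covariates are held at their reference
levels, which cancels exactly in band-vs-band gains. Expectancy "at age X"
for X > 40 uses conditional survival from the same fitted model, not a
refit on survivors. All table identities (radix, monotone lx, dx = lx·qx,
Tx = ΣLy, ex = Tx/lx, ex ≤ e_{x+1} + 1) are asserted at construction.

Sub-annual steps (e.g. monthly, `step=1/12`) are supported; single-year
tables stay within 0.15 years of the closed form over the realistic hazard
range (λ ∈ [1e−5, 1e−3], γ ∈ [0.05, 0.14]) and monthly tables within 0.02,
as the acceptance tests verify.

## Uncertainty

Two engines give the sampling distribution of expectancies and gains:

* **subject bootstrap** (production default, B = 10,000): resample subjects
  with replacement within sex strata, refit, rebuild tables, recompute all
  targets. Non-convergent replicates are dropped and counted; more than 1%
  failures is an error.
* **parameter draws**: draw (log λ, γ, β) from N(estimate, vcov) and
  rebuild the tables per draw. Asymptotically equivalent and much faster;
  the test suite uses it with B = 200 where the bootstrap would dominate
  runtime, and checks that Laplace credible intervals match its widths.

Intervals are percentile (2.5/97.5 at the 95% level) in both engines — the
simplest defensible choice; BCa or normal-approximation intervals are out
of scope. All resampling is deterministic given one seed, split into
per-stratum streams via `SeedSequence`.

## Subgroups

Condition strata (CVD, cancer, hypertension, diabetes, kidney disease) are
*not* mutually exclusive — a subject with two conditions contributes to
both — and are fitted sex-specifically. Multimorbidity-count strata
(0/1/2/3+) partition the cohort exactly and pool the sexes with a sex
covariate, because sex-stratified counts in the high-multimorbidity cells
are too small. Strata are refit per subgroup (not interaction terms).
Strata retaining fewer than a configurable minimum of events (default 50),
or collapsing to a single score band, are skipped with a logged reason
rather than reported with unstable estimates.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
every "truth" available in closed form:

* ~20,000 men and ~26,000 women, entry ages uniform on 40–79;
* 21 years of administrative follow-up plus an independent exponential
  move-out censoring clock (default 0.005/year — a placeholder rate, since
  cohort reports rarely publish it; configurable);
* eight lifestyle components drawn as the minimal ordinal categories the
  scoring rules need, with per-sex healthy-response prevalences of the
  order seen in large Japanese questionnaire cohorts of the 1990s; an
  optional shared latent "healthiness" propensity (`latent_rho`) induces
  the co-occurrence of healthy behaviours seen in real band descriptives;
* death ages by inverse-CDF sampling from the Gompertz PH law conditional
  on survival to entry; defaults λ = 9e−4 (men) / 5e−4 (women), γ = 0.105,
  and β = −0.08 per lifestyle point. These defaults were chosen so the
  implied remaining life expectancies at 40 and top-band gains are of the
  magnitude a high-longevity national cohort exhibits (population e₄₀ in
  the low-to-high 40s, top-band gains of several years);
* a truth summary per sex × band: the mean over members of the analytic
  remaining expectancy at their own covariate profile (the expectancy of a
  mixed population is the mean of its members' expectancies).

One global seed is split deterministically into per-sex vectorised streams
(`SeedSequence.spawn`); same seed, same bytes. Per-subject streams were
considered and rejected: vectorised generation is orders of magnitude
faster and nothing downstream needs partial regeneration.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: community-level sampling design and clustering,
the exclusion cascade of a real survey, measurement error and
misclassification in self-reports, non-proportional or time-varying
lifestyle effects, dependent censoring, and incident (post-baseline)
comorbidity. Within-band score heterogeneity *is* emulated (the generator
applies a per-point effect while the analysis fits band indicators), so
band-level estimates are validated against a mildly misspecified truth, as
in real use.

## Validation designs and problem sizes

The test suite scales simulations to what the checks need, not more:
parameter recovery uses 20 cohorts of n = 20,000 under the default study
conditions; interval coverage uses 100 cohorts of n = 5,000 with B = 200
parameter draws; likelihood correctness uses quadrature on 100 subjects and
an independent Cox partial-likelihood fit on n = 10,000.

The qualitative subgroup check (gains monotone in score band and amplified
in comorbid strata at ages 50/65/80) uses a design powered for 36 strict
inequalities per replicate: band-balanced component prevalences (0.6, so
the extreme bands hold ~5–10% of subjects each), a higher-mortality cohort
(λ = 2e−3 men / 1.4e−3 women) so the strongly protected top band of the
comorbid stratum retains enough deaths for its contrast to be estimable,
multimorbidity 0 vs 1 strata (larger than any single condition), and
amplification −0.08/point on top of −0.10/point. With sparse extreme bands
or the default mortality level, the band 6 vs 7–8 contrast in the comorbid
stratum is only ~1.6 SE wide and adjacent-band inversions occur by chance;
the chosen design separates adjacent bands by roughly 3 SE.

## Known limitations

* The Gompertz law is assumed correct from 40 to 102; no frailty,
  cause-specific or competing-risks structure, and no time-varying
  covariates or lifestyle changes after baseline.
* Percentile intervals can undercover for strongly skewed estimands at
  small event counts; the subject bootstrap refits can fail in tiny strata
  (counted, and an error above 1%).
* The smoking point is ambiguous in common questionnaires ("current
  non-smoker" vs "never smoker"); both rules are implemented
  (`smoking_rule="current"` default, `"never"` optional) and results should
  state which was used.
* Drinkers below 1 g ethanol/day score 0 (outside the printed 1–46.0
  range) — a deliberate, documented reading of the cut-off.
* The reference-table comparison treats the reference as exact (no
  sampling error in national tables).
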