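# lifegain

Lifestyle scoring, Gompertz proportional-hazards mortality modelling and
life-table lifetime-gain estimation for prospective cohort studies.

## The scientific problem

Epidemiological cohorts routinely ask: *how many extra years of life are
associated with adopting healthy behaviours, and does the benefit persist
into old age and in people who already carry chronic disease?*  `lifegain`
implements the full analysis chain used to answer that question on a
questionnaire cohort with long administrative follow-up:

1. **Scoring.** Eight modifiable behaviours each score one point — daily
   fruit, daily fish, near-daily milk, habitual walking (≥ the 0.5–1 h/day
   category) or sports (≥ 5 h/week), BMI 21.0–25.0 kg/m², alcohol at most
   46.0 g ethanol/day (non-drinkers included), non-smoking, and sleep of
   5.5–7.4 h/day — giving a 0–8 score analysed in six bands
   (0–2, 3, 4, 5, 6, 7–8). Records missing any component are excluded
   (complete-case), never silently scored 0.
2. **Mortality model.** Sex-specific Gompertz proportional hazards on the
   age scale with delayed entry:

   ```
   h(a | x) = λ · exp(γ (a − 40)) · exp(x'β)
   ```

   where λ is the hazard at age 40, γ the log-hazard slope per year of age
   and x the score-band indicators plus adjustment covariates (education,
   family history of CVD). Subjects enter at their baseline age, so the
   likelihood conditions on survival to entry (left truncation). Maximum
   likelihood with the observed-information covariance, plus a Bayesian
   variant (Laplace approximation or random-walk Metropolis).
3. **Life tables.** The fitted hazard is converted to single-year period
   life tables over ages 40–102 with a radix of 100,000 at age 40
   (`qx, lx, dx, Lx, Tx, ex`); the terminal interval is closed with the
   analytic Gompertz mean residual life, `e(a) = e^z E₁(z)/γ` with
   `z = (λ/γ)·e^{x'β}·e^{γ(a−40)}`.
4. **Lifetime gains.** The gain for a score band at an index age
   (40/50/65/80) is the difference in remaining life expectancy `ex` against
   the 0–2 band. 95% intervals come from a subject bootstrap (resample
   within sex, refit, rebuild tables) or a faster parameter-draw Monte
   Carlo from the estimator's normal approximation; posterior credible
   intervals are available from the Bayesian fit.
5. **Subgroups.** Gains are re-estimated within comorbidity strata (CVD,
   cancer, hypertension, diabetes, kidney disease) and within multimorbidity
   counts (0/1/2/3+), the latter pooling sexes with a sex covariate.

Because cohort data of this kind are rarely shareable, the package ships a
first-class synthetic-cohort generator with known Gompertz truth, so every
stage is testable end-to-end against closed-form answers.

## Worked example

```python
import lifegain as lg

cfg = lg.SimulationConfig(n_men=8000, n_women=10000, seed=42)
cohort, truth = lg.generate_cohort(cfg)
kept, report = lg.complete_case_filter(lg.score_records(cohort))

model = lg.GompertzPH.from_dataframe(
    kept, covariates=("band", "education", "family_history_cvd"), sex="M")
res = model.fit()
print(res.summary())
```

```
Gompertz proportional-hazards regression (delayed entry)
Stratum: men   n = 8000   events = 3041
Age origin: 40   log-likelihood = -12666.668
----------------------------------------------------------------
parameter               estimate   std err        z       HR
log_lambda               -7.1836    0.0876   -82.03
gamma                     0.1048    0.0019    55.15
band_3                   -0.1111    0.0541    -2.05    0.895
band_4                   -0.1906    0.0533    -3.58    0.826
band_5                   -0.3066    0.0592    -5.18    0.736
band_6                   -0.3665    0.0860    -4.26    0.693
band_7-8                 -0.6509    0.1598    -4.07    0.522
education                 0.0162    0.0456     0.35    1.016
family_history_cvd        0.1008    0.0369     2.73    1.106
----------------------------------------------------------------
lambda (hazard at 40) = 0.00075895   gamma = 0.1048 /yr
```

The hazard ratios fall monotonically with the score band: men with 7–8
points have about half (HR 0.52) the all-cause mortality of the 0–2
reference band at any age. Turning the fit into life tables:

```python
top = res.life_table({"band_7-8": 1.0})
ref = res.life_table({})                      # the 0-2 reference band
print(top.expectancy_at(40.0))                # 47.9 years
print(lg.lifetime_gain(top, ref, 40.0))       # 6.1 years

spec = lg.AnalysisSpec(covariates=("band", "education", "family_history_cvd"),
                       index_ages=(40.0,), sexes=("M",))
boot = lg.bootstrap_estimates(kept, spec,
                              lg.ResampleSpec(method="parameter_draws",
                                              B=1000, seed=7))
```

A 40-year-old man in the healthiest band can expect 47.9 more years —
6.1 years (95% CI 3.1–8.9) longer than one in the 0–2 band. (This cohort
was generated with a true per-point log hazard ratio of −0.08, whose
closed-form top-band gain is 4.0 years; the example estimate sits well
inside its interval.)

The same analysis runs from the shell:

```bash
lifegain simulate --n-men 8000 --n-women 10000 --seed 42 --out cohort.csv
lifegain run --cohort cohort.csv --seed 1 --outdir out
```

which writes the scored cohort, Table-1-style descriptives, per-band life
tables, gains with intervals, subgroup gains and a JSON manifest of every
output with content hashes.

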