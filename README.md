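# sleepreg

Analysis pipeline linking accelerometer-derived **sleep regularity** to a
panel of **adiposity measures**, for epidemiologists working with
minute-epoch wrist-actigraphy surveys (e.g. national health examination
surveys that release minute-level predicted sleep/wake states).

The pipeline covers, end to end:

1. **Actigraphy QC** — parse minute-epoch state predictions
   (wake/sleep/non-wear/unknown), recode to a binary-with-missing sleep
   variable, and apply inclusion filters: unflagged 60-second minutes
   only, complete 1,440-minute days, < 2 h non-wear per day, ≥ 3
   consecutive valid days containing a Saturday or Sunday, ≤ 30%
   missingness; every exclusion is counted in a per-reason ledger.
2. **Sleep Regularity Index (SRI)** — for a sleep/wake series
   s₁, …, s_N with lag c = 1,440 minutes,

   SRI = −100 + 200 · (1 − (1/N_v) · Σᵢ |sᵢ − sᵢ₊c|),

   summing over the N_v comparisons with both epochs observed. SRI = 100
   for a perfectly 24-h-periodic pattern, ≈ 0 for random sleep, −100 for
   daily inversion. A Monte-Carlo null (100,000 replicates of two days of
   i.i.d. Bernoulli(0.5) minutes) has a 99% quantile range of ±6.8;
   observed values below −6.8 are replaced by draws from a normal with
   the null's mean and SD, and exposure quintiles are assigned.
3. **Adiposity panel** — BMI (rounded to one decimal), waist
   circumference, WHtR, ABSI, BRI, VAI, LAP, SAD, SADHtR, fat-mass index
   and percent body fat, with 1st/99th-percentile winsorization and a
   pairwise Pearson correlation summary.
4. **Survey-weighted models** — weighted least squares of log(outcome) on
   SRI quintiles and covariates (four nested model structures, up to
   quintile × sex and quintile × ethnicity interactions), design-based
   sandwich covariance, **multiplication factors**
   MF = exp(linear combination of coefficients) with percentile-bootstrap
   95% CIs, Rao-Scott corrected likelihood-ratio tests of effect
   modification, a quintile-median trend test, kNN (Gower) covariate
   imputation, and predicted-outcome curves across the full SRI range.
5. **Synthetic cohorts** — a first-class generator producing minute-level
   actigraphy of controllable regularity, survey-style covariates and
   weights, and anthropometry whose log(BMI) carries a known
   quintile × sex × ethnicity effect grid, so every stage can be tested
   against ground truth.

## Worked example

```python
import numpy as np
from sleepreg import (GeneratorConfig, generate_cohort, fit_model,
                      multiplication_factors, interaction_test)

cohort = generate_cohort(GeneratorConfig(n_participants=4000, seed=21,
                                         nonwear_rate=0.0))
records = cohort.covariates.copy()
records["quintile"] = cohort.sri_quintile
records["bmi"] = (cohort.anthropometry["weight_kg"]
                  / cohort.anthropometry["height_m"] ** 2)

fit3 = fit_model(records, 3, outcome="bmi")   # covariates + quintile x sex
mf = multiplication_factors(fit3)
print(mf[mf["contrast"] == "Q5 vs Q1"][["sex", "mf"]])
test = interaction_test(fit3, fit_model(records, 2, outcome="bmi"))
print(test["p_value"])
```

prints

```
   sex    mf
  Male 0.988
Female 0.917
4.17e-08
```

The generator's truth sets women's BMI 8% lower (MF 0.92) and men's 2%
lower (MF 0.98) in the most- versus least-regular sleep quintile; the
fitted multiplication factors recover both, and the Rao-Scott test flags
the sex difference. `examples/` contains one narrative script per
capability (SRI basics, QC, adiposity panel, survey models, full
pipeline); `sleepreg run --config run.yaml` runs everything from a single
YAML config and writes the artifact set (ledger, descriptives, MF tables,
interaction tests, prediction curves, manifest).

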