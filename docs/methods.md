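# Methods

## The exposure: Sleep Regularity Index

The SRI of a binary sleep/wake series s₁, …, s_N (1 = sleep, 0 = wake,
NA = non-wear/unknown/quality-flagged) at lag c = 1,440 minutes is

    SRI = −100 + 200 · (1 − (1/N_v) Σᵢ |sᵢ − sᵢ₊c|),

where the sum runs over the N_v index pairs with both epochs observed;
pairs containing an NA contribute nothing and are excluded from N_v. The
index is the affinely rescaled probability of being in the same state 24 h
apart: 100 for exact daily periodicity, 0 in expectation under
state-independent random sleep, −100 when each day inverts the previous
one. A participant whose selected window admits no valid pair (N_v = 0)
has no defined SRI and is excluded. For multi-day windows the comparisons
span the whole window (N_v up to N − 1,440), and the SRI is invariant to
complementing the series (s → 1 − s), since mismatch indicators are.

### Null distribution and winsorization

Under two days of i.i.d. Bernoulli(0.5) minutes the mismatch mean is an
average of 1,440 i.i.d. Bernoulli(0.5) indicators, so SRI ~ approx.
Normal(0, 200·√(0.25/1440)) with SD ≈ 2.64 and a central 99% range of
±200·2.576·√(0.25/1440) ≈ ±6.79. `simulate_null` reproduces this by
direct Monte Carlo (default 100,000 replicates) and returns the 0.5%/99.5%
quantiles and the symmetric cutoff (−6.8 to the printed precision).
Observed SRI values below the cutoff are indistinguishable from — or more
extreme than — random sleep; they are replaced by draws from an
*untruncated* Normal(null mean, null SD), so a rare replacement below the
cutoff is accepted rather than biasing the replacement distribution
upward. Values at or above the cutoff pass through bit-identically, which
preserves zero as the random-sleep reference and leaves the positive range
untouched.

Exposure quintiles are assigned on the analytic sample without survey
weights (boundaries at the order statistics ⌈n·j/5⌉; tied values fall to
the lower quintile), and the per-quintile median SRI is retained as the
trend score.

## Actigraphy quality control

States are recoded sleep → 1, wake → 0, non-wear/unknown → NA; minutes
with a quality flag or other than 60 measured seconds are *kept as
timesteps but set to NA*, which reconciles "only unflagged 60-second
minutes contribute data" with the requirement that a day comprise exactly
1,440 timesteps. Day validity requires all 1,440 minutes present and
strictly fewer than 120 non-wear minutes (the "< 2 hours" rule read
strictly: exactly 120 fails); non-wear is counted from the state field,
not from seconds measured. The analysis window is the longest run of ≥ 3
consecutive valid days containing a Saturday or Sunday, ties broken by
earliest start. Missingness of the binary sleep variable is evaluated on
the *selected window* (the alternative — before selection — is not
distinguishable from the usual description of such filters; evaluating
after selection matches the window actually analysed) and must not exceed
30% (exactly 30% is retained).

The exclusion ledger counts each participant once under the first failing
rule. Two attributions are refinements beyond the pipeline order: when a
participant has *no* valid day at all, the modal per-day failure reason
(incomplete day vs excess non-wear) is charged; and when the missingness
rule fails, the participant is charged to `flagged_minutes` if the
majority of missing minutes stem from quality-flag/short-minute recoding
rather than from non-wear/unknown states, and to `excess_missingness`
otherwise. This keeps device-quality problems separable from behavioural
non-wear in the ledger.

## Adiposity panel

BMI = weight/height² (kg/m²), rounded half-up to one decimal at
computation time. The further measures: WHtR = WC/height (both cm);
ABSI = WC_m/(BMI^(2/3)·height_m^(1/2)), reported in SI metres — some
published tables print ABSI × 10 (≈ 0.8 rather than ≈ 0.08); the SI value
is produced here and not rescaled; BRI = 364.2 − 365.5·√(1 −
(WC/2π)²/(0.5·height)²) (cm), the ellipse-eccentricity form; VAI with the
standard sex-specific constants (men: (WC/(39.68 + 1.88·BMI))·(TG/1.03)·
(1.31/HDL); women: (WC/(36.58 + 1.89·BMI))·(TG/0.81)·(1.52/HDL), TG and
HDL in mmol/L); LAP = (WC − 65)·TG for men and (WC − 58)·TG for women;
FMI = fat mass/height²; percent fat = 100·fat mass/weight; SADHtR =
SAD/height (cm). Fat-mass-derived measures propagate missingness (DXA fat
mass is absent for roughly half of participants in the emulated survey)
and are analysed complete-case, outside the imputation.

Winsorization caps BMI, WC, fat mass, percent fat and SAD at the sample
1st/99th percentiles, computed with linear interpolation between order
statistics. BMI is rounded before capping. Capping with *fixed* bounds is
idempotent; re-estimating bounds from already-capped data moves the
percentiles slightly inward, so the bounds are exposed for reproducible
reapplication.

## Survey-weighted models

Outcomes are log-transformed (BMI is right-skewed) and fitted by weighted
least squares. Model 1 adjusts for age and sex; model 2 adds ethnicity,
education, income, occupation, marital status, alcohol, smoking,
vitamin D, caloric intake, depression score and activity; model 3 adds
quintile × sex and model 4 quintile × ethnicity interactions. Survey
weights from two 2-year cycles combine by halving. The reported
covariance is the design-based sandwich

    V(β̂) = (XᵀWX)⁻¹ [Σᵢ (wᵢeᵢ)² xᵢxᵢᵀ] (XᵀWX)⁻¹,

treating participants as independent sampling units: the multistage
strata/PSU structure of a real survey is deliberately out of scope, and
independent units are what the synthetic cohorts actually are, so the
variance statement is honest for the data the package analyses. An
unweighted refit supports the sensitivity analysis.

Multiplication factors are exponentiated linear combinations of the
quintile main effect plus any applicable sex/ethnicity interaction terms;
MF(Q1 vs Q1) ≡ 1, and stepwise contrasts telescope
(MF(Q5 vs Q1) = Π MF(Q_{j+1} vs Q_j)). Confidence intervals are
percentile bootstrap over participants (weights carried along; default
B = 1,000), seed-reproducible; resamples on which the estimator fails
(e.g. an empty stratum cell making the design rank-deficient) are dropped
up to a 5% budget, beyond which the run aborts.

Effect modification uses a working Gaussian likelihood-ratio statistic,
LR = Σw · log(SSE_w,reduced/SSE_w,full), corrected first-order à la
Rao-Scott: LR is divided by the mean generalized design effect of the
tested coefficients (mean eigenvalue of V_model⁻¹V_design under the full
fit) and referred to χ² on the number of tested terms. The statistic is
invariant to rescaling the weights, and with unit weights and
homoskedastic errors it reduces to the classical LR test (verified against
that oracle). A second-order Satterthwaite correction is a possible
extension. P_trend enters the per-quintile median SRI as a single
continuous score (the standard epidemiological convention) and reports the
design-based Wald p-value of its coefficient.

Prediction curves use a continuous-SRI variant of model 4 (linear SRI
plus the same sex and ethnicity interactions — the quintile version is a
step function, and a linear term is the simplest faithful continuous
parameterization). Curves are evaluated over SRI 0–100 at a reference
covariate profile: survey-weighted medians for skewed continuous
covariates (|weighted skewness| > 1 — the threshold is a package choice),
weighted means otherwise, weighted modal categories. Percentile-bootstrap
bands quantify sampling uncertainty; an optional dispersion envelope
(default 200,000 covariate vectors resampled from the data) shows the
spread of predictions over the covariate distribution and is accordingly
wider than the fixed-profile bands.

Missing covariates are imputed by kNN (k = 5) under Gower distance:
range-normalized absolute differences for continuous, 0/1 mismatch for
categorical covariates, averaged over dimensions observed in both rows;
continuous cells take the donor median, categorical the donor mode.
Fat-mass variables stay out of the imputation. The meal-timing sensitivity
refits model 4 plus the weekday-weekend differences in last-meal timing
and eating window on complete cases, aborting below 100 usable rows.

## Synthetic cohort: what it emulates and what it does not

Sleep is one consolidated nightly block (23:00 onset, 480 min duration by
default) with Normal(0, σ) jitter on onset and duration per night; σ = 0
gives SRI = 100 exactly, larger σ lowers the SRI monotonically, and an
i.i.d.-Bernoulli mode reproduces the null regime (SRI ≈ 0). In cohort
mode each participant's latent σ is `onset_jitter_sd · Exponential(1)`;
the default scale (160 min) was set so the cohort's median SRI ≈ 61,
matching the descriptive SRI distribution of the emulated survey
population. Non-wear is injected as one contiguous block per day covering
`nonwear_rate` of the minutes. Weekday labels start Monday by default
(Friday when fewer than 7 days are generated, so a weekend day is always
present); tests construct weekend-rule violations by relabelling.

Covariate categories and mixing proportions loosely match the margins of
a large US survey cohort (six ethnicity levels, five education levels,
etc.); the *joint* distribution is independent across covariates, which
real data is not. log(BMI) = log(28) + log(MF grid) + 0.001·(age − 50) +
Normal(0, 0.12); covariate effects other than the small age term default
to zero to isolate exposure-effect recovery. The default MF grid is
log-linear in quintile with Q5-vs-Q1 factors 0.92 (women) and 0.98 (men),
uniform across ethnicity — the headline contrast of the emulated study;
any (ethnicity, sex, quintile) grid can be supplied. Outcomes are
generated from each participant's *assigned* quintile, so recovery has an
exact reference. Remaining anthropometry is generated conditional on BMI
(WC = 2.3·BMI + 35 + noise, etc.), which yields corr(BMI, WC) ≈ 0.9 but
weaker BMI–BRI/VAI correlations than real data; the panel formulas, not
the generator's correlation structure, are what the tests certify.

Noise scales: the residual SD of log(BMI), 0.12, is consistent with a
marginal log-BMI SD of ≈ 0.24 and substantial covariate-explained
variance, and survey weights are lognormal with median 1 and σ = 0.35
(moderate unequal weighting, in line with the emulated study's report
that unweighted results were qualitatively unchanged). Under these
defaults, at n = 7,000 the sex-specific Q5-vs-Q1 factors are recovered
within ±0.02 and the sex-interaction test rejects at p < 0.001
essentially always — the regime the recovery tests certify. Passing tests
show the *pipeline* recovers known structure under survey-realistic noise;
they do not validate the behavioural realism of the sleep model or the
covariate joint distribution.

Everything is driven by `numpy.random.default_rng` with explicit seeds
(per-stage seeds in the pipeline config); regeneration with the same seed
is bit-identical, including the winsorization draws and bootstrap.

## Problem sizes in the shipped tests

The test suite exercises recovery at n = 7,000 (100 replicates, the
headline-contrast conditions), bootstrap coverage at n = 1,500 with
B = 500 over 200 replicates, and the Monte-Carlo null at its full 100,000
draws; unit tests use cohorts of 200–2,000 and toy series where hand
oracles exist. These sizes were chosen so each statistical claim is tested
at a scale where its Monte-Carlo error is small relative to the asserted
tolerance.

## Known limitations

* No strata/PSU machinery: design variance treats participants as
  independent; applying the package to a real multistage survey would
  understate variance.
* First-order Rao-Scott only; no Satterthwaite degrees-of-freedom
  adjustment.
* Single kNN completion (no multiple-imputation variance propagation),
  matching the emulated analysis.
* The sleep generator produces one consolidated block per night — no
  naps, split sleep, or circadian drift; SRI values near −100 arise only
  from constructed series, as in real populations.
* ABSI unit convention differs by a factor of 10 from some published
  tables (documented above).
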