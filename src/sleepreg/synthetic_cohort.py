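"""Synthetic cohort generator with known ground truth.

Emulates the inputs of an accelerometer-based sleep-regularity study of
adiposity: minute-level sleep/wake actigraphy of controllable regularity,
a demographic/lifestyle covariate table with survey weights, and an
anthropometry table whose log(BMI) carries known quintile x sex x
ethnicity multiplicative effects.

Sleep model
-----------
Each participant sleeps in one consolidated nightly block.  Night-to-night
regularity is controlled by ``onset_jitter_sd``: onset and duration of each
block are the base schedule (23:00, ``sleep_duration_mean`` minutes) plus
independent Normal(0, sd) jitter.  Zero jitter yields identical days and
hence SRI = 100; large jitter drives the SRI towards 0.  Setting
``iid_sleep_prob`` replaces the block model with i.i.d. Bernoulli minutes
(the SRI null regime).  Non-wear is injected as one contiguous block per
day covering ``nonwear_rate`` of the day's minutes.

Outcome model
-------------
log(BMI) = log(baseline) + log(MF(ethnicity, sex, quintile))
           + beta_age * (age - 50) + Normal(0, residual_sd_logbmi),
with the multiplication-factor (MF) grid recorded in
:class:`SyntheticTruth` before noise is added.  The remaining anthropometry
(height, weight, waist circumference, sagittal abdominal diameter, fat
mass) and lipids are generated conditional on BMI so that corr(BMI, WC)
exceeds 0.85 in moderate samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy_qc import WEEKDAYS, MINUTES_PER_DAY

ETHNICITY_LEVELS = ("Mexican American", "Other Hispanic", "Non-Hispanic White",
                    "Non-Hispanic Black", "Non-Hispanic Asian",
                    "Other Race - Including Multi-Racial")
ETHNICITY_PROPS = (0.12, 0.096, 0.41, 0.234, 0.11, 0.03)

EDUCATION_LEVELS = ("Less Than 9th Grade", "9-11th Grade", "High School Grad/GED",
                    "Some College or AA degree", "College Graduate or above")
EDUCATION_PROPS = (0.091, 0.137, 0.221, 0.300, 0.251)

INCOME_LEVELS = ("< $20,000", ">= $20,000")
INCOME_PROPS = (0.23, 0.77)

OCCUPATION_LEVELS = ("Working", "Retired or Student", "Unable to Work",
                     "Unemployed", "Other")
OCCUPATION_PROPS = (0.515, 0.237, 0.178, 0.046, 0.024)

MARITAL_LEVELS = ("Married", "Widowed", "Divorced", "Separated",
                  "Never married", "Living with partner")
MARITAL_PROPS = (0.509, 0.091, 0.116, 0.033, 0.183, 0.068)

ALCOHOL_LEVELS = ("Heavy Drinker", "Moderate Drinker", "Never/Non-Drinker")
ALCOHOL_PROPS = (0.025, 0.802, 0.173)

SMOKING_LEVELS = ("Heavy smoker", "Light smoker", "Moderate smoker",
                  "Non smokers", "Previous smoker")
SMOKING_PROPS = (0.109, 0.064, 0.019, 0.561, 0.247)

SEX_LEVELS = ("Male", "Female")
SEX_PROPS = (0.47, 0.53)

CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS, "ethnicity": ETHNICITY_LEVELS,
    "education": EDUCATION_LEVELS, "income": INCOME_LEVELS,
    "occupation": OCCUPATION_LEVELS, "marital": MARITAL_LEVELS,
    "alcohol": ALCOHOL_LEVELS, "smoking": SMOKING_LEVELS,
}
CONTINUOUS_COVARIATES = ("age", "vitamin_d", "caloric_intake", "phq9", "activity")

BASE_ONSET_MINUTE = 23 * 60      # 23:00 local clock


def default_true_mf(mf_q5_female: float = 0.92, mf_q5_male: float = 0.98) -> dict:
    """Sex-specific MF grid, log-linear in quintile between Q1 (1.0) and Q5.

    Keys are (ethnicity, sex, "Qj") with "*" wildcards; the defaults mirror
    the headline contrast of the emulated study (women 0.92, men 0.98 for
    Q5 vs Q1, uniform across ethnicity).
    """
    grid = {}
    for sex, mf5 in (("Female", mf_q5_female), ("Male", mf_q5_male)):
        for q in range(2, 6):
            grid[("*", sex, f"Q{q}")] = float(np.exp(np.log(mf5) * (q - 1) / 4))
    return grid


def resolve_mf(true_mf: dict, ethnicity: str, sex: str, quintile: int) -> float:
    """Look up MF(quintile vs Q1) with wildcard fallback; Q1 is identically 1."""
    if quintile == 1:
        return 1.0
    key = f"Q{quintile}"
    for k in ((ethnicity, sex, key), ("*", sex, key),
              (ethnicity, "*", key), ("*", "*", key)):
        if k in true_mf:
            mf = true_mf[k]
            if not mf > 0:
                raise ValueError(f"true_mf for {k} must be positive, got {mf}")
            return float(mf)
    raise KeyError(f"no true_mf entry for ({ethnicity}, {sex}, {key})")


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_participants: int
    n_days: int = 7
    onset_jitter_sd: float = 160.0         # minutes; 0 => perfectly regular
    sleep_duration_mean: float = 480.0     # minutes
    nonwear_rate: float = 0.02             # fraction of each day's minutes
    iid_sleep_prob: float | None = None    # if set, i.i.d. Bernoulli sleep
    covariate_missingness: dict = field(default_factory=dict)
    fat_mass_missing: float = 0.0          # DXA-style missingness, outside kNN scope
    true_mf: dict = field(default_factory=default_true_mf)
    baseline_bmi: float = 28.0             # kg/m^2 at the reference profile
    beta_age: float = 0.001                # per year on log(BMI)
    residual_sd_logbmi: float = 0.12
    weight_distribution: tuple = ("lognormal", {"sigma": 0.35})
    start_weekday: str | None = None       # default: Mon (Fri when n_days < 7)
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1 or self.n_participants < 1:
            raise ValueError("n_participants and n_days must be >= 1")
        if self.onset_jitter_sd < 0 or not (0 <= self.nonwear_rate <= 1):
            raise ValueError("jitter must be >= 0 and nonwear_rate in [0,1]")
        for k, f in self.covariate_missingness.items():
            if not (0 <= f <= 0.30):
                raise ValueError(f"missingness for {k} must be in [0, 0.30]")
        for v in self.true_mf.values():
            if not v > 0:
                raise ValueError("true_mf values must be positive")
        if self.start_weekday is None:
            self.start_weekday = "Mon" if self.n_days >= 7 else "Fri"
        if self.start_weekday not in WEEKDAYS:
            raise ValueError(f"unknown weekday {self.start_weekday!r}")

    def weekdays(self) -> list[str]:
        i0 = WEEKDAYS.index(self.start_weekday)
        return [WEEKDAYS[(i0 + d) % 7] for d in range(self.n_days)]


@dataclass
class SyntheticTruth:
    """Ground truth recorded before noise is added; immutable by convention."""

    jitter_sd: np.ndarray            # per-participant latent regularity (minutes)
    true_mf: dict                    # (ethnicity|*, sex|*, Qj) -> MF
    baseline_log_bmi: float
    beta_age: float
    residual_sd_logbmi: float

    def expected_log_bmi(self, ethnicity, sex, quintile, age) -> float:
        """Noise-free log(BMI) for one covariate/exposure combination."""
        mf = resolve_mf(self.true_mf, ethnicity, sex, int(quintile))
        return self.baseline_log_bmi + np.log(mf) + self.beta_age * (age - 50.0)

    def to_jsonable(self) -> dict:
        return {
            "jitter_sd": np.asarray(self.jitter_sd).tolist(),
            "true_mf": {"|".join(k): v for k, v in self.true_mf.items()},
            "baseline_log_bmi": self.baseline_log_bmi,
            "beta_age": self.beta_age,
            "residual_sd_logbmi": self.residual_sd_logbmi,
        }


def _participant_rng(config: GeneratorConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 7919, index])


def _sleep_matrix(config: GeneratorConfig, jitter_sd: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Sleep/wake matrix (n, n_days*1440) with NaN for non-wear minutes."""
    n = len(jitter_sd)
    T = config.n_days * MINUTES_PER_DAY
    if config.iid_sleep_prob is not None:
        sleep = (rng.random((n, T)) < config.iid_sleep_prob).astype(np.float32)
    else:
        sd = np.asarray(jitter_sd, dtype=float)[:, None]
        delta = np.zeros((n, T + 1), dtype=np.int8)
        row = np.arange(n)
        for d in range(-1, config.n_days):
            onset = (d * MINUTES_PER_DAY + BASE_ONSET_MINUTE
                     + rng.normal(0.0, 1.0, (n, 1)) * sd)
            dur = np.clip(config.sleep_duration_mean
                          + rng.normal(0.0, 1.0, (n, 1)) * sd, 60.0, 1200.0)
            start = np.clip(np.rint(onset), 0, T).astype(int).ravel()
            end = np.clip(np.rint(onset + dur), 0, T).astype(int).ravel()
            np.add.at(delta, (row, start), 1)
            np.add.at(delta, (row, end), -1)
        sleep = (np.cumsum(delta, axis=1, dtype=np.int8)[:, :T] > 0
                 ).astype(np.float32)

    block = int(round(config.nonwear_rate * MINUTES_PER_DAY))
    if block > 0:
        row = np.arange(n)
        for d in range(config.n_days):
            start = (d * MINUTES_PER_DAY
                     + rng.integers(0, MINUTES_PER_DAY - block, n))
            for off in range(block):   # block <= ~170 min for valid configs
                sleep[row, start + off] = np.nan
    return sleep


def generate_sleep_matrix(config: GeneratorConfig
                          ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Cohort sleep matrix plus weekday labels and per-participant jitter.

    The latent regularity of participant i is drawn as
    ``onset_jitter_sd * Exponential(1)``, spreading the cohort across the
    SRI scale while keeping expected regularity monotone in the config knob.
    """
    rng = np.random.default_rng([config.seed, 104729])
    jitter = config.onset_jitter_sd * rng.exponential(1.0, config.n_participants)
    values = _sleep_matrix(config, jitter, rng)
    return values, config.weekdays(), jitter


def generate_sleep_series(config: GeneratorConfig, participant_index: int
                          ) -> pd.DataFrame:
    """Minute-epoch records (EpochRecord rows) for one participant.

    Uses ``config.onset_jitter_sd`` directly as this participant's jitter,
    so the config examples (0 jitter -> SRI 100) hold exactly.  Output is a
    frame with the canonical epoch CSV columns; non-wear minutes carry
    state ``nonwear``, all minutes are unflagged with 60 measured seconds.
    """
    rng = _participant_rng(config, participant_index)
    values = _sleep_matrix(config, np.array([config.onset_jitter_sd]), rng)[0]
    return epochs_frame(values, config.weekdays(),
                        participant_id=f"P{participant_index:06d}")


def epochs_frame(values: np.ndarray, weekdays: list[str],
                 participant_id: str) -> pd.DataFrame:
    """Expand one sleep vector into minute-epoch rows."""
    T = len(values)
    n_days = T // MINUTES_PER_DAY
    state = np.where(np.isnan(values), "nonwear",
                     np.where(values == 1.0, "sleep", "wake"))
    return pd.DataFrame({
        "participant_id": participant_id,
        "day_index": np.repeat(np.arange(1, n_days + 1), MINUTES_PER_DAY),
        "weekday": np.repeat(np.asarray(weekdays[:n_days]), MINUTES_PER_DAY),
        "minute_of_day": np.tile(np.arange(MINUTES_PER_DAY), n_days),
        "state": state,
        "quality_flagged": False,
        "seconds_measured": 60,
    })


def generate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Covariate table with survey weights and MCAR missingness.

    Categorical mixing proportions loosely match the margins of a large US
    survey cohort; continuous covariates use plausible right-skewed or
    symmetric families.  Weights come from ``config.weight_distribution``
    (default lognormal, median 1).
    """
    rng = np.random.default_rng([config.seed, 15485863])
    n = config.n_participants
    df = pd.DataFrame({"participant_id": [f"P{i:06d}" for i in range(n)]})
    for name, (levels, props) in {
        "sex": (SEX_LEVELS, SEX_PROPS),
        "ethnicity": (ETHNICITY_LEVELS, ETHNICITY_PROPS),
        "education": (EDUCATION_LEVELS, EDUCATION_PROPS),
        "income": (INCOME_LEVELS, INCOME_PROPS),
        "occupation": (OCCUPATION_LEVELS, OCCUPATION_PROPS),
        "marital": (MARITAL_LEVELS, MARITAL_PROPS),
        "alcohol": (ALCOHOL_LEVELS, ALCOHOL_PROPS),
        "smoking": (SMOKING_LEVELS, SMOKING_PROPS),
    }.items():
        p = np.asarray(props) / np.sum(props)
        df[name] = rng.choice(levels, size=n, p=p)
    df["age"] = np.clip(rng.normal(51, 16, n), 20, 80).round(0)
    df["vitamin_d"] = rng.lognormal(np.log(63), 0.40, n).round(1)
    df["caloric_intake"] = rng.lognormal(np.log(1917), 0.35, n).round(0)
    df["phq9"] = rng.poisson(2.5, n).astype(float)
    df["activity"] = rng.gamma(2.2, 3.6, n).round(2)

    family, params = config.weight_distribution
    if family == "lognormal":
        w = rng.lognormal(params.get("mean", 0.0), params.get("sigma", 0.5), n)
    elif family == "uniform":
        w = rng.uniform(params.get("low", 0.5), params.get("high", 1.5), n)
    elif family == "constant":
        w = np.full(n, params.get("value", 1.0))
    else:
        raise ValueError(f"unknown weight family {family!r}")
    df["survey_weight"] = w

    for col, frac in config.covariate_missingness.items():
        if frac > 0 and col in df.columns:
            mask = rng.random(n) < frac
            df.loc[mask, col] = np.nan
    return df


def generate_outcomes(covariates: pd.DataFrame, sri_quintile: np.ndarray,
                      truth: SyntheticTruth, config: GeneratorConfig
                      ) -> pd.DataFrame:
    """Anthropometry/lipid table with the log-linear BMI structure.

    log(BMI) carries the truth's MF grid (by ethnicity, sex, assigned
    quintile) plus a small age effect and Gaussian residual; the other
    measures are generated conditional on BMI.
    """
    rng = np.random.default_rng([config.seed, 32452843])
    n = len(covariates)
    q = np.asarray(sri_quintile, dtype=int)
    if len(q) != n:
        raise ValueError("quintile vector must match covariates")
    log_mf = np.array([
        np.log(resolve_mf(truth.true_mf, e, s, qi))
        for e, s, qi in zip(covariates["ethnicity"], covariates["sex"], q)
    ])
    age = covariates["age"].fillna(50.0).to_numpy(dtype=float)
    log_bmi = (truth.baseline_log_bmi + log_mf
               + truth.beta_age * (age - 50.0)
               + rng.normal(0.0, truth.residual_sd_logbmi, n))
    bmi = np.exp(log_bmi)

    male = covariates["sex"].eq("Male").to_numpy()
    height = np.clip(np.where(male, rng.normal(1.76, 0.07, n),
                              rng.normal(1.62, 0.065, n)), 1.35, 2.1)
    weight = bmi * height ** 2
    wc = 2.3 * bmi + 35.0 + rng.normal(0, 3.5, n)
    sad = 0.22 * wc + rng.normal(0, 1.2, n)
    fat = np.clip(np.where(male, 0.28, 0.38) * weight + rng.normal(0, 3.0, n),
                  3.0, None)
    tg = rng.lognormal(np.log(1.4), 0.5, n)
    hdl = np.clip(np.where(male, rng.lognormal(np.log(1.2), 0.25, n),
                           rng.lognormal(np.log(1.45), 0.25, n)), 0.4, None)
    if config.fat_mass_missing > 0:
        fat = np.where(rng.random(n) < config.fat_mass_missing, np.nan, fat)
    return pd.DataFrame({
        "participant_id": covariates["participant_id"].to_numpy(),
        "sex": covariates["sex"].to_numpy(),
        "weight_kg": weight, "height_m": height, "wc_cm": wc, "sad_cm": sad,
        "tg_mmol_l": tg, "hdl_mmol_l": hdl, "fat_mass_kg": fat,
    })


@dataclass
class Cohort:
    """One synthetic study: actigraphy, covariates, anthropometry, truth."""

    config: GeneratorConfig
    sleep_values: np.ndarray         # (n, n_days*1440) over {0, 1, nan}
    weekdays: list[str]
    covariates: pd.DataFrame
    anthropometry: pd.DataFrame
    sri_quintile: np.ndarray
    sri: np.ndarray
    truth: SyntheticTruth

    def epochs(self, max_participants: int | None = None) -> pd.DataFrame:
        """Minute-epoch rows for the first ``max_participants`` (CSV dialect)."""
        m = len(self.sleep_values) if max_participants is None else max_participants
        frames = [epochs_frame(self.sleep_values[i], self.weekdays, f"P{i:06d}")
                  for i in range(m)]
        return pd.concat(frames, ignore_index=True)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """End-to-end synthetic study with exposure-dependent outcomes.

    Generates the sleep matrix, computes each participant's SRI (lag one
    day) on it, assigns unweighted quintiles, and generates outcomes from
    the truth grid at the assigned quintile — so downstream recovery of the
    MF grid has an exact reference.
    """
    from .sri import compute_sri_matrix, assign_quintiles

    values, weekdays, jitter = generate_sleep_matrix(config)
    truth = SyntheticTruth(
        jitter_sd=jitter, true_mf=dict(config.true_mf),
        baseline_log_bmi=float(np.log(config.baseline_bmi)),
        beta_age=config.beta_age,
        residual_sd_logbmi=config.residual_sd_logbmi)
    sri = compute_sri_matrix(values)
    try:
        quintile, _ = assign_quintiles(sri)
    except ValueError as exc:
        raise ValueError(
            f"cohort of {config.n_participants} participants has too few "
            "distinct SRI values to form quintiles; use n_participants >= 5 "
            "with nonzero jitter") from exc
    covariates = generate_covariates(config)
    anthropometry = generate_outcomes(covariates, quintile, truth, config)
    return Cohort(config=config, sleep_values=values, weekdays=weekdays,
                  covariates=covariates, anthropometry=anthropometry,
                  sri_quintile=quintile, sri=sri, truth=truth)


def write_cohort(cohort: Cohort, out_dir, max_epoch_participants: int = 50
                 ) -> dict[str, str]:
    """Write the three CSV dialects plus a truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    epochs = cohort.epochs(min(max_epoch_participants, len(cohort.sleep_values)))
    for name, frame in (("epochs", epochs),
                        ("covariates", cohort.covariates),
                        ("anthropometry", cohort.anthropometry)):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = str(p)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(cohort.truth.to_jsonable(), indent=1))
    paths["truth"] = str(truth_path)
    return paths
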