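import numpy as np
import pandas as pd
import pytest

from sleepreg.actigraphy_qc import MINUTES_PER_DAY


def make_day(pid, day_index, weekday, *, n_minutes=MINUTES_PER_DAY,
             nonwear_minutes=0, unknown_frac=0.0, flagged_frac=0.0,
             sleep_start=1380, sleep_len=480, seed=0):
    """One participant-day of epoch rows with engineered violations.

    The day has a sleep block wrapping from ``sleep_start`` for
    ``sleep_len`` minutes; the first ``nonwear_minutes`` minutes are
    non-wear; ``unknown_frac`` / ``flagged_frac`` of minutes are set to
    unknown state / quality-flagged, spread deterministically.
    """
    minutes = np.arange(n_minutes)
    in_sleep = ((minutes >= sleep_start) & (minutes < sleep_start + sleep_len)) | (
        minutes < max(0, sleep_start + sleep_len - MINUTES_PER_DAY))
    state = np.where(in_sleep, "sleep", "wake").astype(object)
    state[:nonwear_minutes] = "nonwear"
    rng = np.random.default_rng([seed, day_index])
    n_unknown = int(round(unknown_frac * n_minutes))
    if n_unknown:
        idx = rng.choice(np.flatnonzero(state != "nonwear"), n_unknown,
                         replace=False)
        state[idx] = "unknown"
    flagged = np.zeros(n_minutes, dtype=bool)
    n_flag = int(round(flagged_frac * n_minutes))
    if n_flag:
        idx = rng.choice(np.flatnonzero(state != "nonwear"), n_flag,
                         replace=False)
        flagged[idx] = True
    return pd.DataFrame({
        "participant_id": pid, "day_index": day_index, "weekday": weekday,
        "minute_of_day": minutes, "state": state,
        "quality_flagged": flagged, "seconds_measured": 60,
    })


def make_week(pid, day_specs):
    """Stack make_day frames; day_specs is a list of (weekday, kwargs)."""
    frames = [make_day(pid, i + 1, wd, **kw)
              for i, (wd, kw) in enumerate(day_specs)]
    return pd.concat(frames, ignore_index=True)


WEEK = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]


@pytest.fixture(scope="session")
def engineered_cohort():
    """Ten participants: three clean, seven violating exactly one QC rule.

    Returns (epochs, expected_ledger_dict).
    """
    clean = [(wd, {}) for wd in WEEK]
    parts = {
        "p00": clean,
        "p01": [(wd, {"n_minutes": 1439}) for wd in WEEK],          # incomplete
        "p02": [(wd, {"nonwear_minutes": 150}) for wd in WEEK],     # non-wear
        "p03": [(wd, {} if wd in ("Sat", "Sun") else {"n_minutes": 1439})
                for wd in WEEK],                                     # 2 valid days
        "p04": [(wd, {"n_minutes": 1439} if wd in ("Sat", "Sun") else {})
                for wd in WEEK],                                     # no weekend
        "p05": [(wd, {"unknown_frac": 0.35}) for wd in WEEK],        # missing
        "p06": [(wd, {"flagged_frac": 0.35}) for wd in WEEK],        # flagged
        "p07": clean,
        "p08": clean,
        "p09": [(wd, {"nonwear_minutes": 120}) for wd in WEEK],     # boundary
    }
    epochs = pd.concat([make_week(pid, spec) for pid, spec in parts.items()],
                       ignore_index=True)
    expected = {
        "retained": 3, "incomplete_day": 1, "excess_nonwear": 2,
        "too_few_consecutive_days": 1, "no_weekend_day": 1,
        "excess_missingness": 1, "flagged_minutes": 1,
    }
    return epochs, expected


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter synthetic cohort, n = 2,000, reused across tests."""
    import sleepreg as sr

    cfg = sr.GeneratorConfig(n_participants=2000, seed=42, nonwear_rate=0.0)
    return sr.generate_cohort(cfg)


@pytest.fixture()
def analytic_records(small_cohort):
    """Merged analytic frame (covariates + quintile + BMI) from the cohort."""
    c = small_cohort
    rec = c.covariates.copy()
    rec["quintile"] = c.sri_quintile
    rec["sri_final"] = c.sri
    rec["bmi"] = (c.anthropometry["weight_kg"]
                  / c.anthropometry["height_m"] ** 2)
    return rec
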