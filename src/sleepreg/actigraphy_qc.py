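"""Minute-epoch actigraphy quality control.

Parses minute-level state predictions (wake/sleep/non-wear/unknown, one row
per participant-minute), recodes them to a binary-with-missing sleep
variable, and applies the inclusion filters used for wrist-worn
accelerometer studies:

* only unflagged minutes with exactly 60 measured seconds contribute data
  (flagged/short minutes are kept as timesteps but set to missing);
* a day is valid iff all 1,440 minutes are present and non-wear time is
  strictly below 2 hours;
* a participant needs a run of >= 3 consecutive valid days containing a
  Saturday or Sunday (the longest such run is kept, ties to the earliest);
* missingness of the binary sleep variable over the selected window must
  not exceed 30%.

Each excluded participant is counted once in an :class:`ExclusionLedger`
under the first rule that removed them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
STATES = ("wake", "sleep", "nonwear", "unknown")
EPOCH_COLUMNS = ("participant_id", "day_index", "weekday", "minute_of_day",
                 "state", "quality_flagged", "seconds_measured")

MINUTES_PER_DAY = 1440
MAX_NONWEAR_MINUTES = 120        # strict: a day with 120 non-wear minutes fails
MAX_MISSING_FRACTION = 0.30      # inclusive: exactly 30% is retained
MIN_CONSECUTIVE_DAYS = 3

EXCLUSION_REASONS = ("flagged_minutes", "incomplete_day", "excess_nonwear",
                     "too_few_consecutive_days", "no_weekend_day",
                     "excess_missingness")


class EpochParseError(ValueError):
    pass


@dataclass
class SleepSeries:
    """Binary-with-missing sleep vector for one retained participant."""

    participant_id: object
    values: np.ndarray               # float array over {0, 1, nan}
    start_weekday: str
    start_day: int
    lag: int = MINUTES_PER_DAY

    def __post_init__(self):
        if len(self.values) % MINUTES_PER_DAY:
            raise ValueError("series length must be a multiple of 1440")

    @property
    def n_days(self) -> int:
        return len(self.values) // MINUTES_PER_DAY


@dataclass
class ExclusionLedger:
    """Per-reason exclusion counts; each participant appears exactly once."""

    counts: dict = field(default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS})
    retained: int = 0

    @property
    def excluded(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.retained + self.excluded

    def to_dict(self) -> dict:
        return {"retained": self.retained, **self.counts}


def read_epochs(path) -> pd.DataFrame:
    """Read a minute-epoch CSV, validating states and ordering rows.

    Returns an empty, correctly-typed frame for a header-only file.  A row
    with an unrecognized state string raises :class:`EpochParseError`
    naming the offending line.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(EPOCH_COLUMNS) - set(df.columns)
    if missing:
        raise EpochParseError(f"missing columns: {sorted(missing)}")
    if len(df):
        bad_state = ~df["state"].isin(STATES)
        if bad_state.any():
            i = int(np.flatnonzero(bad_state)[0])
            raise EpochParseError(
                f"line {i + 2}: unknown state {df['state'].iloc[i]!r}")
        bad_wd = ~df["weekday"].isin(WEEKDAYS)
        if bad_wd.any():
            i = int(np.flatnonzero(bad_wd)[0])
            raise EpochParseError(
                f"line {i + 2}: unknown weekday {df['weekday'].iloc[i]!r}")
        if (df["seconds_measured"] > 60).any() or (df["seconds_measured"] < 0).any():
            i = int(np.flatnonzero(~df["seconds_measured"].between(0, 60))[0])
            raise EpochParseError(f"line {i + 2}: seconds_measured outside 0..60")
        if not df["minute_of_day"].between(0, 1439).all():
            i = int(np.flatnonzero(~df["minute_of_day"].between(0, 1439))[0])
            raise EpochParseError(f"line {i + 2}: minute_of_day outside 0..1439")
    df["quality_flagged"] = df["quality_flagged"].astype(bool)
    return df.sort_values(
        ["participant_id", "day_index", "minute_of_day"], kind="stable"
    ).reset_index(drop=True)


def recode_state(state: str, quality_flagged: bool = False,
                 seconds_measured: int = 60) -> float:
    """Recode one epoch to {0, 1, nan}.

    sleep -> 1, wake -> 0; non-wear/unknown -> missing; additionally any
    quality-flagged minute or one with other than 60 measured seconds is
    set to missing regardless of state.
    """
    if quality_flagged or seconds_measured != 60:
        return np.nan
    if state == "sleep":
        return 1.0
    if state == "wake":
        return 0.0
    if state in ("nonwear", "unknown"):
        return np.nan
    raise ValueError(f"unknown state {state!r}")


def recode_states(df: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`recode_state` over an epoch frame."""
    out = np.where(df["state"].eq("sleep"), 1.0,
                   np.where(df["state"].eq("wake"), 0.0, np.nan))
    qc_missing = df["quality_flagged"].to_numpy() | (
        df["seconds_measured"].to_numpy() != 60)
    out = np.where(qc_missing, np.nan, out)
    return out


def day_valid(day_records: pd.DataFrame) -> tuple[bool, str | None]:
    """Validity of one participant-day.

    A day passes iff exactly 1,440 distinct minutes are present and the
    number of non-wear minutes is strictly below 120 (the "<2 hours"
    requirement read strictly: a day with exactly 120 fails).
    """
    minutes = day_records["minute_of_day"]
    if len(minutes) != MINUTES_PER_DAY or minutes.nunique() != MINUTES_PER_DAY:
        return False, "incomplete_day"
    if int(day_records["state"].eq("nonwear").sum()) >= MAX_NONWEAR_MINUTES:
        return False, "excess_nonwear"
    return True, None


def select_window(day_validity: pd.DataFrame) -> tuple[tuple[int, int] | None, str | None]:
    """Choose the analysis window from per-day validity.

    ``day_validity`` has columns day_index, weekday, valid.  Returns the
    (first_day, last_day) of the longest run of >= 3 consecutive valid days
    that contains a Saturday or Sunday (ties broken by earliest start), or
    ``(None, reason)`` with reason ``too_few_consecutive_days`` when no run
    of >= 3 valid days exists and ``no_weekend_day`` when such runs exist
    but none touches a weekend.
    """
    dv = day_validity.sort_values("day_index")
    days = dv["day_index"].to_numpy()
    valid = dv["valid"].to_numpy(dtype=bool)
    weekend = dv["weekday"].isin(["Sat", "Sun"]).to_numpy()

    runs = []          # (start_idx, end_idx) inclusive, over valid & consecutive days
    i = 0
    n = len(days)
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1] and days[j + 1] == days[j] + 1:
            j += 1
        runs.append((i, j))
        i = j + 1

    long_runs = [(a, b) for a, b in runs if b - a + 1 >= MIN_CONSECUTIVE_DAYS]
    if not long_runs:
        return None, "too_few_consecutive_days"
    weekend_runs = [(a, b) for a, b in long_runs if weekend[a:b + 1].any()]
    if not weekend_runs:
        return None, "no_weekend_day"
    best = max(weekend_runs, key=lambda r: (r[1] - r[0], -r[0]))
    return (int(days[best[0]]), int(days[best[1]])), None


def missingness_ok(values: np.ndarray,
                   max_fraction: float = MAX_MISSING_FRACTION) -> bool:
    """True iff the missing fraction over the window does not exceed 30%."""
    v = np.asarray(values, dtype=float)
    return bool(np.isnan(v).mean() <= max_fraction)


def qc_pipeline(epochs: pd.DataFrame
                ) -> tuple[list[SleepSeries], ExclusionLedger]:
    """Run recode -> day validity -> window selection -> missingness check.

    Returns the retained :class:`SleepSeries` (one per participant, ordered
    by id) and the exclusion ledger.  When the missingness rule fails, the
    participant is attributed to ``flagged_minutes`` if the majority of
    missing minutes in the window stem from quality flags / short minutes
    rather than from non-wear/unknown states, and ``excess_missingness``
    otherwise; when no valid day run exists at all, the modal invalid-day
    reason (incomplete_day / excess_nonwear) is charged.
    """
    ledger = ExclusionLedger()
    series_out: list[SleepSeries] = []
    if len(epochs) == 0:
        return series_out, ledger

    for pid, pdf in epochs.groupby("participant_id", sort=True):
        rows = []
        for day, ddf in pdf.groupby("day_index", sort=True):
            ok, reason = day_valid(ddf)
            rows.append((day, ddf["weekday"].iloc[0], ok, reason))
        dv = pd.DataFrame(rows, columns=["day_index", "weekday", "valid", "reason"])

        window, reason = select_window(dv[["day_index", "weekday", "valid"]])
        if window is None:
            if reason == "too_few_consecutive_days" and not dv["valid"].any():
                day_reasons = dv["reason"].dropna()
                if (day_reasons == "excess_nonwear").sum() > (
                        day_reasons == "incomplete_day").sum():
                    reason = "excess_nonwear"
                else:
                    reason = "incomplete_day"
            ledger.counts[reason] += 1
            continue

        lo, hi = window
        win = pdf[pdf["day_index"].between(lo, hi)].sort_values(
            ["day_index", "minute_of_day"])
        values = recode_states(win)
        if not missingness_ok(values):
            miss = np.isnan(values)
            qc_driven = (win["quality_flagged"].to_numpy() |
                         (win["seconds_measured"].to_numpy() != 60))
            if (miss & qc_driven).sum() > (miss & ~qc_driven).sum():
                ledger.counts["flagged_minutes"] += 1
            else:
                ledger.counts["excess_missingness"] += 1
            continue

        series_out.append(SleepSeries(
            participant_id=pid, values=values,
            start_weekday=win["weekday"].iloc[0], start_day=int(lo)))
        ledger.retained += 1

    return series_out, ledger
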