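"""Sleep Regularity Index: computation, Monte-Carlo null, winsorization, quintiles.

The SRI measures the probability that a person is in the same sleep/wake
state at two time points 24 hours apart:

    SRI = -100 + 200 * (1 - (1/N_v) * sum_i |s_i - s_{i+c}|)

with s_i in {0 (wake), 1 (sleep), NA}, lag c = 1440 minutes, and N_v the
number of comparisons where both epochs are non-missing.  SRI = 100 for a
perfectly 24-h-periodic pattern, 0 in expectation for random sleep, and
-100 for a pattern that flips state every 24 h.

Negative outliers are handled by a Monte-Carlo winsorization: the SRI null
distribution under random sleep (i.i.d. Bernoulli(0.5) minutes, two days)
is simulated, and observed values below the lower 99%-range cutoff
(approximately -6.8) are replaced with draws from a normal distribution
matching the null's mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_LAG = 1440


class UndefinedSRIError(ValueError):
    """Raised when a series has no valid epoch-by-epoch comparison (N_v = 0)."""


@dataclass
class SriResult:
    """SRI for one participant, before and after winsorization."""

    participant_id: object
    sri_raw: float
    n_valid_comparisons: int
    sri_final: float | None = None
    winsorized: bool = False
    quintile: int | None = None


@dataclass(frozen=True)
class NullSriDistribution:
    """Summary of the simulated SRI distribution under random sleep."""

    n_sims: int
    mean: float
    sd: float
    q005: float
    q995: float
    cutoff: float
    seed: int

    def __post_init__(self):
        if not (self.q005 < self.mean < self.q995):
            raise ValueError("null quantiles must bracket the mean")
        if self.sd <= 0:
            raise ValueError("null sd must be positive")


def _pairwise_mismatch(values: np.ndarray, lag: int) -> tuple[float, int]:
    """Mean |s_i - s_{i+lag}| over valid pairs and the count N_v."""
    a = values[:-lag]
    b = values[lag:]
    valid = ~(np.isnan(a) | np.isnan(b))
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.nan, 0
    mism = float(np.abs(a[valid] - b[valid]).sum()) / n_valid
    return mism, n_valid


def compute_sri(values: Sequence[float] | np.ndarray, lag: int = DEFAULT_LAG,
                participant_id: object = None) -> SriResult:
    """Compute the SRI of one sleep/wake series.

    Parameters
    ----------
    values
        Sequence over {0, 1, NaN}; NaN marks non-wear/unknown/flagged minutes.
    lag
        Comparison lag in epochs (minutes); 1440 compares states 24 h apart.

    Raises
    ------
    UndefinedSRIError
        If no pair of epochs `lag` apart has both values observed.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(v) <= lag:
        raise ValueError(f"series length {len(v)} must exceed lag {lag}")
    mism, n_valid = _pairwise_mismatch(v, lag)
    if n_valid == 0:
        raise UndefinedSRIError(
            f"SRI undefined for participant {participant_id!r}: N_v = 0")
    sri = -100.0 + 200.0 * (1.0 - mism)
    return SriResult(participant_id=participant_id, sri_raw=sri,
                     n_valid_comparisons=n_valid)


def compute_sri_matrix(values: np.ndarray, lag: int = DEFAULT_LAG) -> np.ndarray:
    """Vectorized SRI over a (participants x minutes) matrix.

    Rows with N_v = 0 yield NaN rather than raising, so callers can apply
    the exclusion rule in bulk.
    """
    v = np.asarray(values, dtype=float)
    a = v[:, :-lag]
    b = v[:, lag:]
    valid = ~(np.isnan(a) | np.isnan(b))
    n_valid = valid.sum(axis=1)
    diff = np.abs(np.where(valid, a - b, 0.0)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mism = np.where(n_valid > 0, diff / np.maximum(n_valid, 1), np.nan)
    return -100.0 + 200.0 * (1.0 - mism)


def simulate_null(n_sims: int = 100_000, n_days: int = 2, p_sleep: float = 0.5,
                  seed: int = 0, minutes_per_day: int = 1440,
                  quantile_range: float = 0.99) -> NullSriDistribution:
    """Simulate the SRI null distribution under random sleep.

    Each replicate draws ``n_days`` days of i.i.d. Bernoulli(``p_sleep``)
    minute states and computes the SRI at lag one day.  Returns the moments,
    the 0.5%/99.5% quantiles, and the symmetric winsorization cutoff
    ``-(q995 - q005)/2``.  Under the defaults the closed form for the SD of
    the mismatch mean, 200*sqrt(p(1-p)/1440), gives a 99% range of
    approximately +/-6.8.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = np.random.default_rng(seed)
    lag = minutes_per_day
    sris = np.empty(n_sims)
    chunk = max(1, min(n_sims, 20_000_000 // (n_days * minutes_per_day)))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        s = rng.random((m, n_days * minutes_per_day)) < p_sleep
        mism = (s[:, :-lag] ^ s[:, lag:]).mean(axis=1)
        sris[done:done + m] = -100.0 + 200.0 * (1.0 - mism)
        done += m
    alpha = (1.0 - quantile_range) / 2.0
    q_lo, q_hi = np.quantile(sris, [alpha, 1.0 - alpha])
    if q_lo == q_hi:  # degenerate null (e.g. p_sleep = 1)
        q_lo, q_hi = q_lo - 1e-9, q_hi + 1e-9
    cutoff = -(q_hi - q_lo) / 2.0
    return NullSriDistribution(
        n_sims=n_sims, mean=float(sris.mean()), sd=float(max(sris.std(ddof=1), 1e-12)),
        q005=float(q_lo), q995=float(q_hi), cutoff=float(cutoff), seed=seed)


def winsorize_sri(results: Sequence[SriResult] | np.ndarray,
                  null: NullSriDistribution, seed: int = 0):
    """Replace SRI values below the null cutoff with draws from the null normal.

    Values >= cutoff pass through bit-identically.  Replacement draws are
    N(null.mean, null.sd), untruncated.  Accepts either a list of
    :class:`SriResult` (filled in place and returned) or a plain array
    (returns ``(winsorized_array, replaced_mask)``).
    """
    rng = np.random.default_rng(seed)
    if isinstance(results, np.ndarray) or (
            len(results) and not isinstance(results[0], SriResult)):
        arr = np.asarray(results, dtype=float).copy()
        mask = arr < null.cutoff
        arr[mask] = rng.normal(null.mean, null.sd, size=int(mask.sum()))
        return arr, mask
    for r in results:
        if r.sri_raw < null.cutoff:
            r.sri_final = float(rng.normal(null.mean, null.sd))
            r.winsorized = True
        else:
            r.sri_final = r.sri_raw
            r.winsorized = False
    return results


def assign_quintiles(sri_values: Sequence[float] | np.ndarray
                     ) -> tuple[np.ndarray, dict[int, float]]:
    """Assign unweighted sample quintiles (1..5) and per-quintile medians.

    Boundaries are the order statistics at ceil(n*j/5); tied values spanning
    a boundary all fall in the lower quintile.  Requires >= 5 distinct values.

    Returns
    -------
    (labels, medians)
        ``labels`` is an int array in 1..5; ``medians`` maps quintile ->
        median SRI within it (used as the trend score).
    """
    v = np.asarray(sri_values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("sri values must be non-missing")
    if len(np.unique(v)) < 5:
        raise ValueError("need at least 5 distinct values to form quintiles")
    n = len(v)
    srt = np.sort(v)
    cuts = [srt[int(np.ceil(n * j / 5)) - 1] for j in range(1, 5)]
    labels = np.searchsorted(np.asarray(cuts), v, side="left") + 1
    medians = {q: float(np.median(v[labels == q])) for q in range(1, 6)}
    return labels.astype(int), medians


def sri_table(results: Sequence[SriResult]) -> pd.DataFrame:
    """Tabulate SriResults as the canonical output frame."""
    return pd.DataFrame({
        "participant_id": [r.participant_id for r in results],
        "sri_raw": [r.sri_raw for r in results],
        "sri_final": [r.sri_final for r in results],
        "n_valid": [r.n_valid_comparisons for r in results],
        "winsorized": [r.winsorized for r in results],
        "quintile": [r.quintile for r in results],
    })
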