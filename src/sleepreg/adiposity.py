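"""Adiposity index panel: BMI plus nine further obesity measures.

Computes, per participant, the ten measures used alongside BMI in
population adiposity studies:

* BMI = weight_kg / height_m**2, rounded half-up to one decimal
* WC (waist circumference, cm) and WHtR = WC_cm / height_cm
* ABSI = WC_m / (BMI**(2/3) * height_m**(1/2))  [SI metres]
* BRI = 364.2 - 365.5 * sqrt(1 - ((WC_cm/(2*pi))**2 / (0.5*height_cm)**2))
* VAI (sex-specific):
    men:   (WC / (39.68 + 1.88*BMI)) * (TG/1.03) * (1.31/HDL)
    women: (WC / (36.58 + 1.89*BMI)) * (TG/0.81) * (HDL: 1.52/HDL)
* LAP:  men (WC - 65)*TG, women (WC - 58)*TG   [TG in mmol/L]
* FMI = fat_mass_kg / height_m**2; percent body fat = 100*fat_mass/weight
* SAD (sagittal abdominal diameter, cm) and SADHtR = SAD_cm / height_cm

Fat-mass-derived measures propagate missingness (DXA fat mass is absent for
roughly half of participants in the emulated survey).  Extreme values are
winsorized by capping at the 1st and 99th percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: panel columns winsorized at the 1st/99th percentile, as BMI is
WINSORIZED_MEASURES = ("bmi", "wc", "fat_mass", "pct_fat", "sad")

PANEL_COLUMNS = ("bmi", "wc", "absi", "whtr", "sad", "sadhtr", "vai",
                 "fat_mass", "fmi", "pct_fat", "bri", "lap")


@dataclass(frozen=True)
class AnthropometryRecord:
    """Raw anthropometry and lipids for one participant."""

    sex: str                         # "Male" | "Female"
    weight: float                    # kg
    height: float                    # m
    waist_circumference: float       # cm
    sagittal_abdominal_diameter: float  # cm
    triglycerides: float             # mmol/L
    hdl: float                       # mmol/L
    total_fat_mass: float | None = None  # kg, often missing

    def __post_init__(self):
        for name in ("weight", "height", "waist_circumference",
                     "sagittal_abdominal_diameter", "triglycerides", "hdl"):
            v = getattr(self, name)
            if v is None or not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")
        if not (1.2 < self.height < 2.2):
            raise ValueError(f"height {self.height} m outside plausible range")
        if self.sex not in ("Male", "Female"):
            raise ValueError(f"sex must be 'Male' or 'Female', got {self.sex!r}")


def compute_bmi(weight: float, height: float) -> float:
    """BMI in kg/m^2, rounded half-up to one decimal place."""
    if not (weight > 0 and height > 0):
        raise ValueError("weight and height must be positive")
    bmi = weight / height ** 2
    return math.floor(bmi * 10 + 0.5) / 10


def compute_indices(record: AnthropometryRecord) -> dict[str, float]:
    """Compute the full ten-measure adiposity panel for one participant.

    Fat-mass-derived entries (fat_mass, fmi, pct_fat) are NaN when
    ``total_fat_mass`` is missing.
    """
    bmi = compute_bmi(record.weight, record.height)
    h_m = record.height
    h_cm = h_m * 100.0
    wc_cm = record.waist_circumference
    wc_m = wc_cm / 100.0
    tg = record.triglycerides
    hdl = record.hdl
    sad = record.sagittal_abdominal_diameter

    absi = wc_m / (bmi ** (2.0 / 3.0) * h_m ** 0.5)
    ecc = (wc_cm / (2.0 * math.pi)) ** 2 / (0.5 * h_cm) ** 2
    if ecc >= 1:
        raise ValueError("waist circumference implausibly large for height")
    bri = 364.2 - 365.5 * math.sqrt(1.0 - ecc)
    if record.sex == "Male":
        vai = (wc_cm / (39.68 + 1.88 * bmi)) * (tg / 1.03) * (1.31 / hdl)
        lap = (wc_cm - 65.0) * tg
    else:
        vai = (wc_cm / (36.58 + 1.89 * bmi)) * (tg / 0.81) * (1.52 / hdl)
        lap = (wc_cm - 58.0) * tg

    if record.total_fat_mass is None or (
            isinstance(record.total_fat_mass, float)
            and math.isnan(record.total_fat_mass)):
        fat_mass = fmi = pct_fat = float("nan")
    else:
        fat_mass = record.total_fat_mass
        fmi = fat_mass / h_m ** 2
        pct_fat = 100.0 * fat_mass / record.weight

    return {
        "bmi": bmi, "wc": wc_cm, "whtr": wc_cm / h_cm, "absi": absi,
        "bri": bri, "vai": vai, "lap": lap, "sad": sad,
        "sadhtr": sad / h_cm, "fat_mass": fat_mass, "fmi": fmi,
        "pct_fat": pct_fat,
    }


def compute_panel(anthro: pd.DataFrame) -> pd.DataFrame:
    """Vectorized panel over an anthropometry frame.

    Expects columns participant_id, sex, weight_kg, height_m, wc_cm, sad_cm,
    tg_mmol_l, hdl_mmol_l, fat_mass_kg (fat mass may be NaN).
    """
    bmi = np.floor(anthro["weight_kg"] / anthro["height_m"] ** 2 * 10 + 0.5) / 10
    h_cm = anthro["height_m"] * 100.0
    wc = anthro["wc_cm"].astype(float)
    tg = anthro["tg_mmol_l"].astype(float)
    hdl = anthro["hdl_mmol_l"].astype(float)
    male = anthro["sex"].eq("Male").to_numpy()
    if (hdl <= 0).any() or (anthro["height_m"] <= 0).any():
        raise ValueError("non-positive HDL or height")
    absi = (wc / 100.0) / (bmi ** (2.0 / 3.0) * anthro["height_m"] ** 0.5)
    ecc = (wc / (2 * np.pi)) ** 2 / (0.5 * h_cm) ** 2
    bri = 364.2 - 365.5 * np.sqrt(1.0 - ecc)
    vai = np.where(male,
                   (wc / (39.68 + 1.88 * bmi)) * (tg / 1.03) * (1.31 / hdl),
                   (wc / (36.58 + 1.89 * bmi)) * (tg / 0.81) * (1.52 / hdl))
    lap = np.where(male, (wc - 65.0) * tg, (wc - 58.0) * tg)
    fat = anthro["fat_mass_kg"].astype(float)
    panel = pd.DataFrame({
        "participant_id": anthro["participant_id"].to_numpy(),
        "bmi": bmi, "wc": wc, "whtr": wc / h_cm, "absi": absi, "bri": bri,
        "vai": vai, "lap": lap, "sad": anthro["sad_cm"].astype(float),
        "sadhtr": anthro["sad_cm"] / h_cm, "fat_mass": fat,
        "fmi": fat / anthro["height_m"] ** 2,
        "pct_fat": 100.0 * fat / anthro["weight_kg"],
    })
    return panel


def winsorize_percentile(values, lower: float = 1.0, upper: float = 99.0,
                         bounds: tuple[float, float] | None = None):
    """Cap values outside the [lower, upper] percentile band at the bounds.

    Percentiles use linear interpolation between order statistics; NaNs are
    ignored when computing the bounds and pass through unchanged.  Passing
    explicit ``bounds`` skips estimation (capping with fixed bounds is
    idempotent; re-estimating bounds from already-capped data is not, since
    the 1st/99th percentiles of the capped sample move slightly inward).
    """
    v = np.asarray(values, dtype=float)
    if bounds is None:
        obs = v[~np.isnan(v)]
        if obs.size == 0:
            raise ValueError("cannot winsorize an all-missing vector")
        bounds = tuple(np.percentile(obs, [lower, upper]))
    return np.clip(v, bounds[0], bounds[1])


def winsorize_panel(panel: pd.DataFrame,
                    measures=WINSORIZED_MEASURES) -> pd.DataFrame:
    """Percentile-cap the measures that are winsorized in the same manner as BMI."""
    out = panel.copy()
    for col in measures:
        out[col] = winsorize_percentile(out[col].to_numpy())
    return out


def correlation_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the panel measures."""
    cols = [c for c in PANEL_COLUMNS if c in panel.columns]
    return panel[cols].corr(method="pearson", min_periods=3)
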