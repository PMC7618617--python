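"""End-to-end orchestration: synth -> QC -> SRI -> panel -> models.

Runs the whole analysis on a synthetic cohort from a single config and
emits the study's artifact set: an exclusion ledger, quintile-stratified
descriptives (with and without survey weights), the adiposity-panel
summary and correlation matrix, multiplication-factor tables with
bootstrap CIs, interaction/trend tests, prediction curves, and a manifest
recording seeds and per-stage row counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import actigraphy_qc as qc
from . import adiposity, sri as sri_mod, survey_models as models
from .synthetic_cohort import (GeneratorConfig, generate_cohort,
                               CONTINUOUS_COVARIATES, CATEGORICAL_LEVELS)


@dataclass
class RunConfig:
    """Single-file configuration for an end-to-end run."""

    out_dir: str = "sleepreg_run"
    n_participants: int = 1500
    n_days: int = 7
    onset_jitter_sd: float = 160.0
    nonwear_rate: float = 0.02
    covariate_missingness: dict = field(default_factory=lambda: {"alcohol": 0.05})
    residual_sd_logbmi: float = 0.12
    generator_seed: int = 11
    null_sim_seed: int = 23
    winsorize_seed: int = 29
    bootstrap_seed: int = 37
    n_null_sims: int = 100_000
    models: tuple = (1, 2, 3, 4)
    outcomes: tuple = ("bmi",)
    bootstrap_B: int = 200
    weighted: bool = True
    unweighted_sensitivity: bool = False
    meal_timing_sensitivity: bool = False
    curve_bootstrap_B: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _descriptives(records: pd.DataFrame, weighted: bool) -> pd.DataFrame:
    """Quintile-stratified medians/IQRs and category counts."""
    rows = []
    w = records["survey_weight"].to_numpy(float) if weighted else np.ones(len(records))
    for q, grp in records.groupby("quintile"):
        gw = w[records["quintile"].to_numpy() == q]
        row = {"quintile": q, "n": len(grp)}
        for col in ("sri_final", "age") + CONTINUOUS_COVARIATES:
            if col in grp.columns:
                v = grp[col].to_numpy(float)
                keep = ~np.isnan(v)
                row[f"{col}_median"] = models._weighted_quantile(
                    v[keep], gw[keep], 0.5) if keep.any() else np.nan
        for col in CATEGORICAL_LEVELS:
            if col in grp.columns:
                top = grp[col].mode()
                row[f"{col}_mode"] = top.iloc[0] if len(top) else ""
        rows.append(row)
    return pd.DataFrame(rows).sort_values("quintile")


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seeds": {
        "generator": config.generator_seed, "null_sim": config.null_sim_seed,
        "winsorize": config.winsorize_seed, "bootstrap": config.bootstrap_seed},
        "stages": {}}
    stage = "synth"
    try:
        gen_cfg = GeneratorConfig(
            n_participants=config.n_participants, n_days=config.n_days,
            onset_jitter_sd=config.onset_jitter_sd,
            nonwear_rate=config.nonwear_rate,
            covariate_missingness=dict(config.covariate_missingness),
            residual_sd_logbmi=config.residual_sd_logbmi,
            seed=config.generator_seed)
        cohort = generate_cohort(gen_cfg)
        epochs = cohort.epochs()
        manifest["stages"]["synth"] = {"participants": config.n_participants,
                                       "epoch_rows": len(epochs)}

        stage = "qc"
        series, ledger = qc.qc_pipeline(epochs)
        (out / "ledger.json").write_text(json.dumps(ledger.to_dict(), indent=1))
        manifest["stages"]["qc"] = ledger.to_dict()

        stage = "sri"
        null = sri_mod.simulate_null(n_sims=config.n_null_sims,
                                     seed=config.null_sim_seed)
        results = []
        for s in series:
            r = sri_mod.compute_sri(s.values, participant_id=s.participant_id)
            results.append(r)
        sri_mod.winsorize_sri(results, null, seed=config.winsorize_seed)
        finals = np.array([r.sri_final for r in results])
        labels, qmed = sri_mod.assign_quintiles(finals)
        for r, lab in zip(results, labels):
            r.quintile = int(lab)
        sri_df = sri_mod.sri_table(results)
        sri_df.to_csv(out / "sri.csv", index=False)
        manifest["stages"]["sri"] = {
            "n": len(sri_df), "winsorized": int(sri_df["winsorized"].sum()),
            "null_cutoff": null.cutoff, "quintile_medians": qmed}

        stage = "panel"
        panel = adiposity.compute_panel(cohort.anthropometry)
        panel = adiposity.winsorize_panel(panel)
        corr = adiposity.correlation_summary(panel)
        panel.to_csv(out / "panel.csv", index=False)
        corr.to_csv(out / "panel_correlations.csv")
        manifest["stages"]["panel"] = {"n": len(panel)}

        stage = "assemble"
        records = (sri_df.merge(cohort.covariates, on="participant_id")
                   .merge(panel, on="participant_id"))
        records["survey_weight"] = models.combine_cycle_weights(
            records["survey_weight"].to_numpy(), n_cycles=1)
        if records[list(CONTINUOUS_COVARIATES)].isna().any().any() or \
                records[list(CATEGORICAL_LEVELS)].isna().any().any():
            records = models.knn_impute(records)
        manifest["stages"]["assemble"] = {"n": len(records)}

        stage = "models"
        desc_w = _descriptives(records, weighted=True)
        desc_u = _descriptives(records, weighted=False)
        desc_w.to_csv(out / "descriptives_weighted.csv", index=False)
        desc_u.to_csv(out / "descriptives_unweighted.csv", index=False)
        tests = {}
        for outcome in config.outcomes:
            usable = records[records[outcome].notna() &
                             (records[outcome] > 0)].reset_index(drop=True)
            mf_frames = []
            for mid in config.models:
                mf = models.mf_table_with_ci(
                    usable, mid, outcome=outcome, B=config.bootstrap_B,
                    seed=config.bootstrap_seed, weighted=config.weighted)
                mf_frames.append(mf)
            pd.concat(mf_frames, ignore_index=True).to_csv(
                out / f"mf_table_{outcome}.csv", index=False)
            needed = {m for m in (2, 3, 4) if m <= max(config.models)}
            fits = {mid: models.fit_model(usable, mid, outcome=outcome,
                                          weighted=config.weighted)
                    for mid in needed}
            tests[outcome] = {"trend": models.trend_test(
                usable, qmed, outcome=outcome, weighted=config.weighted)}
            if 3 in fits:
                tests[outcome]["sex_interaction"] = models.interaction_test(
                    fits[3], fits[2])
            if 4 in fits:
                tests[outcome]["ethnicity_interaction"] = \
                    models.interaction_test(fits[4], fits[3])
                tests[outcome]["overall_interaction"] = \
                    models.interaction_test(fits[4], fits[2])
            if config.unweighted_sensitivity:
                mfu = models.mf_table_with_ci(
                    usable, max(config.models), outcome=outcome,
                    B=config.bootstrap_B, seed=config.bootstrap_seed,
                    weighted=False)
                mfu.to_csv(out / f"mf_table_{outcome}_unweighted.csv",
                           index=False)
            if 4 in config.models:
                curves = models.predict_curve(
                    usable, outcome=outcome, B=config.curve_bootstrap_B,
                    seed=config.bootstrap_seed, weighted=config.weighted)
                curves.to_csv(out / f"curves_{outcome}.csv", index=False)
        (out / "interaction_tests.json").write_text(
            json.dumps(tests, indent=1, default=float))
        manifest["stages"]["models"] = {"outcomes": list(config.outcomes),
                                        "models": list(config.models)}
    except Exception as exc:                              # noqa: BLE001
        (out / "manifest_partial.json").write_text(
            json.dumps(manifest, indent=1, default=str))
        raise StageError(stage, exc, manifest) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    partial = out / "manifest_partial.json"
    if partial.exists():
        partial.unlink()
    return manifest
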