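"""Weighted log-linear fits, MFs, bootstrap, Rao-Scott and trend tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sleepreg as sr
from sleepreg.survey_models import RankDeficiencyError, build_design
from sleepreg.synthetic_cohort import CATEGORICAL_LEVELS


def toy_records(n=50, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "quintile": rng.integers(1, 6, n),
        "age": rng.uniform(20, 80, n),
        "sex": rng.choice(["Male", "Female"], n),
        "survey_weight": np.ones(n),
        "bmi": rng.lognormal(np.log(27), 0.2, n),
    })


class TestFitModel:
    def test_unit_weights_match_normal_equations(self):
        rec = toy_records()
        fit = sr.fit_model(rec, 1, outcome="bmi")
        X, names = build_design(rec, 1)
        beta, *_ = np.linalg.lstsq(X, np.log(rec["bmi"]), rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_outcome_scaling_shifts_only_intercept(self):
        rec = toy_records()
        f1 = sr.fit_model(rec, 1, outcome="bmi")
        rec2 = rec.assign(bmi=rec["bmi"] * 3.0)
        f2 = sr.fit_model(rec2, 1, outcome="bmi")
        assert f2.params["Intercept"] - f1.params["Intercept"] == \
            pytest.approx(np.log(3.0), abs=1e-10)
        np.testing.assert_allclose(f1.params.drop("Intercept"),
                                   f2.params.drop("Intercept"), atol=1e-10)

    def test_uniform_truth_recovered(self, analytic_records):
        rec = analytic_records.copy()
        rng = np.random.default_rng(1)
        # regenerate outcome with a uniform MF grid: exp(beta_Q5) -> 0.95
        lmf = np.log(0.95) * (rec["quintile"].to_numpy() - 1) / 4
        rec["bmi"] = np.exp(np.log(28.0) + lmf + rng.normal(0, 0.15, len(rec)))
        fit = sr.fit_model(rec, 1, outcome="bmi")
        assert np.exp(fit.params["Q5"]) == pytest.approx(0.95, abs=0.02)

    def test_nonpositive_outcome_rejected(self):
        rec = toy_records()
        rec.loc[0, "bmi"] = 0.0
        with pytest.raises(ValueError):
            sr.fit_model(rec, 1, outcome="bmi")

    def test_rank_deficiency_names_terms(self):
        rec = toy_records()
        rec["sex"] = "Female"          # sex indicator == intercept complement
        with pytest.raises(RankDeficiencyError, match="sex"):
            sr.fit_model(rec, 1, outcome="bmi")

    def test_design_covariance_psd_and_symmetric(self, analytic_records):
        fit = sr.fit_model(analytic_records, 3, outcome="bmi")
        V = fit.cov_design.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-14)
        assert np.linalg.eigvalsh(V).min() > -1e-12


class TestWeights:
    def test_cdc_combined_cycle_rule(self):
        assert sr.combine_cycle_weights(30_000.0) == 15_000.0
        assert sr.combine_cycle_weights(7.0, n_cycles=1) == 7.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            sr.combine_cycle_weights(np.array([1.0, 0.0]))


class TestMultiplicationFactors:
    def test_direct_exponentiation(self, analytic_records):
        fit = sr.fit_model(analytic_records, 2, outcome="bmi")
        mf = sr.multiplication_factors(fit)
        row = mf[mf["contrast"] == "Q5 vs Q1"].iloc[0]
        assert row["mf"] == pytest.approx(np.exp(fit.params["Q5"]), rel=1e-12)

    def test_stratified_combination(self, analytic_records):
        fit = sr.fit_model(analytic_records, 4, outcome="bmi")
        mf = sr.multiplication_factors(fit)
        eth = "Non-Hispanic Black"
        row = mf[(mf["ethnicity"] == eth) & (mf["sex"] == "Female")
                 & (mf["contrast"] == "Q3 vs Q1")].iloc[0]
        want = np.exp(fit.params["Q3"] + fit.params["Q3:sex[Female]"]
                      + fit.params[f"Q3:ethnicity[{eth}]"])
        assert row["mf"] == pytest.approx(want, rel=1e-12)
        # reference ethnicity stratum carries no interaction term
        ref = CATEGORICAL_LEVELS["ethnicity"][0]
        row0 = mf[(mf["ethnicity"] == ref) & (mf["sex"] == "Male")
                  & (mf["contrast"] == "Q3 vs Q1")].iloc[0]
        assert row0["mf"] == pytest.approx(np.exp(fit.params["Q3"]), rel=1e-12)

    def test_all_strata_present_for_model4(self, analytic_records):
        fit = sr.fit_model(analytic_records, 4, outcome="bmi")
        mf = sr.multiplication_factors(fit)
        assert len(mf) == 6 * 2 * 4
        assert (mf["mf"] > 0).all()

    def test_missing_interactions_raise(self, analytic_records):
        fit = sr.fit_model(analytic_records, 2, outcome="bmi")
        with pytest.raises(KeyError):
            sr.multiplication_factors(fit, strata="sex")


class TestBootstrap:
    def test_degenerate_data_zero_width(self):
        rec = pd.DataFrame({"x": np.full(40, 5.0)})
        point, lo, hi = sr.bootstrap_ci(rec, lambda d: [d["x"].mean()],
                                        B=50, seed=1)
        assert lo[0] == hi[0] == point[0] == 5.0

    def test_ci_width_matches_closed_form(self):
        rng = np.random.default_rng(2)
        rec = pd.DataFrame({"x": rng.normal(0, 1, 400)})
        _, lo, hi = sr.bootstrap_ci(rec, lambda d: [d["x"].mean()],
                                    B=2000, seed=3)
        width = hi[0] - lo[0]
        assert width == pytest.approx(2 * 1.96 / np.sqrt(400), rel=0.15)

    def test_seed_reproducible(self, analytic_records):
        rec = analytic_records.head(400)
        est = lambda d: [np.log(d["bmi"]).mean()]
        a = sr.bootstrap_ci(rec, est, B=100, seed=7)
        b = sr.bootstrap_ci(rec, est, B=100, seed=7)
        assert a[1][0] == b[1][0] and a[2][0] == b[2][0]

    def test_mf_table_ci_brackets_point(self, analytic_records):
        table = sr.mf_table_with_ci(analytic_records, 1, B=60, seed=4)
        assert ((table["ci_low"] <= table["mf"] + 1e-9)
                & (table["mf"] <= table["ci_high"] + 1e-9)).all()

    def test_estimator_failures_abort(self):
        rec = toy_records(30)
        calls = {"n": 0}

        def bad(df):
            calls["n"] += 1
            if calls["n"] > 1:          # succeed on the point estimate only
                raise RuntimeError("boom")
            return [0.0]

        with pytest.raises(RuntimeError, match="failed"):
            sr.bootstrap_ci(rec, bad, B=20, seed=5)


class TestInteractionTest:
    def test_identical_models_give_p_one(self, analytic_records):
        fit = sr.fit_model(analytic_records, 2, outcome="bmi")
        out = sr.interaction_test(fit, fit)
        assert out["statistic"] == 0.0 and out["p_value"] == 1.0

    def test_non_nested_rejected(self, analytic_records):
        f1 = sr.fit_model(analytic_records, 1, outcome="bmi")
        f3 = sr.fit_model(analytic_records, 3, outcome="bmi")
        with pytest.raises(ValueError):
            sr.interaction_test(f1, f3)

    def test_matches_classical_lr_with_unit_weights(self, analytic_records):
        rec = analytic_records.assign(survey_weight=1.0)
        f2 = sr.fit_model(rec, 2, outcome="bmi")
        f3 = sr.fit_model(rec, 3, outcome="bmi")
        out = sr.interaction_test(f3, f2)
        lr = len(rec) * np.log(f2.weighted_sse / f3.weighted_sse)
        p_classical = stats.chi2.sf(lr, out["df"])
        assert out["p_value"] == pytest.approx(p_classical, rel=0.10, abs=1e-12)

    def test_detects_strong_sex_interaction(self, analytic_records):
        f2 = sr.fit_model(analytic_records, 2, outcome="bmi")
        f3 = sr.fit_model(analytic_records, 3, outcome="bmi")
        out = sr.interaction_test(f3, f2)
        assert out["p_value"] < 0.01      # truth: MF 0.92 women vs 0.98 men


class TestTrend:
    def test_negative_trend_detected(self, analytic_records):
        _, qmed = sr.assign_quintiles(analytic_records["sri_final"].to_numpy())
        out = sr.trend_test(analytic_records, qmed, outcome="bmi")
        assert out["coef"] < 0
        assert out["p_value"] < 0.001

    def test_null_pvalues_uniform(self):
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            n = 400
            cfg = sr.GeneratorConfig(n_participants=n, seed=2000 + rep)
            rec = sr.generate_covariates(cfg)
            rec["quintile"] = rng.integers(1, 6, n)
            rec["bmi"] = rng.lognormal(np.log(27), 0.15, n)
            out = sr.trend_test(rec, {q: float(q * 10) for q in range(1, 6)},
                                model_id=1)
            pvals.append(out["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestProfileAndCurves:
    def test_profile_rules(self):
        rng = np.random.default_rng(4)
        n = 4000
        rec = pd.DataFrame({
            "survey_weight": rng.uniform(0.5, 1.5, n),
            "age": rng.normal(50, 10, n),                  # symmetric -> mean
            "vitamin_d": rng.lognormal(4, 0.8, n),          # skewed -> median
            "sex": rng.choice(["Male", "Female"], n, p=[0.3, 0.7]),
        })
        prof = sr.covariate_profile(rec)
        wmean = np.average(rec["age"], weights=rec["survey_weight"])
        assert prof["age"] == pytest.approx(wmean, rel=1e-9)
        assert prof["vitamin_d"] < np.average(rec["vitamin_d"],
                                              weights=rec["survey_weight"])
        assert prof["sex"] == "Female"

    def test_zero_sri_coefficients_give_flat_curve(self, analytic_records):
        from sleepreg.survey_models import _predict
        fit = sr.fit_model(analytic_records, 4, outcome="bmi", exposure="sri")
        for term in fit.params.index:
            if term == "sri" or term.startswith("sri:"):
                fit.params[term] = 0.0
        prof = sr.covariate_profile(analytic_records)
        rows = pd.DataFrame([{**prof, "sex": "Female",
                              "ethnicity": "Non-Hispanic White",
                              "sri_final": s} for s in (0.0, 50.0, 100.0)])
        preds = _predict(fit, rows)
        np.testing.assert_allclose(preds, preds[0], rtol=1e-12)

    def test_curve_shapes_and_envelope(self, analytic_records):
        grid = np.arange(0.0, 101.0, 25.0)
        curves = sr.predict_curve(analytic_records, sri_grid=grid, B=20,
                                  seed=6, envelope_draws=2000)
        assert set(curves["sex"]) == {"Male", "Female"}
        # women's truth declines (MF 0.92): fitted curve decreasing overall
        w = curves[(curves["sex"] == "Female")
                   & (curves["ethnicity"] == "Non-Hispanic White")]
        assert w["fit"].iloc[-1] < w["fit"].iloc[0]
        env_width = (curves["env_hi"] - curves["env_lo"]).mean()
        band_width = (curves["hi"] - curves["lo"]).mean()
        assert env_width > band_width

    def test_grid_outside_range_rejected(self, analytic_records):
        with pytest.raises(ValueError):
            sr.predict_curve(analytic_records, sri_grid=np.array([-5.0, 50.0]))


class TestKnnImpute:
    def test_no_missing_identity(self):
        cfg = sr.GeneratorConfig(n_participants=200, seed=5)
        cov = sr.generate_covariates(cfg)
        out = sr.knn_impute(cov)
        pd.testing.assert_frame_equal(out, cov)

    def test_identical_donors_vote(self):
        base = {"age": 50.0, "vitamin_d": 60.0, "caloric_intake": 2000.0,
                "phq9": 2.0, "activity": 7.0, "sex": "Female",
                "ethnicity": "Other Hispanic", "education": "Some College or AA degree",
                "income": ">= $20,000", "occupation": "Working",
                "marital": "Married", "alcohol": "Moderate Drinker",
                "smoking": "Non smokers"}
        rows = [dict(base) for _ in range(6)]
        rows[0]["alcohol"] = np.nan
        df = pd.DataFrame(rows)
        out = sr.knn_impute(df, k=5)
        assert out.loc[0, "alcohol"] == "Moderate Drinker"

    def test_beats_marginal_imputation_rmse(self):
        cfg = sr.GeneratorConfig(n_participants=600, seed=6)
        cov = sr.generate_covariates(cfg)
        # make vitamin D depend on age so neighbours carry signal
        cov["vitamin_d"] = 40 + 0.6 * cov["age"] + \
            np.random.default_rng(7).normal(0, 3, len(cov))
        truth = cov["vitamin_d"].copy()
        rng = np.random.default_rng(8)
        mask = rng.random(len(cov)) < 0.2
        cov.loc[mask, "vitamin_d"] = np.nan
        out = sr.knn_impute(cov)
        rmse = np.sqrt(((out["vitamin_d"][mask] - truth[mask]) ** 2).mean())
        baseline = np.sqrt(((truth[~mask].mean() - truth[mask]) ** 2).mean())
        assert rmse < baseline

    def test_all_missing_row_rejected(self):
        cfg = sr.GeneratorConfig(n_participants=20, seed=9)
        cov = sr.generate_covariates(cfg)
        cols = [c for c in cov.columns
                if c not in ("participant_id", "survey_weight")]
        cov.loc[0, cols] = np.nan
        with pytest.raises(ValueError):
            sr.knn_impute(cov)


class TestMealTiming:
    @pytest.fixture()
    def records_with_meals(self, analytic_records):
        rec = analytic_records.copy()
        rng = np.random.default_rng(10)
        rec["last_meal_diff_h"] = rng.normal(0, 1.5, len(rec))
        rec["eating_window_diff_h"] = rng.normal(0, 2.0, len(rec))
        miss = rng.random(len(rec)) < 0.38
        rec.loc[miss, "last_meal_diff_h"] = np.nan
        return rec

    def test_complete_case_count(self, records_with_meals):
        table = sr.sensitivity_meal_timing(records_with_meals, B=10, seed=11)
        expected_n = records_with_meals.dropna(
            subset=["last_meal_diff_h", "eating_window_diff_h"]).shape[0]
        assert (table["n_complete"] == expected_n).all()

    def test_independent_meal_covariates_barely_move_mfs(
            self, records_with_meals):
        # compare against model 4 on the same complete-case subset, so the
        # only difference is the two extra (outcome-independent) covariates
        sub = records_with_meals.dropna(
            subset=["last_meal_diff_h", "eating_window_diff_h"]
        ).reset_index(drop=True)
        base_fit = sr.fit_model(sub, 4, outcome="bmi")
        base = sr.multiplication_factors(base_fit)
        sens = sr.sensitivity_meal_timing(records_with_meals, B=10, seed=12)
        merged = base.merge(sens, on=["ethnicity", "sex", "contrast"],
                            suffixes=("_base", "_sens"))
        assert np.abs(merged["mf_sens"] - merged["mf_base"]).max() < 0.03

    def test_all_missing_aborts(self, analytic_records):
        rec = analytic_records.copy()
        rec["last_meal_diff_h"] = np.nan
        rec["eating_window_diff_h"] = np.nan
        with pytest.raises(RuntimeError):
            sr.sensitivity_meal_timing(rec)
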