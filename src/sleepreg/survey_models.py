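"""Survey-weighted log-linear models of adiposity on SRI quintiles.

Fits weighted least squares of log(outcome) on SRI exposure plus
covariates, with a design-based (linearization/sandwich) covariance
treating participants as independent sampling units:

    V(beta) = (X'WX)^{-1} [ sum_i (w_i e_i)^2 x_i x_i' ] (X'WX)^{-1}

Four model structures are supported:

1. quintiles + age + sex
2. model 1 + ethnicity, education, income, occupation, marital status,
   alcohol, smoking, vitamin D, caloric intake, PHQ-9, activity
3. model 2 + quintile x sex interactions
4. model 3 + quintile x ethnicity interactions

Exponentiated linear combinations of coefficients give multiplication
factors (MF) — ratios of expected outcome between an SRI quintile and Q1
within a sex/ethnicity stratum — with percentile-bootstrap confidence
intervals.  Effect modification is tested with a first-order Rao-Scott
corrected working likelihood-ratio test; the trend test enters the
per-quintile median SRI as a single continuous score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_cohort import CATEGORICAL_LEVELS, CONTINUOUS_COVARIATES

QUINTILES = (2, 3, 4, 5)

MODEL2_CATEGORICAL = ("ethnicity", "education", "income", "occupation",
                      "marital", "alcohol", "smoking")
MODEL2_CONTINUOUS = ("vitamin_d", "caloric_intake", "phq9", "activity")


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


# ---------------------------------------------------------------------------
# design matrices

def _dummies(df: pd.DataFrame, col: str) -> tuple[np.ndarray, list[str]]:
    """Indicator columns for the non-reference levels of a categorical."""
    levels = CATEGORICAL_LEVELS[col]
    missing_levels = set(df[col].dropna().unique()) - set(levels)
    if missing_levels:
        raise ValueError(f"unknown {col} levels: {sorted(missing_levels)}")
    cols = [(df[col] == lev).to_numpy(float) for lev in levels[1:]]
    names = [f"{col}[{lev}]" for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(df), 0)), names


def build_design(records: pd.DataFrame, model_id: int,
                 exposure: str = "quintile") -> tuple[np.ndarray, list[str]]:
    """Design matrix for one of the four model structures.

    ``exposure="quintile"`` codes Q2..Q5 indicators with Q1 as reference;
    ``exposure="sri"`` enters continuous SRI (used for prediction curves);
    ``exposure="score"`` enters the column ``sri_score`` (trend test).
    Interactions in models 3/4 attach to whichever exposure coding is used.
    """
    if model_id not in (1, 2, 3, 4):
        raise ValueError("model_id must be 1..4")
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]

    if exposure == "quintile":
        expo_cols = [(records["quintile"].to_numpy() == q).astype(float)
                     for q in QUINTILES]
        expo_names = [f"Q{q}" for q in QUINTILES]
    elif exposure == "sri":
        expo_cols = [records["sri_final"].to_numpy(float)]
        expo_names = ["sri"]
    elif exposure == "score":
        expo_cols = [records["sri_score"].to_numpy(float)]
        expo_names = ["sri_score"]
    else:
        raise ValueError(f"unknown exposure {exposure!r}")
    cols += expo_cols
    names += expo_names

    cols.append(records["age"].to_numpy(float))
    names.append("age")
    female = (records["sex"] == "Female").to_numpy(float)
    cols.append(female)
    names.append("sex[Female]")

    if model_id >= 2:
        for cat in MODEL2_CATEGORICAL:
            block, bnames = _dummies(records, cat)
            cols += list(block.T)
            names += bnames
        for cont in MODEL2_CONTINUOUS:
            cols.append(records[cont].to_numpy(float))
            names.append(cont)

    if model_id >= 3:
        for ec, en in zip(expo_cols, expo_names):
            cols.append(ec * female)
            names.append(f"{en}:sex[Female]")
    if model_id >= 4:
        eth_block, eth_names = _dummies(records, "ethnicity")
        for ec, en in zip(expo_cols, expo_names):
            for j, bn in enumerate(eth_names):
                cols.append(ec * eth_block[:, j])
                names.append(f"{en}:{bn}")

    X = np.column_stack(cols)
    if np.isnan(X).any():
        bad = [names[j] for j in np.unique(np.argwhere(np.isnan(X))[:, 1])]
        raise ValueError(f"missing values in design columns {bad}; impute first")
    return X, names


# ---------------------------------------------------------------------------
# fitting

@dataclass
class SurveyFit:
    """Weighted log-linear fit with design-based covariance."""

    model_id: int
    outcome: str
    params: pd.Series                # coefficients, indexed by term label
    cov_design: pd.DataFrame         # sandwich covariance
    cov_model: pd.DataFrame          # working (model-based) covariance
    n: int
    sum_weights: float
    weighted_sse: float              # sum_i w_i e_i^2
    weighted: bool
    exposure: str = "quintile"

    @property
    def working_loglik(self) -> float:
        """Profile working Gaussian log-likelihood (weights as frequencies)."""
        s2 = self.weighted_sse / self.sum_weights
        return -0.5 * self.sum_weights * (np.log(2 * np.pi * s2) + 1.0)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_design)),
                         index=self.params.index)


def fit_model(records: pd.DataFrame, model_id: int, outcome: str = "bmi",
              weighted: bool = True, exposure: str = "quintile",
              log_outcome: bool = True) -> SurveyFit:
    """Fit one of the four models of log(outcome).

    Point estimates come from weighted least squares; the reported
    covariance is the design-based sandwich with participants as
    independent units.  ``weighted=False`` refits with unit weights (the
    unweighted sensitivity analysis).
    """
    y = records[outcome].to_numpy(float)
    if log_outcome:
        if (y <= 0).any():
            raise ValueError(f"outcome {outcome!r} must be positive to log")
        y = np.log(y)
    X, names = build_design(records, model_id, exposure=exposure)
    w = (records["survey_weight"].to_numpy(float) if weighted
         else np.ones(len(records)))
    if (w <= 0).any():
        raise ValueError("survey weights must be positive")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        dep = [names[j] for j in range(X.shape[1])
               if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise RankDeficiencyError(f"collinear terms: {dep or 'unidentified'}")

    res = sm.WLS(y, X, weights=w).fit()
    beta = res.params
    e = y - X @ beta
    xw = X * w[:, None]
    A = X.T @ xw                                  # X'WX
    A_inv = np.linalg.inv(A)
    U = X * (w * e)[:, None]
    V_design = A_inv @ (U.T @ U) @ A_inv
    sigma2 = float((w * e ** 2).sum() / w.sum())
    V_model = sigma2 * A_inv

    return SurveyFit(
        model_id=model_id, outcome=outcome,
        params=pd.Series(beta, index=names),
        cov_design=pd.DataFrame(V_design, index=names, columns=names),
        cov_model=pd.DataFrame(V_model, index=names, columns=names),
        n=len(y), sum_weights=float(w.sum()),
        weighted_sse=float((w * e ** 2).sum()), weighted=weighted,
        exposure=exposure)


def combine_cycle_weights(weight_2yr, n_cycles: int = 2):
    """Combined-cycle analysis weight: the 2-year weight divided by cycles."""
    w = np.asarray(weight_2yr, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return w / n_cycles


# ---------------------------------------------------------------------------
# multiplication factors

def _mf_terms(fit: SurveyFit, ethnicity: str | None, sex: str | None,
              q: int) -> list[str]:
    terms = [f"Q{q}"]
    if sex == "Female" and f"Q{q}:sex[Female]" in fit.params.index:
        terms.append(f"Q{q}:sex[Female]")
    if ethnicity is not None:
        t = f"Q{q}:ethnicity[{ethnicity}]"
        if t in fit.params.index:
            terms.append(t)
        elif ethnicity not in CATEGORICAL_LEVELS["ethnicity"]:
            raise KeyError(f"unknown ethnicity stratum {ethnicity!r}")
    return terms


def multiplication_factors(fit: SurveyFit, strata: str = "auto") -> pd.DataFrame:
    """MF table: exp(linear combination) per stratum and quintile contrast.

    ``strata`` is "none" (overall, models 1-2), "sex" (model 3),
    "sex_ethnicity" (model 4) or "auto" (chosen from the model id).
    MF(Q1 vs Q1) = 1 by construction and is omitted.
    """
    if fit.exposure != "quintile":
        raise ValueError("multiplication factors need quintile exposure")
    if strata == "auto":
        strata = {1: "none", 2: "none", 3: "sex", 4: "sex_ethnicity"}[fit.model_id]
    if strata == "none":
        cells = [(None, None)]
    elif strata == "sex":
        cells = [(None, "Male"), (None, "Female")]
    elif strata == "sex_ethnicity":
        cells = [(e, s) for e in CATEGORICAL_LEVELS["ethnicity"]
                 for s in ("Male", "Female")]
    else:
        raise ValueError(f"unknown strata {strata!r}")
    if strata == "sex" and "Q5:sex[Female]" not in fit.params.index:
        raise KeyError("fit lacks quintile x sex interaction terms")
    if strata == "sex_ethnicity" and not any(
            t.startswith("Q5:ethnicity") for t in fit.params.index):
        raise KeyError("fit lacks quintile x ethnicity interaction terms")

    rows = []
    for eth, sex in cells:
        for q in QUINTILES:
            lc = sum(fit.params[t] for t in _mf_terms(fit, eth, sex, q))
            rows.append({"model_id": fit.model_id, "outcome": fit.outcome,
                         "ethnicity": eth or "", "sex": sex or "",
                         "contrast": f"Q{q} vs Q1", "mf": float(np.exp(lc))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(records: pd.DataFrame, estimator, B: int = 1000,
                 seed: int = 0, alpha: float = 0.05):
    """Percentile bootstrap over participants (weights carried along).

    ``estimator`` maps a records frame to a 1-D array-like of quantities.
    Aborts if more than 5% of resamples fail.

    Returns
    -------
    (point, lo, hi)
        Point estimate on the original data and the alpha/2, 1-alpha/2
        percentile bounds per quantity.
    """
    rng = np.random.default_rng(seed)
    point = np.asarray(estimator(records), dtype=float)
    n = len(records)
    draws = np.full((B, point.size), np.nan)
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            draws[b] = np.asarray(estimator(records.iloc[idx]), dtype=float)
        except Exception:
            failures += 1
            if failures > 0.05 * B:
                raise RuntimeError(
                    f"estimator failed on {failures}/{b + 1} resamples")
    ok = ~np.isnan(draws).any(axis=1)
    lo, hi = np.percentile(draws[ok], [100 * alpha / 2, 100 * (1 - alpha / 2)],
                           axis=0)
    return point, lo, hi


def mf_table_with_ci(records: pd.DataFrame, model_id: int, outcome: str = "bmi",
                     B: int = 1000, seed: int = 0, weighted: bool = True,
                     strata: str = "auto") -> pd.DataFrame:
    """Multiplication factors with percentile-bootstrap 95% CIs."""

    def estimator(df):
        fit = fit_model(df, model_id, outcome=outcome, weighted=weighted)
        return multiplication_factors(fit, strata=strata)["mf"].to_numpy()

    fit = fit_model(records, model_id, outcome=outcome, weighted=weighted)
    table = multiplication_factors(fit, strata=strata)
    _, lo, hi = bootstrap_ci(records, estimator, B=B, seed=seed)
    table["ci_low"] = lo
    table["ci_high"] = hi
    return table


# ---------------------------------------------------------------------------
# hypothesis tests

def interaction_test(fit_full: SurveyFit, fit_reduced: SurveyFit) -> dict:
    """First-order Rao-Scott corrected working likelihood-ratio test.

    The working LR statistic ``sum(w) * log(SSE_w,red / SSE_w,full)`` is
    scaled by the mean generalized design effect of the tested terms —
    the mean eigenvalue of V_model^{-1} V_design over the coefficients
    present only in the full model — and referred to chi-square on the
    number of tested terms.
    """
    full_terms = list(fit_full.params.index)
    red_terms = set(fit_reduced.params.index)
    if not red_terms <= set(full_terms):
        raise ValueError("models are not nested")
    tested = [t for t in full_terms if t not in red_terms]
    q = len(tested)
    if q == 0:
        return {"statistic": 0.0, "df": 0, "p_value": 1.0, "design_effect": 1.0}
    if fit_full.weighted_sse > fit_reduced.weighted_sse + 1e-12:
        raise ValueError("full model fits worse than reduced; not nested fits")

    lr = fit_full.sum_weights * np.log(
        max(fit_reduced.weighted_sse, 1e-300) /
        max(fit_full.weighted_sse, 1e-300))
    Vd = fit_full.cov_design.loc[tested, tested].to_numpy()
    Vm = fit_full.cov_model.loc[tested, tested].to_numpy()
    delta_bar = float(np.trace(np.linalg.solve(Vm, Vd)) / q)
    stat = lr / max(delta_bar, 1e-12)
    return {"statistic": float(stat), "df": q,
            "p_value": float(stats.chi2.sf(stat, q)),
            "design_effect": delta_bar, "working_lr": float(lr)}


def trend_test(records: pd.DataFrame, quintile_medians: dict[int, float],
               model_id: int = 2, outcome: str = "bmi",
               weighted: bool = True) -> dict:
    """P_trend: per-quintile median SRI entered as a continuous score.

    Refits the model with the quintile indicators replaced by a single
    score column and reports the design-based Wald p-value of its
    coefficient.
    """
    df = records.copy()
    df["sri_score"] = df["quintile"].map(quintile_medians).astype(float)
    fit = fit_model(df, min(model_id, 2), outcome=outcome, weighted=weighted,
                    exposure="score")
    coef = float(fit.params["sri_score"])
    se = float(np.sqrt(fit.cov_design.loc["sri_score", "sri_score"]))
    z = coef / se
    return {"coef": coef, "se": se, "z": z,
            "p_value": float(2 * stats.norm.sf(abs(z)))}


# ---------------------------------------------------------------------------
# reference profile and prediction curves

def _weighted_quantile(v: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(v)
    cw = np.cumsum(w[order])
    return float(v[order][np.searchsorted(cw, q * cw[-1])])


def covariate_profile(records: pd.DataFrame, skew_threshold: float = 1.0
                      ) -> dict[str, object]:
    """Survey-weighted reference covariate profile.

    Continuous covariates with |weighted skewness| above the threshold get
    their weighted median, others their weighted mean; categorical
    covariates get the weighted modal category.
    """
    w = records["survey_weight"].to_numpy(float)
    profile: dict[str, object] = {}
    for col in CONTINUOUS_COVARIATES:
        if col not in records.columns:
            continue
        v = records[col].to_numpy(float)
        m = np.average(v, weights=w)
        sd = np.sqrt(np.average((v - m) ** 2, weights=w))
        skew = np.average(((v - m) / sd) ** 3, weights=w) if sd > 0 else 0.0
        profile[col] = (_weighted_quantile(v, w, 0.5)
                        if abs(skew) > skew_threshold else float(m))
    for col in CATEGORICAL_LEVELS:
        if col not in records.columns:
            continue
        totals = records.groupby(col, observed=True)["survey_weight"].sum()
        profile[col] = totals.idxmax()
    return profile


def _curve_row(profile: dict, sex: str, ethnicity: str, sri: float
               ) -> pd.DataFrame:
    row = dict(profile)
    row["sex"] = sex
    row["ethnicity"] = ethnicity
    row["sri_final"] = sri
    return row


def _predict(fit: SurveyFit, rows: pd.DataFrame) -> np.ndarray:
    X, names = build_design(rows, fit.model_id, exposure="sri")
    beta = fit.params.reindex(names).to_numpy()
    return np.exp(X @ beta)


def predict_curve(records: pd.DataFrame, outcome: str = "bmi",
                  sri_grid: np.ndarray | None = None, B: int = 200,
                  seed: int = 0, weighted: bool = True,
                  envelope_draws: int = 0) -> pd.DataFrame:
    """Predicted outcome across the SRI range per sex x ethnicity stratum.

    Fits the continuous-SRI variant of model 4 (linear SRI plus the same
    sex and ethnicity interactions), evaluates exp(predicted log outcome)
    over ``sri_grid`` at the weighted reference profile, and adds
    percentile-bootstrap bands (``lo``/``hi``).  With ``envelope_draws``
    > 0, also adds a dispersion envelope (``env_lo``/``env_hi``): the
    2.5/97.5 percentiles of predictions across that many covariate vectors
    resampled from the data, holding the stratum fixed.
    """
    if sri_grid is None:
        sri_grid = np.arange(0.0, 101.0, 1.0)
    sri_grid = np.asarray(sri_grid, dtype=float)
    lo_obs, hi_obs = 0.0, 100.0
    if sri_grid.min() < lo_obs or sri_grid.max() > hi_obs:
        raise ValueError("sri_grid outside the supported 0..100 range")

    fit = fit_model(records, 4, outcome=outcome, weighted=weighted,
                    exposure="sri")
    profile = covariate_profile(records)
    strata = [(e, s) for e in CATEGORICAL_LEVELS["ethnicity"]
              for s in ("Male", "Female")]
    grids = {}
    for eth, sex in strata:
        rows = pd.DataFrame([_curve_row(profile, sex, eth, s) for s in sri_grid])
        grids[(eth, sex)] = rows

    out_rows = []
    point = {key: _predict(fit, rows) for key, rows in grids.items()}

    boot = {key: np.empty((B, len(sri_grid))) for key in grids}
    rng = np.random.default_rng(seed)
    n = len(records)
    for b in range(B):
        idx = rng.integers(0, n, n)
        bfit = fit_model(records.iloc[idx], 4, outcome=outcome,
                         weighted=weighted, exposure="sri")
        for key, rows in grids.items():
            boot[key][b] = _predict(bfit, rows)

    env = {}
    if envelope_draws > 0:
        erng = np.random.default_rng(seed + 1)
        idx = erng.integers(0, n, envelope_draws)
        draws = records.iloc[idx].reset_index(drop=True)
        for eth, sex in strata:
            d = draws.copy()
            d["sex"] = sex
            d["ethnicity"] = eth
            preds = np.empty((len(sri_grid), envelope_draws))
            for gi, s in enumerate(sri_grid):
                d["sri_final"] = s
                preds[gi] = _predict(fit, d)
            env[(eth, sex)] = np.percentile(preds, [2.5, 97.5], axis=1)

    for key in grids:
        eth, sex = key
        lo, hi = np.percentile(boot[key], [2.5, 97.5], axis=0)
        for gi, s in enumerate(sri_grid):
            row = {"ethnicity": eth, "sex": sex, "sri": s,
                   "fit": point[key][gi], "lo": lo[gi], "hi": hi[gi]}
            if env:
                row["env_lo"] = env[key][0][gi]
                row["env_hi"] = env[key][1][gi]
            out_rows.append(row)
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# imputation

def knn_impute(covariates: pd.DataFrame, k: int = 5,
               columns: tuple = CONTINUOUS_COVARIATES + tuple(CATEGORICAL_LEVELS)
               ) -> pd.DataFrame:
    """k-nearest-neighbour imputation under Gower distance over mixed types.

    Distance between two rows is the mean, over covariates observed in
    both, of |difference|/range for continuous columns and a 0/1 mismatch
    for categoricals.  A missing continuous cell gets the median of its k
    nearest donors with that cell observed; a categorical cell gets their
    mode.  Observed cells are never altered.
    """
    cols = [c for c in columns if c in covariates.columns]
    cont = [c for c in cols if c in CONTINUOUS_COVARIATES]
    cat = [c for c in cols if c in CATEGORICAL_LEVELS]
    out = covariates.copy()

    num = out[cont].to_numpy(float) if cont else np.empty((len(out), 0))
    rng_ = np.nanmax(num, axis=0) - np.nanmin(num, axis=0) if cont else None
    if cont:
        rng_ = np.where(rng_ > 0, rng_, 1.0)
        num_n = num / rng_
    codes = np.column_stack([
        pd.Categorical(out[c], categories=CATEGORICAL_LEVELS[c]).codes
        for c in cat]) if cat else np.empty((len(out), 0), dtype=int)

    any_missing = out[cols].isna().any(axis=1).to_numpy()
    if (out[cols].isna().all(axis=1)).any():
        raise ValueError("a row is missing every covariate; cannot impute")
    if (out[cols].isna().mean() > 0.5).any():
        bad = out[cols].isna().mean()
        raise ValueError(
            f"missingness above 50% in {list(bad[bad > 0.5].index)}")

    n = len(out)
    for i in np.flatnonzero(any_missing):
        parts = []
        if cont:
            d = np.abs(num_n - num_n[i])          # nan where either missing
            parts.append(d)
        if cat:
            both = (codes >= 0) & (codes[i] >= 0)
            dc = np.where(both, (codes != codes[i]).astype(float), np.nan)
            parts.append(dc)
        dist = np.nanmean(np.hstack(parts), axis=1)
        dist[i] = np.inf
        for c in cont:
            if np.isnan(out.at[out.index[i], c]):
                ok = ~out[c].isna().to_numpy()
                donors = np.argsort(np.where(ok, dist, np.inf),
                                    kind="stable")[:k]
                out.iat[i, out.columns.get_loc(c)] = float(
                    np.median(out[c].to_numpy(float)[donors]))
        for c in cat:
            if pd.isna(out.at[out.index[i], c]):
                ok = ~out[c].isna().to_numpy()
                donors = np.argsort(np.where(ok, dist, np.inf),
                                    kind="stable")[:k]
                vals = out[c].iloc[donors]
                out.iat[i, out.columns.get_loc(c)] = vals.mode().iloc[0]
    return out


# ---------------------------------------------------------------------------
# meal-timing sensitivity

def sensitivity_meal_timing(records: pd.DataFrame, outcome: str = "bmi",
                            B: int = 200, seed: int = 0,
                            weighted: bool = True,
                            min_subset: int = 100) -> pd.DataFrame:
    """Model 4 + meal-timing covariates on the complete-case subset.

    Requires columns ``last_meal_diff_h`` and ``eating_window_diff_h``
    (weekday-weekend differences, hours); rows missing either are dropped.
    Aborts when fewer than ``min_subset`` complete cases remain.
    """
    need = ["last_meal_diff_h", "eating_window_diff_h"]
    for c in need:
        if c not in records.columns:
            raise ValueError(f"records lack meal-timing column {c!r}")
    sub = records.dropna(subset=need).reset_index(drop=True)
    if len(sub) < min_subset:
        raise RuntimeError(
            f"meal-timing subset too small: {len(sub)} < {min_subset}")

    def estimator(df):
        fit = _fit_meal(df, outcome, weighted)
        return multiplication_factors(fit, strata="sex_ethnicity")["mf"].to_numpy()

    fit = _fit_meal(sub, outcome, weighted)
    table = multiplication_factors(fit, strata="sex_ethnicity")
    _, lo, hi = bootstrap_ci(sub, estimator, B=B, seed=seed)
    table["ci_low"] = lo
    table["ci_high"] = hi
    table["n_complete"] = len(sub)
    return table


def _fit_meal(df: pd.DataFrame, outcome: str, weighted: bool) -> SurveyFit:
    """Model 4 with the two meal-timing covariates appended to the design."""
    y = np.log(df[outcome].to_numpy(float))
    X, names = build_design(df, 4)
    extra = df[["last_meal_diff_h", "eating_window_diff_h"]].to_numpy(float)
    X = np.hstack([X, extra])
    names = names + ["last_meal_diff_h", "eating_window_diff_h"]
    w = df["survey_weight"].to_numpy(float) if weighted else np.ones(len(df))
    res = sm.WLS(y, X, weights=w).fit()
    e = y - X @ res.params
    A_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    U = X * (w * e)[:, None]
    Vd = A_inv @ (U.T @ U) @ A_inv
    s2 = float((w * e ** 2).sum() / w.sum())
    return SurveyFit(model_id=4, outcome=outcome,
                     params=pd.Series(res.params, index=names),
                     cov_design=pd.DataFrame(Vd, index=names, columns=names),
                     cov_model=pd.DataFrame(s2 * A_inv, index=names, columns=names),
                     n=len(y), sum_weights=float(w.sum()),
                     weighted_sse=float((w * e ** 2).sum()), weighted=weighted)
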