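"""Statistical analysis of lesion load.

Lesion volumes are log-transformed with an offset of one voxel volume so the
transform exists at zero load.  Cross-sectional group, grey-matter, genotype
and plasma-marker associations are ordinary least squares on the latest-visit
log volume with age, sex, scanner and total intracranial volume (TIV) as
covariates; coefficients on the log scale are reported as percent excess
100·(exp(β)−1).  Longitudinal accrual uses a two-level linear mixed model
(random intercept and random slope per subject, REML).  Brain-behaviour
associations are Spearman correlations between covariate-adjusted residuals.
Following the source design, no multiple-comparison correction is applied by
default.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

GROUP_ORDER = ("control", "presymptomatic", "symptomatic")
SEVERITY_THRESHOLDS_MM3 = (1000.0, 2500.0)


class RankDeficientDesign(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, as used for reported percentages."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def log_volume(v_mm3, voxel_volume_mm3: float = 1.0):
    """log(v + one voxel volume); defined at v = 0."""
    v = np.asarray(v_mm3, float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    out = np.log(v + voxel_volume_mm3)
    return float(out) if np.isscalar(v_mm3) else out


def percent_excess(beta_log, ci_log=None):
    """Re-express a log-scale effect multiplicatively: 100·(exp(·)−1)."""
    with np.errstate(over="ignore"):
        point = 100.0 * (np.exp(np.asarray(beta_log, float)) - 1.0)
        point = float(point) if np.ndim(beta_log) == 0 else point
        if ci_log is None:
            return point
        ci = 100.0 * (np.exp(np.asarray(ci_log, float)) - 1.0)
    return point, ci


@dataclass
class ModelResult:
    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    residuals: np.ndarray
    shapiro: tuple[float, float]
    percent_excess: dict = field(default_factory=dict)
    fitted: object = None

    def excess(self, term: str):
        """Point estimate and 95% CI of a log-scale term, in percent."""
        return self.percent_excess[term]


def _check_rank(exog: pd.DataFrame):
    x = np.asarray(exog, float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns whose removal restores full column rank
        bad = []
        for j, name in enumerate(exog.columns):
            keep = [k for k in range(x.shape[1]) if k != j]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                bad.append(str(name))
        raise RankDeficientDesign(
            f"design matrix rank {rank} < {x.shape[1]} columns; "
            f"collinear columns: {bad}")


def _reference_levels(table: pd.DataFrame, columns=("sex", "scanner")):
    """Treatment coding with the most frequent level as reference."""
    refs = {}
    for col in columns:
        if col in table:
            refs[col] = table[col].value_counts().idxmax()
    return refs


def _encode(term: str, table: pd.DataFrame, refs: dict) -> str:
    if term in refs:
        return f"C({term}, Treatment('{refs[term]}'))"
    if term == "group":
        return "C(group, Treatment('control'))"
    return term


def latest_visit(table: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: the maximum visit_time (ties: last row wins)."""
    if "visit_time" not in table:
        return table
    idx = table.groupby("subject_id")["visit_time"].idxmax()
    return table.loc[idx].reset_index(drop=True)


def _attach_excess(result: ModelResult):
    for term in result.params.index:
        lo, hi = result.conf_int.loc[term]
        result.percent_excess[term] = (
            percent_excess(result.params[term]),
            (percent_excess(lo), percent_excess(hi)))


def fit_cross_sectional(table: pd.DataFrame, outcome: str = "wmh_mm3",
                        predictors=("group",),
                        covariates=("age", "sex", "scanner", "tiv_mm3"),
                        voxel_volume_mm3: float = 1.0,
                        use_latest_visit: bool = True) -> ModelResult:
    """OLS on log lesion volume at the latest time point.

    ``outcome`` may be a raw-volume column (log-transformed with the 1-voxel
    offset) or an existing ``log_*`` column used as-is.  Percent-excess
    transforms of every coefficient are attached, along with the Shapiro-Wilk
    normality check on residuals.
    """
    df = latest_visit(table) if use_latest_visit else table.copy()
    df = df.dropna(subset=[c for c in (outcome, *predictors, *covariates)
                           if c in df]).copy()
    if outcome.startswith("log_"):
        df["_y"] = df[outcome]
    else:
        df["_y"] = log_volume(df[outcome].to_numpy(), voxel_volume_mm3)
    refs = _reference_levels(df)
    terms = [_encode(t, df, refs) for t in (*predictors, *covariates)]
    formula = "_y ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    _check_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    fit = model.fit()
    resid = np.asarray(fit.resid)
    shapiro = sps.shapiro(resid) if resid.size >= 3 else (np.nan, np.nan)
    result = ModelResult(fit.params, fit.conf_int(), fit.pvalues, resid,
                         (float(shapiro[0]), float(shapiro[1])), fitted=fit)
    _attach_excess(result)
    return result


def fit_longitudinal(table: pd.DataFrame, outcome: str = "wmh_mm3",
                     predictors=("group",),
                     covariates=("age", "sex", "scanner", "tiv_mm3"),
                     voxel_volume_mm3: float = 1.0,
                     reml: bool = True) -> ModelResult:
    """Two-level mixed model of log volume with random intercept and slope.

    Fixed effects: time, predictor main effects and predictor×time
    interactions, plus the standard covariates; random effects: per-subject
    intercept and slope on time (unstructured 2×2 covariance, REML).
    The accrual in %/year for a group is ``percent_excess`` of its total time
    slope.
    """
    df = table.dropna(subset=[c for c in (outcome, *predictors, *covariates,
                                          "visit_time", "subject_id")
                              if c in table]).copy()
    if df.groupby("subject_id")["visit_time"].nunique().max() < 2:
        raise ValueError("longitudinal model needs repeated visits")
    # canonical row order: estimates must not depend on table ordering
    df = df.sort_values(["subject_id", "visit_time"]).reset_index(drop=True)
    if outcome.startswith("log_"):
        df["_y"] = df[outcome]
    else:
        df["_y"] = log_volume(df[outcome].to_numpy(), voxel_volume_mm3)
    if "age" in covariates:
        # baseline age: within-subject ageing is collinear with visit_time
        base_age = df.sort_values("visit_time").groupby("subject_id")[
            "age"].first()
        df["age"] = df["subject_id"].map(base_age)
    refs = _reference_levels(df)
    fixed = ["visit_time"]
    for t in predictors:
        enc = _encode(t, df, refs)
        fixed += [enc, f"visit_time:{enc}"]
    fixed += [_encode(c, df, refs) for c in covariates]
    formula = "_y ~ " + " + ".join(fixed)
    model = smf.mixedlm(formula, data=df, groups=df["subject_id"],
                        re_formula="~visit_time")
    import warnings as _w
    try:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            fit = model.fit(reml=reml, method=["lbfgs", "powell"])
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ConvergenceError(f"mixed model failed: {exc}") from exc
    if not np.all(np.isfinite(np.asarray(fit.params, float))):
        raise ConvergenceError(f"mixed model failed: {fit.summary()}")
    # marginal residuals: y − Xβ̂ (conditional residuals need the random
    # effects, whose prediction fails on boundary covariance estimates)
    resid = np.asarray(model.endog - model.exog @ np.asarray(fit.fe_params))
    shapiro = sps.shapiro(resid) if resid.size >= 3 else (np.nan, np.nan)
    result = ModelResult(fit.fe_params, fit.conf_int().loc[
        fit.fe_params.index], fit.pvalues.loc[fit.fe_params.index],
        resid, (float(shapiro[0]), float(shapiro[1])), fitted=fit)
    _attach_excess(result)
    return result


def accrual_percent_per_year(result: ModelResult, group: str | None = None
                             ) -> float:
    """Group-specific accrual in %/year from a longitudinal fit."""
    slope = result.params["visit_time"]
    if group is not None and group != "control":
        inter = [t for t in result.params.index
                 if t.startswith("visit_time:") and f"[T.{group}]" in t]
        slope = slope + sum(result.params[t] for t in inter)
    return percent_excess(float(slope))


def residual_spearman(table: pd.DataFrame, region_col: str, score_col: str,
                      volume_covariates=("age", "sex", "scanner", "tiv_mm3"),
                      score_covariates=("age", "sex", "education"),
                      voxel_volume_mm3: float = 1.0,
                      use_latest_visit: bool = True):
    """Spearman ρ between covariate-adjusted lesion load and a cognitive score.

    Log volume is residualized on age/sex/scanner/TIV and the score on
    age/sex/education; the correlation is computed between the two residual
    vectors.
    """
    df = latest_visit(table) if use_latest_visit else table.copy()
    needed = {region_col, score_col, *volume_covariates, *score_covariates}
    df = df.dropna(subset=[c for c in needed if c in df]).copy()
    if len(df) < 5:
        raise ValueError("fewer than 5 complete cases")
    if df[score_col].nunique() <= 1:
        raise ValueError(f"score {score_col!r} is constant; "
                         "correlation undefined")
    if region_col.startswith("log_"):
        df["_y"] = df[region_col]
    else:
        df["_y"] = log_volume(df[region_col].to_numpy(), voxel_volume_mm3)
    refs = _reference_levels(df)
    f_vol = "_y ~ " + " + ".join(_encode(c, df, refs)
                                 for c in volume_covariates)
    f_sc = f"{score_col} ~ " + " + ".join(_encode(c, df, refs)
                                          for c in score_covariates)
    r_vol = smf.ols(f_vol, data=df).fit().resid
    r_sc = smf.ols(f_sc, data=df).fit().resid
    rho, p = sps.spearmanr(r_vol, r_sc)
    return float(rho), float(p)


def adjust_pvalues(pvalues, method: str | None = None):
    """Optional multiple-comparison adjustment.

    The analysis stack applies none by default (dependent outcomes are
    strongly correlated); pass e.g. ``"bonferroni"`` or ``"fdr_bh"`` to
    opt in.  Returns the p-values unchanged when ``method`` is None.
    """
    p = np.asarray(pvalues, float)
    if method is None:
        return p
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method=method)[1]


def severity_group(total_wmh_mm3):
    """Stratify lesion load: <1000 none/mild, 1000–2500 moderate, ≥2500 severe
    (thresholds in mm³ against a mean TIV of 1400 ml)."""
    v = np.asarray(total_wmh_mm3, float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    lo, hi = SEVERITY_THRESHOLDS_MM3
    labels = np.where(v < lo, "none/mild",
                      np.where(v < hi, "moderate", "severe"))
    return str(labels) if np.ndim(total_wmh_mm3) == 0 else labels


def occupancy_percent(volume_mm3: float, tiv_ml: float) -> float:
    """Volume as a percentage of TIV, reported to 2 decimals (half-up)."""
    if tiv_ml <= 0:
        raise ValueError("TIV must be positive")
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    return round_half_up(100.0 * volume_mm3 / (tiv_ml * 1000.0), 2)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographics: N, sex ratio, percent female, mean (SD)s."""
    df = latest_visit(table)
    unknown = set(df["group"]) - set(GROUP_ORDER)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    rows = []
    for group in GROUP_ORDER:
        g = df[df["group"] == group]
        if g.empty:
            continue
        n = len(g)
        n_f = int((g["sex"] == "F").sum())
        row = {"group": group, "n": n, "female": n_f, "male": n - n_f,
               "percent_female": round_half_up(100.0 * n_f / n, 1)}
        for col in ("age", "education", "nfl_pg_ml", "gfap_pg_ml"):
            if col in g:
                row[f"{col}_mean"] = float(g[col].mean())
                row[f"{col}_sd"] = float(g[col].std())
        rows.append(row)
    return pd.DataFrame(rows)


def severity_table(table: pd.DataFrame, volume_col: str = "wmh_mm3"
                   ) -> pd.DataFrame:
    """Carrier stratification by lesion-load severity (latest visit)."""
    df = latest_visit(table)
    carriers = df[df["group"].isin(("presymptomatic", "symptomatic"))].copy()
    carriers["severity"] = severity_group(carriers[volume_col].to_numpy())
    rows = []
    for sev in ("none/mild", "moderate", "severe"):
        s = carriers[carriers["severity"] == sev]
        row = {"severity": sev, "n": len(s)}
        for grp in ("presymptomatic", "symptomatic"):
            sub = df[df["group"] == grp]
            n_g = int((s["group"] == grp).sum())
            row[f"{grp}_n"] = n_g
            row[f"{grp}_percent"] = round_half_up(
                100.0 * n_g / max(len(sub), 1), 1)
        row["wmh_mean_mm3"] = float(s[volume_col].mean()) if len(s) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
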