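"""Control-calibrated presymptomatic staging.

A mutation carrier is considered presymptomatic when the baseline cUHDRS lies
above the lower bound of a 95% prediction interval from a linear mixed model
fitted to family controls (random intercept and age-slope per control,
fixed effects for age, sex, education, marital status, health behaviours and
comorbidity count).  The interval is a *prediction* interval for a new
individual: its variance combines fixed-coefficient uncertainty, the
random-effect covariance and the residual variance, and the bound uses the
normal 97.5% quantile (z = 1.959964; with thousands of controls the t
correction is immaterial).

The module also applies the cohort-selection flowchart: complete core data,
baseline score above the bound, complete health-behaviour data, no off-norm
trajectory (very rapid early decline with extreme CAG, or no decline despite
advanced age), and at least two visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import scores
from .synthetic_cohort import REFERENCE_AGE

__all__ = [
    "MixedModelFit",
    "StagingOptions",
    "fit_control_model",
    "prediction_lower_bound",
    "apply_flowchart",
    "per_subject_slopes",
]

Z_975 = 1.959964

#: fixed-effect covariates of the control model, in design order (after the
#: intercept and centred age).  Comorbidity count is the sum of the five
#: history flags.
CONTROL_COVARIATES = ["sex", "isced", "marital", "alcohol_units", "tobacco",
                      "coffee", "drugs", "bmi", "n_comorbidities"]

_COMORBIDITY_FLAGS = ["cmb_cardio", "cmb_metab", "cmb_neuro", "cmb_psych", "cmb_other"]


@dataclass
class MixedModelFit:
    """Control-calibrated linear mixed model for cUHDRS."""

    feature_names: list[str]
    beta: np.ndarray
    beta_cov: np.ndarray
    D: np.ndarray            # 2x2 random-effect covariance (intercept, age-slope)
    sigma2: float            # residual variance
    reference_age: float = REFERENCE_AGE
    converged: bool = True

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("residual variance must be positive")
        if np.linalg.eigvalsh((self.D + self.D.T) / 2).min() < -1e-10:
            raise ValueError("random-effect covariance must be PSD")


def _comorbidity_count(baseline: pd.DataFrame) -> np.ndarray:
    return baseline[_COMORBIDITY_FLAGS].to_numpy(float).sum(axis=1)


def _design(baseline: pd.DataFrame, age: np.ndarray, reference_age: float) -> tuple[np.ndarray, list[str]]:
    cols = {"intercept": np.ones(len(age)), "age_c": np.asarray(age, float) - reference_age}
    b = baseline.reset_index(drop=True)
    for c in CONTROL_COVARIATES:
        cols[c] = _comorbidity_count(b) if c == "n_comorbidities" else b[c].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns lying in the span of their predecessors
        bad = []
        for j in range(1, X.shape[1]):
            prev = X[:, :j]
            resid = X[:, j] - prev @ np.linalg.lstsq(prev, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(names[j])
        raise ValueError(f"singular design: collinear column(s) {', '.join(bad) or 'unknown'}")


def fit_control_model(control_visits: pd.DataFrame, control_baseline: pd.DataFrame,
                      *, random_effects: bool = True,
                      reference_age: float = REFERENCE_AGE) -> MixedModelFit:
    """Fit the control mixed model by REML.

    ``control_visits`` uses the long-format visit schema; cUHDRS is computed
    internally.  With ``random_effects=False`` the model degenerates to OLS
    (D = 0), which is also the exact limit when every control has a single
    visit.
    """
    merged = scores.add_cuhdrs_column(control_visits).merge(
        control_baseline, on="subjid", validate="many_to_one")
    if merged["cuhdrs"].isna().any():
        merged = merged.dropna(subset=["cuhdrs"])
    if merged["subjid"].nunique() < 2:
        raise ValueError("need at least two controls with a scorable visit")
    y = merged["cuhdrs"].to_numpy(float)
    X, names = _design(merged, merged["visit_age"].to_numpy(float), reference_age)
    if np.isnan(X).any():
        bad = names[int(np.flatnonzero(np.isnan(X).any(axis=0))[0])]
        raise ValueError(f"control covariate {bad!r} has missing values")
    _check_full_rank(X, names)

    if not random_effects:
        res = sm.OLS(y, X).fit()
        return MixedModelFit(names, res.params, res.cov_params(), np.zeros((2, 2)),
                             float(res.mse_resid), reference_age)

    exog_re = np.column_stack([np.ones(len(y)), merged["visit_age"].to_numpy(float) - reference_age])
    model = sm.MixedLM(y, X, groups=merged["subjid"].to_numpy(), exog_re=exog_re)
    res = model.fit(reml=True, method="lbfgs", maxiter=200)
    if not res.converged:
        # boundary fits (random-effect variances near zero) often stall
        # under lbfgs; Powell is slower but robust there
        res = model.fit(reml=True, method="powell", maxiter=500)
    k = X.shape[1]
    beta_cov = np.asarray(res.cov_params())[:k, :k]
    D = np.asarray(res.cov_re)
    # clamp tiny negative eigenvalues from the optimizer boundary
    w, V = np.linalg.eigh((D + D.T) / 2)
    D = (V * np.maximum(w, 0.0)) @ V.T
    return MixedModelFit(names, np.asarray(res.fe_params), beta_cov, D,
                         float(res.scale), reference_age, converged=bool(res.converged))


def prediction_lower_bound(fit: MixedModelFit, baseline: pd.DataFrame, age,
                           *, z: float = Z_975) -> np.ndarray:
    """Lower bound of the 95% prediction interval for new individuals.

    v = x' Cov(beta) x + [1, age_c] D [1, age_c]' + sigma^2 and the bound is
    x'beta - z*sqrt(v).  Vectorised over baseline rows (with matching ages).
    """
    age = np.atleast_1d(np.asarray(age, float))
    X, _ = _design(baseline, age, fit.reference_age)
    yhat = X @ fit.beta
    Zr = np.column_stack([np.ones(len(age)), age - fit.reference_age])
    v = (np.einsum("ij,jk,ik->i", X, fit.beta_cov, X)
         + np.einsum("ij,jk,ik->i", Zr, fit.D, Zr)
         + fit.sigma2)
    if (v < 0).any():
        raise ValueError("negative prediction variance (numerical failure)")
    return yhat - z * np.sqrt(v)


def per_subject_slopes(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-subject OLS slope of cUHDRS on age (NaN for single-visit subjects)."""
    scored = scores.add_cuhdrs_column(visits)
    rows = []
    for sid, g in scored.groupby("subjid", sort=True):
        g = g.dropna(subset=["cuhdrs"])
        a = g["visit_age"].to_numpy(float)
        if len(g) < 2 or np.ptp(a) <= 0:
            rows.append((sid, np.nan))
        else:
            rows.append((sid, float(np.polyfit(a, g["cuhdrs"].to_numpy(float), 1)[0])))
    return pd.DataFrame(rows, columns=["subjid", "slope"])


@dataclass
class StagingOptions:
    """Tunable thresholds of the selection flowchart.

    The off-norm rule mirrors the verbal exclusion: very rapid and early
    decline with an extreme expansion (CAG above ``off_norm_cag`` declining
    faster than ``rapid_decline_slope`` cUHDRS points/yr), or lack of decline
    (slope above ``max_nondecline_slope``) despite baseline age beyond
    ``advanced_age``.
    """

    z: float = Z_975
    off_norm_cag: int = 55
    rapid_decline_slope: float = -2.0
    max_nondecline_slope: float = 0.0
    advanced_age: float = 60.0
    core_columns: tuple = ("cag", "sex", "isced", "marital", "residence")
    behavior_columns: tuple = ("alcohol_units", "tobacco", "coffee", "drugs", "bmi")
    comorbidity_columns: tuple = tuple(_COMORBIDITY_FLAGS) + ("rx_anx", "rx_dep")


_FLOWCHART_ORDER = ["missing_core_data", "below_bound", "missing_behavior_data",
                    "off_norm_trajectory", "single_visit"]


def apply_flowchart(carrier_visits: pd.DataFrame, carrier_baseline: pd.DataFrame,
                    fit: MixedModelFit,
                    options: StagingOptions | None = None) -> tuple[pd.DataFrame, dict]:
    """Stage carriers and apply the exclusion flowchart in order.

    Returns a per-subject decision table (subjid, baseline_cuhdrs,
    lower_bound, presymptomatic, exclusion_reason) and an ordered dict of
    exclusion counts; a subject is attributed to the first rule that
    excludes it, so counts sum to (input - retained).
    """
    opt = options or StagingOptions()
    base = carrier_baseline.reset_index(drop=True)
    scored = scores.add_cuhdrs_column(carrier_visits)
    first = (scored.dropna(subset=["cuhdrs"])
             .sort_values(["subjid", "visit_age"], kind="stable")
             .groupby("subjid", sort=True).first())
    n_visits = scored.dropna(subset=["cuhdrs"]).groupby("subjid").size()
    slopes = per_subject_slopes(carrier_visits).set_index("subjid")["slope"]

    idx = base["subjid"]
    baseline_age = first["visit_age"].reindex(idx).to_numpy(float)
    baseline_score = first["cuhdrs"].reindex(idx).to_numpy(float)

    # lower bound is only computable with complete model covariates; mark
    # incomplete-behaviour subjects first so the bound never sees NaNs
    core_missing = base[list(opt.core_columns)].isna().any(axis=1).to_numpy() \
        | np.isnan(baseline_score)
    behavior_missing = base[list(opt.behavior_columns)].isna().any(axis=1).to_numpy() \
        | base[list(opt.comorbidity_columns)].isna().any(axis=1).to_numpy()

    bound = np.full(len(base), np.nan)
    computable = ~(core_missing | behavior_missing)
    if computable.any():
        bound[computable] = prediction_lower_bound(
            fit, base.loc[computable].reset_index(drop=True),
            baseline_age[computable], z=opt.z)

    slope = slopes.reindex(idx).to_numpy(float)
    cag = base["cag"].to_numpy(float)
    off_norm = ((cag > opt.off_norm_cag) & (slope < opt.rapid_decline_slope)) \
        | ((slope > opt.max_nondecline_slope) & (baseline_age > opt.advanced_age))
    off_norm = off_norm & ~np.isnan(slope)

    reason = np.full(len(base), "", dtype=object)
    reason[core_missing] = "missing_core_data"
    free = reason == ""
    below = free & ~(baseline_score > bound)  # NaN bound counts as not-above
    # subjects whose bound is incomputable because of behaviour gaps are not
    # judged on the bound; they fall to the behaviour rule next
    below &= computable
    reason[below] = "below_bound"
    free = reason == ""
    reason[free & behavior_missing] = "missing_behavior_data"
    free = reason == ""
    reason[free & off_norm] = "off_norm_trajectory"
    free = reason == ""
    reason[free & (n_visits.reindex(idx).fillna(0).to_numpy() < 2)] = "single_visit"

    decisions = pd.DataFrame({
        "subjid": base["subjid"],
        "baseline_cuhdrs": baseline_score,
        "lower_bound": bound,
        "presymptomatic": reason == "",
        "exclusion_reason": reason,
    })
    counts = {r: int((reason == r).sum()) for r in _FLOWCHART_ORDER}
    counts["retained"] = int((reason == "").sum())
    return decisions, counts
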