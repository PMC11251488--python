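"""Descriptive comparison of slow vs fast decliners (Table-1 style).

Categorical variables are compared with Pearson's chi-squared test (no
continuity correction), continuous variables with a two-sided two-sample
t-test (Welch by default; the classic equal-variance variant is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import scores

__all__ = ["chi_squared_test", "t_test", "build_table_one", "GroupComparison"]

log = logging.getLogger(__name__)

#: Table-1 variables: name -> ("categorical" | "continuous", source)
TABLE_ONE_VARIABLES = {
    "sex": "categorical",
    "age": "continuous",
    "cag": "continuous",
    "isced": "continuous",
    "marital": "categorical",
    "residence": "categorical",
    "alcohol_units": "continuous",
    "tobacco": "categorical",
    "coffee": "categorical",
    "drugs": "categorical",
    "bmi": "continuous",
    "cmb_cardio": "categorical",
    "cmb_metab": "categorical",
    "cmb_neuro": "categorical",
    "cmb_psych": "categorical",
    "cmb_other": "categorical",
    "rx_anx": "categorical",
    "rx_dep": "categorical",
    "cuhdrs": "continuous",
    "tfc": "continuous",
    "tms": "continuous",
    "sdmt": "continuous",
    "swr": "continuous",
    "followup_years": "continuous",
}


def chi_squared_test(contingency) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a counts matrix.

    X^2 = sum (O-E)^2 / E with expected counts from the margins, df =
    (r-1)(c-1), no continuity correction.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.sum() <= 0:
        raise ValueError("contingency table is empty")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all():
        raise ValueError(f"zero margin in row {int(np.flatnonzero(~row_ok)[0])}")
    if not col_ok.all():
        raise ValueError(f"zero margin in column {int(np.flatnonzero(~col_ok)[0])}")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def t_test(group_a, group_b, *, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            log.info("degenerate t-test: both groups constant and equal; p = 1")
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    variable: str
    var_type: str                    # categorical | continuous
    summaries: dict                  # group -> {"n":..} per level or {"mean","sd","n"}
    test: str                        # chi_squared | t_test
    statistic: float
    p_value: float


def _subject_level(visits: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: baseline covariates + first-visit scores + follow-up."""
    scored = scores.add_cuhdrs_column(visits).dropna(subset=["cuhdrs"])
    scored = scored.sort_values(["subjid", "visit_age"], kind="stable")
    first = scored.groupby("subjid", sort=True).first()
    span = scored.groupby("subjid")["visit_age"].agg(lambda a: a.max() - a.min())
    out = baseline.set_index("subjid").copy()
    out["age"] = first["visit_age"]
    for c in ("tfc", "tms", "sdmt", "swr", "cuhdrs"):
        out[c] = first[c]
    out["followup_years"] = span
    return out.reset_index()


def build_table_one(visits: pd.DataFrame, baseline: pd.DataFrame,
                    labels: pd.DataFrame, *, equal_var: bool = False) -> list[GroupComparison]:
    """Compare slow vs fast decliners on every Table-1 variable.

    ``labels`` carries subjid and a ``label`` column ("slow"/"fast").
    Categorical variables get Pearson's chi-squared on the level-by-group
    counts, continuous ones a t-test on subject-level values.
    """
    subj = _subject_level(visits, baseline).merge(
        labels[["subjid", "label"]], on="subjid", validate="one_to_one")
    groups = ("slow", "fast")
    out: list[GroupComparison] = []
    for var, kind in TABLE_ONE_VARIABLES.items():
        if var not in subj.columns:
            continue
        sub = subj.dropna(subset=[var])
        if kind == "categorical":
            tab = pd.crosstab(sub[var], sub["label"]).reindex(columns=list(groups), fill_value=0)
            tab = tab.loc[tab.sum(axis=1) > 0]
            try:
                stat, p = chi_squared_test(tab.to_numpy())
            except ValueError:
                stat, p = float("nan"), float("nan")
            summaries = {}
            for grp in groups:
                col = tab[grp]
                tot = col.sum()
                summaries[grp] = {str(level): {"n": int(cnt),
                                               "pct": 100.0 * cnt / tot if tot else float("nan")}
                                  for level, cnt in col.items()}
            out.append(GroupComparison(var, kind, summaries, "chi_squared", stat, p))
        elif kind == "continuous":
            a = sub.loc[sub["label"] == "slow", var].to_numpy(float)
            b = sub.loc[sub["label"] == "fast", var].to_numpy(float)
            try:
                stat, p = t_test(a, b, equal_var=equal_var)
            except ValueError:
                stat, p = float("nan"), float("nan")
            summaries = {grp: {"mean": float(np.mean(v)) if len(v) else float("nan"),
                               "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
                               "n": int(len(v))}
                         for grp, v in (("slow", a), ("fast", b))}
            out.append(GroupComparison(var, kind, summaries, "t_test", stat, p))
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
    return out


def table_one_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten a comparison list to a tidy CSV-ready frame."""
    rows = []
    for c in comparisons:
        if c.var_type == "continuous":
            s, f = c.summaries["slow"], c.summaries["fast"]
            rows.append({"variable": c.variable, "type": c.var_type,
                         "slow": f"{s['mean']:.2f} ({s['sd']:.2f})",
                         "fast": f"{f['mean']:.2f} ({f['sd']:.2f})",
                         "test": c.test, "statistic": c.statistic, "p_value": c.p_value})
        else:
            for level in c.summaries["slow"]:
                s = c.summaries["slow"][level]
                f = c.summaries["fast"].get(level, {"n": 0, "pct": float("nan")})
                rows.append({"variable": f"{c.variable}={level}", "type": c.var_type,
                             "slow": f"{s['n']} ({s['pct']:.1f}%)",
                             "fast": f"{f['n']} ({f['pct']:.1f}%)",
                             "test": c.test, "statistic": c.statistic, "p_value": c.p_value})
    return pd.DataFrame(rows)


def render_table_one(comparisons: list[GroupComparison]) -> str:
    """Aligned plain-text rendering of the comparison table."""
    df = table_one_frame(comparisons)
    widths = {c: max(len(c), int(df[c].astype(str).str.len().max() or 0)) for c in df.columns}
    lines = ["  ".join(c.ljust(widths[c]) for c in df.columns)]
    for _, r in df.iterrows():
        cells = []
        for c in df.columns:
            v = r[c]
            cells.append((f"{v:.4g}" if isinstance(v, float) else str(v)).ljust(widths[c]))
        lines.append("  ".join(cells))
    return "\n".join(lines)
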