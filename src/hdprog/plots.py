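"""Minimal figure output: importance bars and partial-dependence curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["importance_bar", "pd_curves"]


def importance_bar(importance: pd.DataFrame, path) -> None:
    """Horizontal mean(|shap|) bar chart, most important on top."""
    df = importance.sort_values("mean_abs_shap")
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(df) + 1))
    ax.barh(df["feature"], df["mean_abs_shap"], color="#4878a8")
    ax.set_xlabel("mean(|shap|) (cUHDRS points)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pd_curves(pd_table: pd.DataFrame, path) -> None:
    """Grid of partial-dependence curves, one panel per feature."""
    feats = pd_table["feature"].unique()
    fig, axes = plt.subplots(1, len(feats), figsize=(3.2 * len(feats), 3), squeeze=False)
    for ax, feat in zip(axes[0], feats):
        sub = pd_table[pd_table["feature"] == feat]
        for stratum, grp in sub.groupby("stratum"):
            ax.plot(grp["grid"], grp["pd"], label=stratum)
        ax.set_xlabel(feat)
        ax.set_ylabel("predicted cUHDRS")
        if sub["stratum"].nunique() > 1:
            ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
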