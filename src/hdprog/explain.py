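"""Model-agnostic explanation: Shapley values, interactions, partial dependence.

Shapley values are estimated with the permutation estimator against a
background sample: for an observation x, a background row r and a permutation
pi of the features, features of r are replaced by those of x in pi-order, and
the contribution of feature j is the prediction change when j is inserted.
For every (r, pi) the contributions telescope to f(x) - f(r), so the averaged
attributions satisfy local accuracy *exactly* —

    base_value + sum_j phi_j(x) = f(x)

with base_value the mean prediction over the background — at any permutation
count; sampling only affects the split among features, never the total.
Permutations are drawn in antithetic pairs (pi and its reverse) for variance
reduction.

Shapley interaction indices are estimated by Monte Carlo over feature
coalitions: for a pair (j, k), random subsets S of the remaining features are
sampled (size uniform, then members uniform — the Shapley interaction
weighting) and the second difference
f(S+jk) - f(S+j) - f(S+k) + f(S) is averaged, with features outside the
coalition taken from background rows.

Partial dependence sweeps one feature over a grid, averaging predictions with
all other features held at their observed values; optional strata partition
the rows (e.g. CAG below/above the cohort median) and yield one curve each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Explanation",
    "PDCurve",
    "shap_values",
    "importance_ranking",
    "shap_interaction",
    "partial_dependence",
]


def _as_array(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)


@dataclass
class Explanation:
    """Per-observation Shapley attributions in prediction (cUHDRS) units."""

    base_value: float
    phi: np.ndarray                 # observations x features
    predictions: np.ndarray         # f(x) per observation
    feature_names: list[str]
    mc_config: dict = field(default_factory=dict)

    def importance(self) -> pd.DataFrame:
        return importance_ranking(self)

    def to_long_frame(self) -> pd.DataFrame:
        n, p = self.phi.shape
        return pd.DataFrame({
            "observation": np.repeat(np.arange(n), p),
            "feature": np.tile(self.feature_names, n),
            "phi": self.phi.ravel(),
        })


def shap_values(predict_fn, X, background, n_permutation_pairs: int = 64,
                seed: int = 0) -> Explanation:
    """Permutation-Shapley attributions for every row of ``X``.

    ``predict_fn`` maps a feature matrix to predictions.  ``background`` is
    the reference sample defining the base value.  Deterministic given
    ``seed``; local accuracy is exact by construction.
    """
    Xa = _as_array(X)
    bg = _as_array(background)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D sample")
    if Xa.shape[1] != bg.shape[1]:
        raise ValueError(f"feature count mismatch: X has {Xa.shape[1]}, "
                         f"background has {bg.shape[1]}")
    if n_permutation_pairs < 1:
        raise ValueError("need at least one permutation pair")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(Xa.shape[1])]

    n, p = Xa.shape
    m = bg.shape[0]
    rng = np.random.default_rng(seed)

    f_x = np.asarray(predict_fn(Xa), float)
    f_bg = np.asarray(predict_fn(bg), float)
    base_value = float(f_bg.mean())

    phi = np.zeros((n, p))
    # row layout of the working matrix: observation-major blocks of the
    # background, so pair (o, r) sits at index o*m + r
    x_rep = np.repeat(Xa, m, axis=0)
    perms = []
    for _ in range(n_permutation_pairs):
        fwd = rng.permutation(p)
        perms.extend([fwd, fwd[::-1]])

    for pi in perms:
        current = np.tile(bg, (n, 1))
        prev = np.tile(f_bg, n)
        for step, j in enumerate(pi):
            current[:, j] = x_rep[:, j]
            if step < p - 1:
                cur = np.asarray(predict_fn(current), float)
            else:
                cur = np.repeat(f_x, m)  # fully x: prediction known exactly
            phi[:, j] += (cur - prev).reshape(n, m).sum(axis=1)
            prev = cur
    phi /= len(perms) * m

    return Explanation(base_value=base_value, phi=phi, predictions=f_x,
                       feature_names=names,
                       mc_config={"n_permutation_pairs": n_permutation_pairs,
                                  "background_size": m, "seed": seed})


def importance_ranking(expl: Explanation) -> pd.DataFrame:
    """Features sorted by mean(|phi|), ties broken by column order."""
    imp = np.abs(expl.phi).mean(axis=0)
    order = np.argsort(-imp, kind="stable")
    return pd.DataFrame({
        "feature": [expl.feature_names[j] for j in order],
        "mean_abs_shap": imp[order],
    })


def shap_interaction(predict_fn, X, background, pair, n_draws: int = 64,
                     seed: int = 0) -> np.ndarray:
    """Monte-Carlo Shapley interaction values for one feature pair.

    Returns one interaction value per row of ``X``; symmetric in (j, k) by
    construction (the second difference is).  Deterministic given ``seed``.
    """
    j, k = pair
    if j == k:
        raise ValueError("interaction pair must be two distinct features")
    Xa = _as_array(X)
    bg = _as_array(background)
    if Xa.shape[1] != bg.shape[1]:
        raise ValueError("feature count mismatch between X and background")
    n, p = Xa.shape
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    if isinstance(j, str):
        j = names.index(j)
    if isinstance(k, str):
        k = names.index(k)

    others = np.array([f for f in range(p) if f not in (j, k)])
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(n_draws):
        r = bg[rng.integers(bg.shape[0])]
        size = int(rng.integers(0, len(others) + 1)) if len(others) else 0
        S = rng.choice(others, size=size, replace=False) if size else np.array([], dtype=int)
        base = np.tile(r, (n, 1))
        if size:
            base[:, S] = Xa[:, S]
        with_j = base.copy(); with_j[:, j] = Xa[:, j]
        with_k = base.copy(); with_k[:, k] = Xa[:, k]
        with_jk = with_j.copy(); with_jk[:, k] = Xa[:, k]
        stacked = np.vstack([with_jk, with_j, with_k, base])
        preds = np.asarray(predict_fn(stacked), float).reshape(4, n)
        acc += preds[0] - preds[1] - preds[2] + preds[3]
    return acc / n_draws


@dataclass
class PDCurve:
    """Partial-dependence curve, optionally stratified."""

    feature: str
    grid: np.ndarray
    pd_values: np.ndarray
    strata: dict[str, tuple[np.ndarray, np.ndarray]] | None = None  # name -> (grid, pd)

    def __post_init__(self):
        if len(self.grid) > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("PD grid must be strictly increasing")
        if not np.all(np.isfinite(self.pd_values)):
            raise ValueError("PD values must be finite")


def _default_grid(col: np.ndarray, n_grid: int) -> np.ndarray:
    uniq = np.unique(col)
    if len(uniq) <= max(n_grid // 2, 10):
        return uniq.astype(float)
    qs = np.linspace(0.0, 1.0, n_grid)
    return np.unique(np.quantile(col, qs))


def partial_dependence(predict_fn, X, feature, grid=None, strata=None,
                       n_grid: int = 40) -> PDCurve:
    """Partial dependence of the prediction on one feature.

    ``strata`` may be an array of labels (one per row); each stratum yields
    its own curve over the same grid, and empty strata are dropped with a
    warning.  Ordinal/binary features default to their observed levels as
    the grid.
    """
    Xa = _as_array(X)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(Xa.shape[1])]
    fidx = names.index(feature) if isinstance(feature, str) else int(feature)
    fname = names[fidx]
    col = Xa[:, fidx]
    g = np.asarray(grid, float) if grid is not None else _default_grid(col, n_grid)

    def curve(rows: np.ndarray) -> np.ndarray:
        out = np.empty(len(g))
        work = rows.copy()
        for i, v in enumerate(g):
            work[:, fidx] = v
            out[i] = float(np.mean(predict_fn(work)))
        return out

    pd_main = curve(Xa)
    strata_out = None
    if strata is not None:
        strata = np.asarray(strata)
        strata_out = {}
        for lab in pd.unique(strata):
            mask = strata == lab
            if not mask.any():
                warnings.warn(f"stratum {lab!r} is empty; dropped", stacklevel=2)
                continue
            strata_out[str(lab)] = (g, curve(Xa[mask]))
    return PDCurve(feature=fname, grid=g, pd_values=pd_main, strata=strata_out)
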