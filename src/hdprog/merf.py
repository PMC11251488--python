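"""Mixed-effects random forest (MERF) for longitudinal cUHDRS trajectories.

The model is  y_ij = f(x_ij) + b0_i + b1_i * (age_ij - 40) + eps_ij  with a
regression forest as the fixed-effect learner and per-subject random
intercept/slope (age as the timescale, centred at a reference age so the
intercept is identifiable over short follow-ups).  Fitting alternates, EM
style, between

  (a) refitting the forest on the de-trended responses y - Z b,
  (b) the BLUP update        b_i = D Z_i' V_i^{-1} (y_i - f(X_i)),
  (c) the residual variance  s2 <- N^{-1} sum_i [e_i'e_i
                                   + s2 (n_i - s2 tr V_i^{-1})],
  (d) the covariance         D  <- m^{-1} sum_i [b_i b_i'
                                   + (D - D Z_i' V_i^{-1} Z_i D)],

with V_i = Z_i D Z_i' + s2 I and e_i = y_i - f(X_i) - Z_i b_i, monitoring the
generalized log-likelihood criterion

  GLL = sum_i [ e_i'e_i / s2 + b_i' D^{-1} b_i + ln|D| + n_i ln s2 ],

which should be non-increasing once the alternation settles.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from . import scores
from .synthetic_cohort import REFERENCE_AGE

__all__ = [
    "FEATURES",
    "MerfConfig",
    "MerfModel",
    "build_feature_matrix",
    "fit_merf",
    "predict",
    "evaluate",
    "split_by_subject",
    "save_model",
    "load_model",
]

#: fixed-effect features, in canonical column order
FEATURES = [
    "age", "cag", "sex", "isced", "marital", "residence", "alcohol_units",
    "tobacco", "coffee", "drugs", "bmi", "cmb_cardio", "cmb_metab",
    "cmb_neuro", "cmb_psych", "cmb_other", "rx_anx", "rx_dep",
]

log = logging.getLogger(__name__)


@dataclass
class MerfConfig:
    n_trees: int = 300
    max_depth: int | None = None
    min_samples_leaf: int = 5
    max_features: int | None = None  # default: ceil(p / 3)
    max_iter: int = 30
    tol: float = 1e-4                # relative GLL change
    seed: int = 0
    reference_age: float = REFERENCE_AGE

    def make_forest(self, n_features: int) -> RandomForestRegressor:
        mf = self.max_features if self.max_features is not None else ceil(n_features / 3)
        return RandomForestRegressor(
            n_estimators=self.n_trees, max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf, max_features=mf,
            random_state=self.seed, n_jobs=1, bootstrap=True)


@dataclass
class MerfModel:
    forest: RandomForestRegressor
    feature_names: list[str]
    subject_ids: np.ndarray      # m unique training subjects
    b: np.ndarray                # m x 2 random effects (intercept, age-slope)
    D: np.ndarray                # 2 x 2
    sigma2: float
    gll_trace: list[float]
    config: MerfConfig
    n_iterations: int = field(init=False)

    def __post_init__(self):
        self.n_iterations = len(self.gll_trace)
        if np.linalg.eigvalsh((self.D + self.D.T) / 2).min() < -1e-10:
            raise ValueError("D must be PSD")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def build_feature_matrix(visits: pd.DataFrame, baseline: pd.DataFrame):
    """Assemble (X, y, subjects) from the long-format cohort tables.

    X holds the 18 fixed-effect features in canonical order, one row per
    scorable visit; y is cUHDRS.  Rows with any missing feature or score are
    dropped (completeness is a staging-stage concern).
    """
    merged = scores.add_cuhdrs_column(visits).merge(
        baseline, on="subjid", validate="many_to_one")
    merged = merged.rename(columns={"visit_age": "age"})
    merged = merged.dropna(subset=["cuhdrs"] + FEATURES)
    X = merged[FEATURES].astype(float).reset_index(drop=True)
    y = merged["cuhdrs"].to_numpy(float)
    subjects = merged["subjid"].to_numpy()
    return X, y, subjects


def _z_matrix(ages: np.ndarray, reference_age: float) -> np.ndarray:
    return np.column_stack([np.ones(len(ages)), np.asarray(ages, float) - reference_age])


def _floor_psd(D: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh((D + D.T) / 2)
    if w.min() < floor:
        warnings.warn("random-effect covariance projected to the PSD cone", stacklevel=3)
    return (V * np.maximum(w, floor)) @ V.T


def _variance_components(rtr, z, M, n_i, b, D, sigma2, *, max_sweeps, rtol):
    """Apply the closed-form (b, sigma2, D) update sweep(s).

    Works entirely in per-subject 2x2 sufficient statistics (Woodbury form of
    the prescribed updates): with posterior precision A_i = D^-1 + M_i/s2 and
    C_i = A_i^-1,

        b_i            = C_i z_i / s2
        e_i'e_i        = r'r - 2 b'z + b'M b
        s2 contribution = e_i'e_i + tr(C_i M_i)       (== e'e + s2(n - s2 tr V^-1))
        D              <- m^-1 sum_i [b_i b_i' + C_i]  (C_i == D - D Z'V^-1 Z D)

    so each sweep is the exact update set, vectorised over subjects; with
    many sweeps the loop converges to the variance-component maximizer for
    the given residuals.
    """
    m = len(n_i)
    N = float(n_i.sum())
    for _ in range(max_sweeps):
        Dinv = np.linalg.inv(D)
        A = Dinv[None, :, :] + M / sigma2
        C = np.linalg.inv(A)
        b = np.einsum("ijk,ik->ij", C, z) / sigma2
        ee = rtr - 2 * np.einsum("ij,ij->i", b, z) + np.einsum("ij,ijk,ik->i", b, M, b)
        trCM = np.einsum("ijk,ikj->i", C, M)
        sigma2_new = float((ee + trCM).sum() / N)
        D_new = _floor_psd((np.einsum("ij,ik->ijk", b, b) + C).sum(axis=0) / m)
        moved = max(abs(sigma2_new - sigma2) / max(sigma2, 1e-12),
                    float(np.abs(D_new - D).max()) / max(float(np.abs(D).max()), 1e-12))
        sigma2, D = max(sigma2_new, 1e-10), D_new
        if moved < rtol:
            break
    return b, D, sigma2


def fit_merf(X, y, subjects, config: MerfConfig | None = None) -> MerfModel:
    """Fit the MERF by EM-style alternation.

    Each iteration refits the forest on the de-trended responses and applies
    one closed-form (b, sigma2, D) update sweep on the training residuals,
    recording the GLL, until the GLL change falls below ``config.tol``
    (relative) or ``config.max_iter`` is reached.  The GLL trace is logged
    but not guaranteed monotone: the forest and the random effects compete
    for the subject-level signal (visits of one subject are near-neighbours
    in feature space), and the slow redistribution between them can raise
    the plug-in GLL while the variance components converge.

    All randomness (bootstraps, feature subsampling) derives from
    ``config.seed``; refitting with the same data and config is
    bit-identical.  Ages for the random-slope design are taken from the
    ``age`` feature column.
    """
    cfg = config or MerfConfig()
    Xdf = pd.DataFrame(X, columns=FEATURES) if not isinstance(X, pd.DataFrame) else X
    Xa = Xdf.to_numpy(float)
    y = np.asarray(y, float)
    subjects = np.asarray(subjects)
    if len(y) != len(Xa) or len(subjects) != len(y):
        raise ValueError("X, y and subjects must align")

    uniq, inv = np.unique(subjects, return_inverse=True)
    m = len(uniq)
    groups = [np.flatnonzero(inv == i) for i in range(m)]
    ages = Xa[:, Xdf.columns.get_loc("age")]
    Z = _z_matrix(ages, cfg.reference_age)
    for g in groups:
        if len(g) > 1 and np.ptp(ages[g]) == 0:
            warnings.warn("subject with identical ages at every visit: random slope "
                          "weakly identified", stacklevel=2)
            break

    # per-subject sufficient statistics that do not depend on the residuals
    n_i = np.array([len(g) for g in groups])
    M = np.stack([Z[g].T @ Z[g] for g in groups])           # m x 2 x 2

    b = np.zeros((m, 2))
    D = 0.1 * np.eye(2)
    sigma2 = float(np.var(y)) / 2.0 or 1.0
    forest = cfg.make_forest(Xa.shape[1])

    gll_trace: list[float] = []
    prev_gll = np.inf
    for _ in range(cfg.max_iter):
        # (a) forest on de-trended responses
        ystar = y - np.einsum("ij,ij->i", Z, b[inv])
        forest.fit(Xa, ystar)
        resid = y - forest.predict(Xa)

        # (b)-(d) one closed-form update sweep given this forest
        rtr = np.array([resid[g] @ resid[g] for g in groups])
        z = np.stack([Z[g].T @ resid[g] for g in groups])
        b, D, sigma2 = _variance_components(rtr, z, M, n_i, b, D, sigma2,
                                            max_sweeps=1, rtol=0.0)

        # GLL at the updated parameters
        Dinv = np.linalg.inv(D)
        _, logdetD = np.linalg.slogdet(D)
        ee = rtr - 2 * np.einsum("ij,ij->i", b, z) + np.einsum("ij,ijk,ik->i", b, M, b)
        gll = float((ee / sigma2 + np.einsum("ij,jk,ik->i", b, Dinv, b)
                     + logdetD + n_i * np.log(sigma2)).sum())
        gll_trace.append(gll)
        if len(gll_trace) > 2 and gll > prev_gll + 1e-6 * max(1.0, abs(gll)):
            log.info("GLL rose by %.4g at iteration %d (forest/random-effect "
                     "redistribution; see methods note)", gll - prev_gll,
                     len(gll_trace) - 1)
        if abs(prev_gll - gll) < cfg.tol * max(1.0, abs(gll)):
            break
        prev_gll = gll

    # final forest refit on the converged de-trended responses (full-forest
    # predictions are what predict() serves)
    ystar = y - np.einsum("ij,ij->i", Z, b[inv])
    forest.fit(Xa, ystar)

    return MerfModel(forest=forest, feature_names=list(Xdf.columns),
                     subject_ids=uniq, b=b, D=D, sigma2=sigma2,
                     gll_trace=gll_trace, config=cfg)


def predict(model: MerfModel, X, subjects=None, *, return_flags: bool = False):
    """Predict cUHDRS.

    Population prediction is f(X); when ``subjects`` is given, known training
    subjects additionally receive their estimated Z b_i trajectory.  Unknown
    subjects fall back to the population prediction (flagged when
    ``return_flags``).
    """
    Xdf = pd.DataFrame(X, columns=model.feature_names) if not isinstance(X, pd.DataFrame) else X
    Xa = Xdf[model.feature_names].to_numpy(float)
    pred = model.forest.predict(Xa)
    unknown = np.zeros(len(pred), dtype=bool)
    if subjects is not None:
        subjects = np.asarray(subjects)
        lookup = {s: i for i, s in enumerate(model.subject_ids)}
        ages = Xa[:, model.feature_names.index("age")]
        Z = _z_matrix(ages, model.config.reference_age)
        for r, s in enumerate(subjects):
            i = lookup.get(s)
            if i is None:
                unknown[r] = True
            else:
                pred[r] += Z[r] @ model.b[i]
    if return_flags:
        return pred, unknown
    return pred


def evaluate(model: MerfModel, X, y, subjects=None) -> dict:
    """MAE and MSE of (subject-specific, when subjects given) predictions."""
    y = np.asarray(y, float)
    if len(y) == 0:
        raise ValueError("empty evaluation partition")
    pred = predict(model, X, subjects)
    err = y - pred
    return {"mae": float(np.mean(np.abs(err))), "mse": float(np.mean(err ** 2))}


def split_by_subject(subjects, test_frac: float = 0.2, seed: int = 0):
    """Seeded train/validation split by subject (never by visit).

    Returns boolean row masks (train, test).
    """
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    n_test = int(round(test_frac * len(uniq)))
    test_subjects = set(rng.choice(uniq, size=n_test, replace=False))
    test = np.array([s in test_subjects for s in subjects])
    return ~test, test


def save_model(model: MerfModel, path) -> Path:
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    return path


def load_model(path) -> MerfModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, MerfModel):
        raise TypeError("archive does not contain a MERF model")
    return model
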