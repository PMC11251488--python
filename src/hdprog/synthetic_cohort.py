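"""Synthetic Enroll-HD-like longitudinal cohort generator with known ground truth.

The real study population (an application-gated observational cohort of
huntingtin-mutation carriers and their family controls) cannot ship with a
package, so every downstream stage is exercised on cohorts drawn from an
explicit generative model:

    latent cUHDRS_ij = mu(age_ij, CAG_i, covariates_i)
                       + b0_i + b1_i * (age_ij - 40) + eps_ij

where ``mu`` is a fixed-effect surface (a logistic-in-age decline whose
midpoint moves earlier with CAG length, plus additive covariate terms with
the effect signs reported for this population) and (b0, b1) are per-subject
random intercept/slope draws.  The four UHDRS components are then generated
so that applying the published cUHDRS formula to them recovers the latent
score exactly (three components are drawn around their observed means, the
fourth is solved from the identity).

Covariate marginals default to the observed cohort description (57.5% female,
mean age 40.16, mean BMI 26.0, mean education ISCED 3.92, ...), so a large
generated cohort reproduces those descriptives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import scores

__all__ = [
    "GroundTruth",
    "SimulationConfig",
    "CohortTruth",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "CohortSchemaError",
    "VISIT_COLUMNS",
    "BASELINE_COLUMNS",
    "REFERENCE_AGE",
]

VISIT_COLUMNS = ["subjid", "visit_age", "tfc", "tms", "sdmt", "swr"]
BASELINE_COLUMNS = [
    "subjid", "group", "cag", "sex", "isced", "marital", "residence",
    "alcohol_units", "tobacco", "coffee", "drugs", "bmi",
    "cmb_cardio", "cmb_metab", "cmb_neuro", "cmb_psych", "cmb_other",
    "rx_anx", "rx_dep",
]

#: Reference age (years) at which the random intercept is defined; the random
#: slope acts on (age - REFERENCE_AGE).  Close to the cohort mean age so that
#: intercept and slope stay identifiable over short follow-ups.
REFERENCE_AGE = 40.0


def _default_covariate_effects() -> dict:
    # Additive latent-cUHDRS effects (points); signs follow the per-factor
    # effect sizes reported for this population: protective education,
    # moderate alcohol, current coffee and female sex; detrimental tobacco,
    # antidepressant/anxiolytic exposure and psychiatric history.
    return {
        "sex": 0.18,            # female (=1) vs male
        "isced_per_level": 0.45,
        "marital": -0.02,       # in couple vs single
        "residence": 0.02,      # city vs elsewhere
        "alcohol_peak": 0.25,   # protective up to ~16 units/week
        "alcohol_peak_units": 16.0,
        "alcohol_excess_slope": -0.01,
        "tobacco": -0.30,
        "coffee_currently": 0.06,
        "coffee_heavy": 0.04,
        "drugs": -0.05,
        "bmi_low_bonus": 0.14,  # BMI < ~23 vs above (additive approximation)
        "cmb_cardio": -0.05,
        "cmb_metab": -0.05,
        "cmb_neuro": -0.08,
        "cmb_psych": -0.20,
        "cmb_other": -0.03,
        "rx_anx": -0.15,
        "rx_dep": -0.34,
    }


@dataclass
class GroundTruth:
    """Generative model for the latent cUHDRS trajectory.

    The carrier decline is ``amplitude / (1 + exp(-(age - m(CAG))/width))``
    with midpoint ``m(CAG) = midpoint_intercept - midpoint_per_cag * CAG``:
    longer expansions pull the decline earlier, which also plants a genuine
    age x CAG interaction for the explanation stage to recover.  Controls
    (no expansion) get only a gentle linear ageing slope.  Covariate terms
    are additive, so age x CAG is the only structural interaction.
    """

    baseline_level: float = 18.5
    decline_amplitude: float = 6.0
    decline_width_years: float = 8.0
    midpoint_intercept: float = 110.0
    midpoint_per_cag: float = 1.5
    control_age_slope: float = -0.02  # points per year past the reference age
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    random_intercept_sd: float = 0.8
    random_slope_sd: float = 0.05
    intercept_slope_corr: float = -0.1
    residual_sd: float = 0.5
    #: optional override: mapping (age, cag, baseline-frame) -> latent mean
    fixed_effect_function: Callable | None = None

    def random_effect_cov(self) -> np.ndarray:
        c = self.intercept_slope_corr * self.random_intercept_sd * self.random_slope_sd
        D = np.array([[self.random_intercept_sd ** 2, c],
                      [c, self.random_slope_sd ** 2]])
        if np.linalg.eigvalsh(D).min() < -1e-12:
            raise ValueError("random-effect covariance is not positive semidefinite")
        return D

    def covariate_contribution(self, baseline: pd.DataFrame) -> np.ndarray:
        e = self.covariate_effects
        alcohol = baseline["alcohol_units"].to_numpy(float)
        bmi = baseline["bmi"].to_numpy(float)
        coffee = baseline["coffee"].to_numpy(float)
        out = (
            e["sex"] * baseline["sex"].to_numpy(float)
            + e["isced_per_level"] * (baseline["isced"].to_numpy(float) - 4.0)
            + e["marital"] * baseline["marital"].to_numpy(float)
            + e["residence"] * baseline["residence"].to_numpy(float)
            + e["alcohol_peak"] * np.minimum(alcohol, e["alcohol_peak_units"]) / e["alcohol_peak_units"]
            + e["alcohol_excess_slope"] * np.maximum(alcohol - e["alcohol_peak_units"], 0.0)
            + e["tobacco"] * baseline["tobacco"].to_numpy(float)
            + e["coffee_currently"] * (coffee == 1)
            + e["coffee_heavy"] * (coffee == 2)
            + e["drugs"] * baseline["drugs"].to_numpy(float)
            # smooth step: full bonus below BMI 23, fading over ~1.5 units
            + e["bmi_low_bonus"] / (1.0 + np.exp((bmi - 23.0) / 1.5))
        )
        for k in ("cmb_cardio", "cmb_metab", "cmb_neuro", "cmb_psych", "cmb_other",
                  "rx_anx", "rx_dep"):
            out = out + e[k] * baseline[k].to_numpy(float)
        return out

    def carrier_decline(self, age, cag) -> np.ndarray:
        age = np.asarray(age, float)
        cag = np.asarray(cag, float)
        midpoint = self.midpoint_intercept - self.midpoint_per_cag * cag
        return self.decline_amplitude / (1.0 + np.exp(-(age - midpoint) / self.decline_width_years))

    def latent_mean(self, age, baseline: pd.DataFrame) -> np.ndarray:
        """Fixed-effect latent cUHDRS mean at ``age`` for each baseline row."""
        if self.fixed_effect_function is not None:
            return np.asarray(
                self.fixed_effect_function(np.asarray(age, float), baseline), float
            )
        age = np.asarray(age, float)
        cag = baseline["cag"].to_numpy(float)
        carrier = (baseline["group"] == "carrier").to_numpy()
        trend = np.where(
            carrier,
            -self.carrier_decline(age, cag),
            self.control_age_slope * (age - REFERENCE_AGE),
        )
        return self.baseline_level + trend + self.covariate_contribution(baseline)


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    ``visits_per_subject`` is an inclusive integer range; visit spacing is
    annual by default.  ``cag_distribution`` maps carrier CAG values in
    [36, 55] to probabilities; controls draw a normal-range allele (no
    expansion).  ``missing_behavior_rate`` blanks the health-behaviour block
    of that fraction of subjects so the selection flowchart has something to
    exclude.
    """

    n_carriers: int = 400
    n_controls: int = 300
    visits_per_subject: tuple[int, int] = (2, 8)
    visit_spacing_years: float = 1.0
    cag_distribution: dict[int, float] | None = None
    age_mean: float = 40.16
    age_sd: float = 12.60
    age_range: tuple[float, float] = (18.0, 80.0)
    female_frac: float = 0.575
    isced_mean: float = 3.92
    isced_sd: float = 1.16
    marital_couple_frac: float = 0.666
    residence_city_frac: float = 0.456
    alcohol_zero_frac: float = 0.45
    alcohol_nonzero_mean: float = 7.1
    tobacco_frac: float = 0.235
    coffee_probs: tuple[float, float, float] = (0.372, 0.369, 0.259)
    drugs_frac: float = 0.146
    bmi_mean: float = 26.01
    bmi_sd: float = 5.36
    comorbidity_fracs: dict = field(default_factory=lambda: {
        "cmb_cardio": 0.133, "cmb_metab": 0.126, "cmb_neuro": 0.150,
        "cmb_psych": 0.270, "cmb_other": 0.699})
    rx_anx_frac: float = 0.069
    rx_dep_frac: float = 0.153
    missing_behavior_rate: float = 0.0
    effect_spec: GroundTruth = field(default_factory=GroundTruth)
    seed: int = 0

    def __post_init__(self):
        if self.n_carriers < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_carriers + self.n_controls == 0:
            raise ValueError("cohort must contain at least one subject")
        lo, hi = self.visits_per_subject
        if lo < 1 or hi < lo:
            raise ValueError("visits_per_subject must be a range with 1 <= lo <= hi")
        if self.cag_distribution is not None:
            vals = np.array(list(self.cag_distribution.keys()))
            probs = np.array(list(self.cag_distribution.values()))
            if vals.min() < 36 or vals.max() > 55:
                raise ValueError("carrier CAG support must lie in [36, 55]")
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
                raise ValueError("cag_distribution probabilities must be >=0 and sum to 1")
        for p in (self.female_frac, self.tobacco_frac, self.drugs_frac,
                  self.rx_anx_frac, self.rx_dep_frac, self.alcohol_zero_frac,
                  self.missing_behavior_rate, *self.coffee_probs,
                  *self.comorbidity_fracs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        self.effect_spec.random_effect_cov()  # raises if not PSD

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_spec"].pop("fixed_effect_function", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "effect_spec" in d and isinstance(d["effect_spec"], dict):
            d["effect_spec"] = GroundTruth(**d["effect_spec"])
        for key in ("visits_per_subject", "age_range", "coffee_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "cag_distribution" in d and d["cag_distribution"] is not None:
            d["cag_distribution"] = {int(k): float(v) for k, v in d["cag_distribution"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "seed" not in d:
            raise ValueError("simulation config must set a seed")
        return cls.from_dict(d)


@dataclass
class CohortTruth:
    """Ground-truth record accompanying a simulated cohort."""

    config: SimulationConfig
    subject_effects: pd.DataFrame   # subjid, b0, b1
    latent: pd.DataFrame            # subjid, visit_age, latent_mean, latent_cuhdrs


def _default_cag_probs() -> tuple[np.ndarray, np.ndarray]:
    # discretized normal around the observed carrier mean 41.97 (SD 2.52)
    vals = np.arange(36, 56)
    w = np.exp(-0.5 * ((vals - 42.0) / 2.5) ** 2)
    return vals, w / w.sum()


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _simulate_baseline(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_carriers + cfg.n_controls
    subjid = np.array([f"S{i:05d}" for i in range(1, n + 1)])
    group = np.array(["carrier"] * cfg.n_carriers + ["control"] * cfg.n_controls)

    if cfg.cag_distribution is not None:
        vals = np.array(sorted(cfg.cag_distribution))
        probs = np.array([cfg.cag_distribution[v] for v in vals], float)
    else:
        vals, probs = _default_cag_probs()
    cag = np.empty(n, dtype=int)
    cag[: cfg.n_carriers] = rng.choice(vals, size=cfg.n_carriers, p=probs)
    # controls carry a normal-range allele, well below the 36-repeat threshold
    cag[cfg.n_carriers:] = np.clip(np.round(rng.normal(19.0, 3.0, size=cfg.n_controls)), 10, 30)

    df = pd.DataFrame({
        "subjid": subjid,
        "group": group,
        "cag": cag,
        "sex": (rng.random(n) < cfg.female_frac).astype(int),
        "isced": np.clip(np.round(rng.normal(cfg.isced_mean, cfg.isced_sd, n)), 0, 6).astype(int),
        "marital": (rng.random(n) < cfg.marital_couple_frac).astype(int),
        "residence": (rng.random(n) < cfg.residence_city_frac).astype(int),
        "alcohol_units": np.where(
            rng.random(n) < cfg.alcohol_zero_frac, 0.0,
            np.minimum(rng.exponential(cfg.alcohol_nonzero_mean, n), 60.0)).round(1),
        "tobacco": (rng.random(n) < cfg.tobacco_frac).astype(int),
        "coffee": rng.choice([0, 1, 2], size=n, p=np.asarray(cfg.coffee_probs) /
                             np.sum(cfg.coffee_probs)),
        "drugs": (rng.random(n) < cfg.drugs_frac).astype(int),
        # truncation bounds wide enough that the realized mean stays within
        # ~0.1 of the target
        "bmi": _truncnorm(rng, cfg.bmi_mean, cfg.bmi_sd, 13.0, 55.0, n).round(1),
    })
    for k in sorted(cfg.comorbidity_fracs):  # canonical order: robust to config (de)serialisation
        df[k] = (rng.random(n) < cfg.comorbidity_fracs[k]).astype(int)
    df["rx_anx"] = (rng.random(n) < cfg.rx_anx_frac).astype(int)
    df["rx_dep"] = (rng.random(n) < cfg.rx_dep_frac).astype(int)
    return df[BASELINE_COLUMNS]


_BEHAVIOR_COLS = ["alcohol_units", "tobacco", "coffee", "drugs", "bmi"]


def _split_components(latent: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Inverse-formula construction of TFC/TMS/SDMT/SWR from latent cUHDRS.

    Three components are drawn around the observed cohort means, each
    carrying a share of the latent deviation from the cohort-mean score; the
    fourth (SWR) is solved from the cUHDRS identity so the formula recovers
    the latent score exactly.  Out-of-range solutions are clipped and the
    identity re-solved through SDMT, then TMS (whose 0-124 range always
    absorbs the remainder for plausible scores).
    """
    d = latent - 17.16
    n = latent.shape[0]
    tfc = np.clip(12.88 + 0.15 * d * scores.CUHDRS_SCALES["tfc"] + rng.normal(0, 0.25, n), 0.0, 13.0)
    tms = np.clip(2.56 - 0.25 * d * scores.CUHDRS_SCALES["tms"] + rng.normal(0, 1.5, n), 0.0, 124.0)
    sdmt = np.clip(54.47 + 0.30 * d * scores.CUHDRS_SCALES["sdmt"] + rng.normal(0, 3.5, n), 0.0, 140.0)
    swr = scores.solve_component(latent, {"tfc": tfc, "tms": tms, "sdmt": sdmt}, "swr")

    bad = (swr < 0.0) | (swr > 160.0)
    if bad.any():
        swr = np.clip(swr, 0.0, 160.0)
        sdmt = np.where(bad,
                        scores.solve_component(latent, {"tfc": tfc, "tms": tms, "swr": swr}, "sdmt"),
                        sdmt)
        bad2 = (sdmt < 0.0) | (sdmt > 140.0)
        if bad2.any():
            sdmt = np.clip(sdmt, 0.0, 140.0)
            tms = np.where(bad2,
                           scores.solve_component(latent, {"tfc": tfc, "sdmt": sdmt, "swr": swr}, "tms"),
                           tms)
    return pd.DataFrame({"tfc": tfc, "tms": tms, "sdmt": sdmt, "swr": swr})


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Draw a full longitudinal cohort.

    Returns ``(visits, baseline, truth)``: long-format visit records, one
    baseline row per subject, and the ground-truth record (per-subject random
    effects and per-visit latent scores).  All randomness flows from
    ``config.seed``; identical configs give bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    truth_spec = config.effect_spec
    D = truth_spec.random_effect_cov()

    baseline = _simulate_baseline(config, rng)
    n = len(baseline)

    lo, hi = config.visits_per_subject
    n_visits = rng.integers(lo, hi + 1, size=n)
    age0 = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_range, size=n)
    w, V = np.linalg.eigh(D)
    b = rng.standard_normal((n, 2)) @ (V * np.sqrt(np.maximum(w, 0.0))).T

    rows = []
    for i in range(n):
        ages = age0[i] + config.visit_spacing_years * np.arange(n_visits[i])
        rows.append(pd.DataFrame({
            "subjid": baseline["subjid"].iloc[i],
            "row": i,
            "visit_age": np.round(ages, 4),
        }))
    visits = pd.concat(rows, ignore_index=True)

    base_rep = baseline.iloc[visits["row"].to_numpy()].reset_index(drop=True)
    mu = truth_spec.latent_mean(visits["visit_age"].to_numpy(), base_rep)
    b_rep = b[visits["row"].to_numpy()]
    age_c = visits["visit_age"].to_numpy() - REFERENCE_AGE
    eps = rng.normal(0.0, truth_spec.residual_sd, size=len(visits)) \
        if truth_spec.residual_sd > 0 else np.zeros(len(visits))
    latent = mu + b_rep[:, 0] + b_rep[:, 1] * age_c + eps

    comps = _split_components(latent, rng)
    visits = pd.concat([visits[["subjid", "visit_age"]], comps], axis=1)[VISIT_COLUMNS]

    # optional missingness in the health-behaviour block (baseline only)
    if config.missing_behavior_rate > 0:
        drop = rng.random(n) < config.missing_behavior_rate
        baseline.loc[drop, _BEHAVIOR_COLS] = np.nan

    truth = CohortTruth(
        config=config,
        subject_effects=pd.DataFrame({"subjid": baseline["subjid"], "b0": b[:, 0], "b1": b[:, 1]}),
        latent=pd.DataFrame({
            "subjid": visits["subjid"], "visit_age": visits["visit_age"],
            "latent_mean": mu, "latent_cuhdrs": latent}),
    )
    return visits, baseline, truth


# --------------------------------------------------------------------- io

class CohortSchemaError(ValueError):
    """Raised when a cohort file violates the long-format schema."""


#: single documented missing-value sentinel in cohort CSVs: the empty field
MISSING_SENTINEL = ""


def write_cohort(visits: pd.DataFrame, baseline: pd.DataFrame, path) -> tuple[Path, Path]:
    """Write ``visits.csv`` and ``baseline.csv`` under ``path`` (a directory).

    Missing values are encoded as empty fields.  Round-trips losslessly via
    :func:`read_cohort` for values and column order.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _validate(visits, VISIT_COLUMNS, "visits")
    _validate(baseline, BASELINE_COLUMNS, "baseline")
    vpath, bpath = path / "visits.csv", path / "baseline.csv"
    visits.to_csv(vpath, index=False, na_rep=MISSING_SENTINEL)
    baseline.to_csv(bpath, index=False, na_rep=MISSING_SENTINEL)
    return vpath, bpath


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    visits = pd.read_csv(path / "visits.csv", dtype={"subjid": "string"})
    baseline = pd.read_csv(path / "baseline.csv", dtype={"subjid": "string", "group": "string"})
    _validate(visits, VISIT_COLUMNS, "visits")
    _validate(baseline, BASELINE_COLUMNS, "baseline")
    for df, name in ((visits, "visits"), (baseline, "baseline")):
        missing_id = df["subjid"].isna() | (df["subjid"].astype("string").str.len() == 0)
        if missing_id.any():
            line = int(np.flatnonzero(missing_id.to_numpy())[0]) + 2  # +header +1-base
            raise CohortSchemaError(f"{name}.csv line {line}: missing participant id")
    if not np.issubdtype(visits["visit_age"].dtype, np.number):
        coerced = pd.to_numeric(visits["visit_age"], errors="coerce")
        bad = coerced.isna() & visits["visit_age"].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise CohortSchemaError(f"visits.csv line {line}: non-numeric visit_age")
        visits["visit_age"] = coerced
    visits["subjid"] = visits["subjid"].astype(str)
    baseline["subjid"] = baseline["subjid"].astype(str)
    baseline["group"] = baseline["group"].astype(str)
    return visits, baseline


def _validate(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{name} table is missing column(s): {', '.join(missing)}")
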