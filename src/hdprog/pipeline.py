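"""End-to-end pipeline: simulate -> score -> stage -> fit -> explain -> report.

Every stage writes plain CSV/JSON under the run directory so stages can be
inspected and re-run in isolation.  A manifest records the config hash, the
global seed and package versions; the same config and seed always produce
the same manifest hash and byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, explain, merf, scores, staging, synthetic_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "report"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class ExplainConfig:
    n_observations: int = 150       # visits explained (sampled from training rows)
    background_size: int = 100
    n_permutation_pairs: int = 16
    n_interaction_draws: int = 48
    interaction_pairs: tuple = (("age", "cag"), ("age", "isced"), ("age", "bmi"))
    pd_features: tuple = ("age", "cag", "isced", "bmi", "alcohol_units",
                          "tobacco", "rx_dep")
    cag_stratum_cut: float = 42.0
    make_plots: bool = False


@dataclass
class PipelineConfig:
    simulation: synthetic_cohort.SimulationConfig = field(
        default_factory=synthetic_cohort.SimulationConfig)
    staging_options: staging.StagingOptions = field(default_factory=staging.StagingOptions)
    merf_config: merf.MerfConfig = field(default_factory=merf.MerfConfig)
    explain_config: ExplainConfig = field(default_factory=ExplainConfig)
    decliner_convention: str = "signed"
    validation_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        # module seeds derive deterministically from the global seed
        ss = np.random.SeedSequence(self.seed)
        sim_seed, merf_seed, split_seed, shap_seed = \
            (int(s) % (2 ** 31) for s in ss.generate_state(4))
        self.simulation.seed = sim_seed
        self.merf_config.seed = merf_seed
        self._split_seed = split_seed
        self._shap_seed = shap_seed

    def to_dict(self) -> dict:
        d = {
            "simulation": self.simulation.to_dict(),
            "staging_options": dataclasses.asdict(self.staging_options),
            "merf_config": dataclasses.asdict(self.merf_config),
            "explain_config": dataclasses.asdict(self.explain_config),
            "decliner_convention": self.decliner_convention,
            "validation_frac": self.validation_frac,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        if "simulation" in kw:
            kw["simulation"] = synthetic_cohort.SimulationConfig.from_dict(kw["simulation"])
        if "staging_options" in kw:
            so = dict(kw["staging_options"])
            for key in ("core_columns", "behavior_columns", "comorbidity_columns"):
                if key in so:
                    so[key] = tuple(so[key])
            kw["staging_options"] = staging.StagingOptions(**so)
        if "merf_config" in kw:
            kw["merf_config"] = merf.MerfConfig(**kw["merf_config"])
        if "explain_config" in kw:
            ec = dict(kw["explain_config"])
            for key in ("interaction_pairs", "pd_features"):
                if key in ec:
                    ec[key] = tuple(tuple(x) if isinstance(x, list) else x for x in ec[key])
            kw["explain_config"] = ExplainConfig(**ec)
        return cls(**kw)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    log.error("stage %s: failed (%s)", name, exc)
                    raise PipelineError(name, str(exc)) from exc
                log.info("stage %s: done in %.2fs", name, timings[name])
        return _T()

    # 1. simulate ----------------------------------------------------------
    with _stage("simulate"):
        visits, baseline, truth = synthetic_cohort.simulate_cohort(config.simulation)
        synthetic_cohort.write_cohort(visits, baseline, out / "cohort")
        truth.subject_effects.to_csv(out / "truth_subject_effects.csv", index=False)

    carriers = baseline[baseline["group"] == "carrier"]
    controls = baseline[baseline["group"] == "control"]
    carrier_visits = visits[visits["subjid"].isin(carriers["subjid"])]
    control_visits = visits[visits["subjid"].isin(controls["subjid"])]

    # 2. staging -----------------------------------------------------------
    with _stage("staging"):
        if len(carriers) == 0:
            raise ValueError("no carriers simulated; nothing to stage")
        control_ok = controls.dropna(subset=list(config.staging_options.behavior_columns))
        fit = staging.fit_control_model(
            control_visits[control_visits["subjid"].isin(control_ok["subjid"])], control_ok)
        decisions, counts = staging.apply_flowchart(
            carrier_visits, carriers, fit, config.staging_options)
        decisions.to_csv(out / "staging.csv", index=False)
        _write_json(out / "flowchart.json", counts)
        retained = decisions.loc[decisions["presymptomatic"], "subjid"]
        if len(retained) == 0:
            raise ValueError("staging retained no presymptomatic carriers")

    cohort_b = carriers[carriers["subjid"].isin(retained)].reset_index(drop=True)
    cohort_v = carrier_visits[carrier_visits["subjid"].isin(retained)].reset_index(drop=True)

    # 3. decliner scores ---------------------------------------------------
    with _stage("score"):
        deltas = scores.subject_deltas(cohort_v)
        split = scores.classify_decliners(deltas, convention=config.decliner_convention)
        split.labels.to_csv(out / "decliners.csv", index=False)
        _write_json(out / "decliner_threshold.json",
                    {"threshold": split.threshold,
                     "mean_delta_per_year": float(np.nanmean(deltas["delta_per_year"]))})

    # 4. table one ---------------------------------------------------------
    with _stage("table_one"):
        comparisons = cohort_stats.build_table_one(cohort_v, cohort_b, split.labels)
        cohort_stats.table_one_frame(comparisons).to_csv(out / "table_one.csv", index=False)
        (out / "table_one.txt").write_text(cohort_stats.render_table_one(comparisons) + "\n")

    # 5. MERF --------------------------------------------------------------
    with _stage("merf"):
        X, y, subjects = merf.build_feature_matrix(cohort_v, cohort_b)
        train, test = merf.split_by_subject(subjects, config.validation_frac,
                                            seed=config._split_seed)
        model = merf.fit_merf(X[train], y[train], subjects[train], config.merf_config)
        metrics = {
            "train": merf.evaluate(model, X[train], y[train], subjects[train]),
            "validation": merf.evaluate(model, X[test], y[test], subjects[test])
            if test.any() else None,
            "sigma2": model.sigma2,
            "D": model.D.tolist(),
            "n_iterations": model.n_iterations,
            "gll_trace": model.gll_trace,
        }
        _write_json(out / "merf_metrics.json", metrics)
        merf.save_model(model, out / "merf_model.pkl")

    # 6. explain -----------------------------------------------------------
    with _stage("explain"):
        ec = config.explain_config
        rng = np.random.default_rng(config._shap_seed)
        Xtr = X[train].reset_index(drop=True)
        bg_idx = rng.choice(len(Xtr), size=min(ec.background_size, len(Xtr)), replace=False)
        obs_idx = rng.choice(len(Xtr), size=min(ec.n_observations, len(Xtr)), replace=False)
        background = Xtr.iloc[bg_idx]
        Xexp = Xtr.iloc[obs_idx]
        predict_fn = lambda A: merf.predict(model, A)  # population predictions only

        expl = explain.shap_values(predict_fn, Xexp, background,
                                   n_permutation_pairs=ec.n_permutation_pairs,
                                   seed=config._shap_seed)
        expl.to_long_frame().to_csv(out / "shap_values.csv", index=False)
        imp = explain.importance_ranking(expl)
        imp.to_csv(out / "shap_importance.csv", index=False)
        _write_json(out / "shap_summary.json",
                    {"base_value": expl.base_value,
                     "importance": dict(zip(imp["feature"], imp["mean_abs_shap"]))})

        inter = {}
        for (a, b) in ec.interaction_pairs:
            vals = explain.shap_interaction(predict_fn, Xexp, background, (a, b),
                                            n_draws=ec.n_interaction_draws,
                                            seed=config._shap_seed)
            inter[f"{a}*{b}"] = float(np.mean(np.abs(vals)))
        _write_json(out / "shap_interactions.json", inter)

        pd_rows = []
        for feat in ec.pd_features:
            curve = explain.partial_dependence(predict_fn, Xtr, feat)
            pd_rows.extend({"feature": feat, "stratum": "all", "grid": g, "pd": v}
                           for g, v in zip(curve.grid, curve.pd_values))
        cag_strata = np.where(Xtr["cag"] < ec.cag_stratum_cut,
                              f"cag<{ec.cag_stratum_cut:g}", f"cag>={ec.cag_stratum_cut:g}")
        age_by_cag = explain.partial_dependence(predict_fn, Xtr, "age", strata=cag_strata)
        for name, (g, v) in (age_by_cag.strata or {}).items():
            pd_rows.extend({"feature": "age", "stratum": name, "grid": gi, "pd": vi}
                           for gi, vi in zip(g, v))
        pd.DataFrame(pd_rows).to_csv(out / "partial_dependence.csv", index=False)
        if ec.make_plots:
            from . import plots
            plots.importance_bar(imp, out / "shap_importance.png")
            plots.pd_curves(pd.DataFrame(pd_rows), out / "partial_dependence.png")

    # 7. manifest + report -------------------------------------------------
    with _stage("report"):
        import sklearn
        import statsmodels
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {"hdprog": "0.1.0", "numpy": np.__version__,
                         "pandas": pd.__version__, "sklearn": sklearn.__version__,
                         "statsmodels": statsmodels.__version__},
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        _write_json(out / "manifest.json", manifest)
        _write_json(out / "timings.json", timings)
        (out / "report.txt").write_text(report(out))
    return out


# --------------------------------------------------------------------- report

_PLANTED_SIGNS = {
    # sign of the planted additive effect for factors large enough to recover
    "isced": +1, "tobacco": -1, "rx_dep": -1,
}


def report(run_dir) -> str:
    """Render a human-readable run summary from stage outputs.

    Byte-identical across calls on the same run directory; missing stage
    outputs are listed as absent rather than failing.
    """
    run = Path(run_dir)
    lines = ["HD progression factor analysis - run report",
             "=" * 46, ""]

    def _load_json(name):
        p = run / name
        return json.loads(p.read_text()) if p.exists() else None

    flow = _load_json("flowchart.json")
    if flow:
        lines.append("Cohort selection flowchart (carriers):")
        for k, v in flow.items():
            lines.append(f"  {k:>22}: {v}")
    else:
        lines.append("flowchart.json: absent")
    lines.append("")

    thr = _load_json("decliner_threshold.json")
    if thr:
        lines.append(f"Decliner threshold |mean dcUHDRS/yr| = {thr['threshold']:.4f} "
                     f"(mean change {thr['mean_delta_per_year']:.4f}/yr)")
    else:
        lines.append("decliner_threshold.json: absent")
    lines.append("")

    metrics = _load_json("merf_metrics.json")
    if metrics:
        tr = metrics["train"]
        lines.append(f"MERF: {metrics['n_iterations']} iterations, "
                     f"sigma2={metrics['sigma2']:.4f}")
        lines.append(f"  train      MAE={tr['mae']:.3f}  MSE={tr['mse']:.3f}")
        if metrics.get("validation"):
            va = metrics["validation"]
            lines.append(f"  validation MAE={va['mae']:.3f}  MSE={va['mse']:.3f}")
    else:
        lines.append("merf_metrics.json: absent")
    lines.append("")

    summ = _load_json("shap_summary.json")
    if summ:
        lines.append(f"SHAP base value (adjusted mean cUHDRS): {summ['base_value']:.2f}")
        lines.append("Importance ranking, mean(|shap|):")
        for feat, v in sorted(summ["importance"].items(), key=lambda kv: -kv[1]):
            lines.append(f"  {feat:>14}: {v:.3f}")
    else:
        lines.append("shap_summary.json: absent")
    lines.append("")

    inter = _load_json("shap_interactions.json")
    if inter:
        lines.append("Interaction strength, mean(|shap interaction|):")
        for k, v in sorted(inter.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {k:>14}: {v:.3f}")
        lines.append("")

    # ground-truth recovery: planted vs recovered effect direction
    pd_path = run / "partial_dependence.csv"
    truth_path = run / "truth_subject_effects.csv"
    if pd_path.exists() and truth_path.exists():
        pdf = pd.read_csv(pd_path)
        lines.append("Ground-truth recovery (planted vs fitted PD direction):")
        for feat, sign in _PLANTED_SIGNS.items():
            cur = pdf[(pdf["feature"] == feat) & (pdf["stratum"] == "all")]
            if len(cur) < 2:
                continue
            fitted = np.sign(cur["pd"].iloc[-1] - cur["pd"].iloc[0]) or 0
            ok = "ok" if fitted == sign else "MISMATCH"
            lines.append(f"  {feat:>14}: planted {sign:+d}, fitted {int(fitted):+d}  [{ok}]")
        lines.append("")

    return "\n".join(lines) + "\n"
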