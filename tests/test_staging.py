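"""Control-calibrated staging: mixed-model fit, prediction bound, flowchart."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hdprog import scores, staging, synthetic_cohort as sc


def _zero_effects():
    e = sc._default_covariate_effects()
    return {k: (16.0 if k == "alcohol_peak_units" else 0.0) for k in e}


def _controls(n, *, intercept=17.0, resid_sd=1.0, b0_sd=0.0, b1_sd=0.0,
              visits=(1, 3), seed=0):
    gt = sc.GroundTruth(baseline_level=intercept, control_age_slope=0.0,
                        covariate_effects=_zero_effects(),
                        random_intercept_sd=b0_sd, random_slope_sd=b1_sd,
                        intercept_slope_corr=0.0, residual_sd=resid_sd)
    cfg = sc.SimulationConfig(n_carriers=0, n_controls=n, visits_per_subject=visits,
                              effect_spec=gt, seed=seed)
    v, b, _ = sc.simulate_cohort(cfg)
    return v, b


class TestFitControlModel:
    def test_parameter_recovery_no_random_effects(self):
        v, b = _controls(500, intercept=17.0, resid_sd=1.0, seed=1)
        fit = staging.fit_control_model(v, b)
        # all covariate effects are zero, so the fitted mean must sit at the
        # generating level and the residual variance at its true value
        merged = scores.add_cuhdrs_column(v).merge(b, on="subjid")
        X, _ = staging._design(merged, merged["visit_age"].to_numpy(float),
                               fit.reference_age)
        assert 16.9 < float(np.mean(X @ fit.beta)) < 17.1
        assert 0.9 < fit.sigma2 < 1.1

    def test_single_visit_reduces_to_ols(self):
        v, b = _controls(300, visits=(1, 1), seed=2)
        fit = staging.fit_control_model(v, b, random_effects=False)
        merged = scores.add_cuhdrs_column(v).merge(b, on="subjid")
        X, names = staging._design(merged, merged["visit_age"].to_numpy(float),
                                   fit.reference_age)
        oracle = sm.OLS(merged["cuhdrs"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-6)
        assert np.allclose(fit.D, 0.0)

    def test_random_intercept_variance_recovery(self):
        v, b = _controls(500, b0_sd=2.0, resid_sd=1.0, visits=(2, 4), seed=3)
        fit = staging.fit_control_model(v, b)
        assert 3.2 < fit.D[0, 0] < 4.9

    def test_collinear_design_names_column(self):
        v, b = _controls(100, seed=4)
        b = b.copy()
        b["drugs"] = b["tobacco"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear.*(drugs|tobacco)"):
            staging.fit_control_model(v, b)

    def test_too_few_controls_rejected(self):
        v, b = _controls(10, seed=5)
        one = b["subjid"].iloc[[0]]
        with pytest.raises(ValueError, match="two controls"):
            staging.fit_control_model(v[v["subjid"].isin(one)], b[b["subjid"].isin(one)])


class TestPredictionLowerBound:
    @staticmethod
    def _fit_like(model, *, beta0=17.0, D=None, sigma2=1.0):
        beta = np.zeros(len(model.feature_names))
        beta[0] = beta0
        return staging.MixedModelFit(model.feature_names, beta,
                                     np.zeros((len(beta), len(beta))),
                                     D if D is not None else np.zeros((2, 2)),
                                     sigma2, model.reference_age)

    def test_closed_form_residual_only(self):
        v, b = _controls(50, seed=6)
        model = staging.fit_control_model(v, b, random_effects=False)
        f = self._fit_like(model)
        lb = staging.prediction_lower_bound(f, b.iloc[[0]], 45.0)
        assert lb[0] == pytest.approx(17.0 - 1.959964, abs=1e-6)

    def test_closed_form_with_intercept_variance(self):
        v, b = _controls(50, seed=6)
        model = staging.fit_control_model(v, b, random_effects=False)
        f = self._fit_like(model, D=np.diag([1.0, 0.0]))
        for age in (20.0, 40.0, 70.0):
            lb = staging.prediction_lower_bound(f, b.iloc[[0]], age)
            assert lb[0] == pytest.approx(17.0 - 1.959964 * np.sqrt(2.0), abs=1e-6)

    def test_monotone_in_residual_variance(self):
        v, b = _controls(50, seed=6)
        model = staging.fit_control_model(v, b, random_effects=False)
        lows = [staging.prediction_lower_bound(self._fit_like(model, sigma2=s2),
                                               b.iloc[[0]], 45.0)[0]
                for s2 in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b_ for a, b_ in zip(lows, lows[1:]))

    def test_bound_below_fitted_values_at_negligible_noise(self):
        v, b = _controls(120, resid_sd=1e-4, seed=7)
        fit = staging.fit_control_model(v, b, random_effects=False)
        merged = scores.add_cuhdrs_column(v).merge(b, on="subjid")
        X, _ = staging._design(merged, merged["visit_age"].to_numpy(float),
                               fit.reference_age)
        lb = staging.prediction_lower_bound(
            fit, merged, merged["visit_age"].to_numpy(float))
        # the bound sits strictly below the model surface (its variance is
        # positive) and below nearly every observation
        assert (X @ fit.beta > lb).all()
        assert float(np.mean(merged["cuhdrs"].to_numpy() > lb)) >= 0.95

    def test_heldout_coverage_near_nominal(self):
        v, b = _controls(1300, b0_sd=0.8, b1_sd=0.02, resid_sd=0.5,
                         visits=(2, 5), seed=8)
        ids = b["subjid"].to_numpy()
        fit_set, ho_set = set(ids[:400]), set(ids[400:])
        fit = staging.fit_control_model(v[v["subjid"].isin(fit_set)],
                                        b[b["subjid"].isin(fit_set)])
        ho_b = b[b["subjid"].isin(ho_set)].reset_index(drop=True)
        first = (scores.add_cuhdrs_column(v[v["subjid"].isin(ho_set)])
                 .sort_values(["subjid", "visit_age"]).groupby("subjid").first())
        age = first["visit_age"].reindex(ho_b["subjid"]).to_numpy()
        score = first["cuhdrs"].reindex(ho_b["subjid"]).to_numpy()
        frac = float(np.mean(score < staging.prediction_lower_bound(fit, ho_b, age)))
        assert 0.01 <= frac <= 0.05


class TestFlowchart:
    @pytest.fixture()
    def staged(self, small_cohort):
        visits, baseline, _ = small_cohort
        controls = baseline[baseline["group"] == "control"]
        carriers = baseline[baseline["group"] == "carrier"]
        fit = staging.fit_control_model(
            visits[visits["subjid"].isin(controls["subjid"])], controls)
        return visits, carriers, fit

    def test_counts_sum_to_excluded(self, staged):
        visits, carriers, fit = staged
        decisions, counts = staging.apply_flowchart(
            visits[visits["subjid"].isin(carriers["subjid"])], carriers, fit)
        excluded = sum(v for k, v in counts.items() if k != "retained")
        assert excluded + counts["retained"] == len(carriers)
        assert (decisions["presymptomatic"] == (decisions["exclusion_reason"] == "")).all()

    def test_below_bound_excluded(self, staged):
        visits, carriers, fit = staged
        decisions, _ = staging.apply_flowchart(
            visits[visits["subjid"].isin(carriers["subjid"])], carriers, fit)
        below = decisions["baseline_cuhdrs"] <= decisions["lower_bound"]
        assert (decisions.loc[below, "exclusion_reason"] == "below_bound").all()
        assert (decisions.loc[below, "presymptomatic"] == False).all()  # noqa: E712

    def test_single_visit_excluded(self, staged):
        visits, carriers, fit = staged
        v = visits[visits["subjid"].isin(carriers["subjid"])]
        keep_one = v.sort_values(["subjid", "visit_age"]).groupby("subjid").head(1)
        decisions, counts = staging.apply_flowchart(keep_one, carriers, fit)
        # with one visit nobody has follow-up: all retained-so-far become single_visit
        assert counts["single_visit"] > 0
        assert counts["retained"] == 0

    def test_planted_offnorm_rapid_decliners_recovered(self, staged):
        visits, carriers, fit = staged
        v = visits[visits["subjid"].isin(carriers["subjid"])].copy()
        scored = scores.add_cuhdrs_column(v)
        retained_before, _ = staging.apply_flowchart(v, carriers, fit)
        ok_ids = retained_before.loc[retained_before["presymptomatic"], "subjid"]
        planted = list(ok_ids[:10])
        carriers2 = carriers.copy()
        carriers2.loc[carriers2["subjid"].isin(planted), "cag"] = 58
        # force a steep decline (< -2/yr) for the planted subjects
        for sid in planted:
            rows = v["subjid"] == sid
            ages = v.loc[rows, "visit_age"]
            base = scored.loc[rows, "cuhdrs"].iloc[0]
            target = base - 3.0 * (ages - ages.min())
            v.loc[rows, "swr"] = scores.solve_component(
                target.to_numpy(),
                {"tfc": v.loc[rows, "tfc"].to_numpy(),
                 "tms": v.loc[rows, "tms"].to_numpy(),
                 "sdmt": v.loc[rows, "sdmt"].to_numpy()}, "swr")
        # disable the advanced-age non-decline rule to isolate the planted feature
        opts = staging.StagingOptions(max_nondecline_slope=np.inf)
        decisions, counts = staging.apply_flowchart(v, carriers2, fit, opts)
        flagged = set(decisions.loc[decisions["exclusion_reason"] == "off_norm_trajectory",
                                    "subjid"])
        assert flagged == set(planted)

    def test_missing_behavior_excluded(self, staged):
        visits, carriers, fit = staged
        carriers2 = carriers.copy().reset_index(drop=True)
        carriers2.loc[:4, "bmi"] = np.nan
        decisions, counts = staging.apply_flowchart(
            visits[visits["subjid"].isin(carriers2["subjid"])], carriers2, fit)
        blanked = decisions.loc[decisions["subjid"].isin(carriers2["subjid"][:5])]
        assert (blanked["exclusion_reason"] == "missing_behavior_data").all()
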