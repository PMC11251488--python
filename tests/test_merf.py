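"""Mixed-effects random forest: updates, predictions, recovery properties."""

import numpy as np
import pandas as pd
import pytest

from hdprog import merf, synthetic_cohort as sc
from hdprog.merf import _variance_components


class TestUpdateEquations:
    def test_single_subject_shrinkage_fixed_point(self):
        # intercept-only design, f frozen at 0: b0 converges to
        # ybar * n D / (n D + sigma2)
        rng = np.random.default_rng(0)
        n, D0, s2 = 6, 0.7, 0.3
        y = rng.normal(2.0, 0.1, n)
        Z = np.column_stack([np.ones(n), np.zeros(n)])
        M = (Z.T @ Z)[None]
        z = (Z.T @ y)[None]
        rtr = np.array([y @ y])
        b, _, _ = _variance_components(rtr, z, M, np.array([n]),
                                       np.zeros((1, 2)), np.diag([D0, 1.0]), s2,
                                       max_sweeps=1, rtol=0.0)
        expected = y.mean() * n * D0 / (n * D0 + s2)
        assert b[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_variance_components_match_lmm_oracle(self):
        # pure linear-mixed data, no forest: the update sweeps converge to
        # the same variance components statsmodels MixedLM estimates by ML
        rng = np.random.default_rng(1)
        m, ni = 150, 5
        true_D, sig = np.diag([1.0, 0.01]), 0.5
        rows, subj, ages = [], [], []
        for i in range(m):
            a0 = rng.uniform(25, 60)
            a = a0 + np.arange(ni)
            b = rng.multivariate_normal([0, 0], true_D)
            yv = b[0] + b[1] * (a - 40) + rng.normal(0, sig, ni)
            rows.append(yv), subj.extend([i] * ni), ages.extend(a)
        y = np.concatenate(rows)
        ages = np.asarray(ages)
        Zfull = np.column_stack([np.ones(len(y)), ages - 40.0])
        groups = [np.flatnonzero(np.asarray(subj) == i) for i in range(m)]
        rtr = np.array([y[g] @ y[g] for g in groups])
        z = np.stack([Zfull[g].T @ y[g] for g in groups])
        M = np.stack([Zfull[g].T @ Zfull[g] for g in groups])
        n_i = np.full(m, ni)
        _, D, s2 = _variance_components(rtr, z, M, n_i, np.zeros((m, 2)),
                                        np.eye(2), 1.0, max_sweeps=20000, rtol=1e-12)
        import statsmodels.api as sm
        res = sm.MixedLM(y, np.ones((len(y), 1)), groups=np.asarray(subj),
                         exog_re=Zfull).fit(reml=False)
        assert D[0, 0] == pytest.approx(np.asarray(res.cov_re)[0, 0], rel=0.05, abs=0.05)
        assert s2 == pytest.approx(res.scale, rel=0.05)


class TestFitMerf:
    def test_seed_reproducibility(self, small_cohort):
        visits, baseline, _ = small_cohort
        carriers = baseline[baseline["group"] == "carrier"]
        X, y, s = merf.build_feature_matrix(
            visits[visits["subjid"].isin(carriers["subjid"])], carriers)
        cfg = merf.MerfConfig(n_trees=30, max_iter=4, seed=11)
        m1 = merf.fit_merf(X, y, s, cfg)
        m2 = merf.fit_merf(X, y, s, cfg)
        assert m1.gll_trace == m2.gll_trace
        np.testing.assert_array_equal(m1.b, m2.b)
        np.testing.assert_array_equal(m1.D, m2.D)
        np.testing.assert_array_equal(merf.predict(m1, X), merf.predict(m2, X))

    def test_gll_trace_length_matches_iterations(self, fitted_merf):
        model, *_ = fitted_merf
        assert model.n_iterations == len(model.gll_trace)
        assert model.sigma2 > 0
        assert np.linalg.eigvalsh(model.D).min() >= -1e-10

    def test_random_effects_centered(self, fitted_merf):
        model, *_ = fitted_merf
        b0 = model.b[:, 0]
        se = b0.std(ddof=1) / np.sqrt(len(b0))
        assert abs(b0.mean()) < 3 * se + 1e-9

    def test_variance_recovery_small(self):
        # scaled-down recovery run; the acceptance suite runs the full one
        gt = sc.GroundTruth(random_intercept_sd=1.0, random_slope_sd=0.1,
                            residual_sd=0.5)
        cfg = sc.SimulationConfig(n_carriers=150, n_controls=0,
                                  visits_per_subject=(5, 5), effect_spec=gt, seed=5)
        v, b, _ = sc.simulate_cohort(cfg)
        X, y, s = merf.build_feature_matrix(v, b)
        model = merf.fit_merf(X, y, s, merf.MerfConfig(n_trees=100, seed=3))
        assert 0.6 < model.D[0, 0] < 1.6
        assert 0.1 < model.sigma2 < 0.45

    def test_misaligned_inputs_rejected(self, fitted_merf):
        _, X, y, s = fitted_merf
        with pytest.raises(ValueError, match="align"):
            merf.fit_merf(X, y[:-1], s, merf.MerfConfig(n_trees=5, max_iter=1))


class TestPredict:
    def test_zero_random_effect_subject_matches_population(self, fitted_merf):
        model, X, _, s = fitted_merf
        model2 = merf.MerfModel(model.forest, model.feature_names, model.subject_ids,
                                np.zeros_like(model.b), model.D, model.sigma2,
                                model.gll_trace, model.config)
        np.testing.assert_allclose(merf.predict(model2, X, s),
                                   merf.predict(model2, X), atol=1e-12)

    def test_constant_response_predicts_constant(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(60, len(merf.FEATURES))),
                         columns=merf.FEATURES)
        X["age"] = rng.uniform(30, 50, 60)
        y = np.full(60, 4.2)
        s = np.repeat(np.arange(20), 3)
        model = merf.fit_merf(X, y, s, merf.MerfConfig(n_trees=10, max_iter=3, seed=0))
        np.testing.assert_allclose(merf.predict(model, X), 4.2, atol=1e-8)

    def test_unknown_subject_falls_back_flagged(self, fitted_merf):
        model, X, _, s = fitted_merf
        pred, flags = merf.predict(model, X.iloc[:3], ["nope"] * 3, return_flags=True)
        assert flags.all()
        np.testing.assert_allclose(pred, merf.predict(model, X.iloc[:3]), atol=1e-12)

    def test_subject_specific_beats_population_with_random_intercepts(self):
        gt = sc.GroundTruth(random_intercept_sd=1.0, residual_sd=0.3)
        cfg = sc.SimulationConfig(n_carriers=120, n_controls=0,
                                  visits_per_subject=(4, 4), effect_spec=gt, seed=8)
        v, b, _ = sc.simulate_cohort(cfg)
        X, y, s = merf.build_feature_matrix(v, b)
        model = merf.fit_merf(X, y, s, merf.MerfConfig(n_trees=60, max_iter=8, seed=1))
        pop = merf.evaluate(model, X, y)
        subj = merf.evaluate(model, X, y, s)
        assert subj["mae"] < pop["mae"]


class TestEvaluate:
    def test_perfect_predictions(self, fitted_merf):
        model, X, _, s = fitted_merf
        pred = merf.predict(model, X, s)
        m = merf.evaluate(model, X, pred, s)
        assert m == {"mae": 0.0, "mse": 0.0}

    def test_alternating_unit_errors(self):
        y = np.array([1.0, -1.0] * 5) + 3.0
        err = y - 3.0
        assert float(np.mean(np.abs(err))) == 1.0 and float(np.mean(err ** 2)) == 1.0

    def test_empty_partition_rejected(self, fitted_merf):
        model, X, *_ = fitted_merf
        with pytest.raises(ValueError, match="empty"):
            merf.evaluate(model, X.iloc[:0], np.array([]))

    def test_training_error_below_validation(self, fitted_merf):
        model, X, y, s = fitted_merf
        train, test = merf.split_by_subject(s, 0.2, seed=3)
        # refit on the training part only so validation is genuinely held out
        m2 = merf.fit_merf(X[train], y[train], s[train],
                           merf.MerfConfig(n_trees=60, max_iter=6, seed=3))
        tr = merf.evaluate(m2, X[train], y[train], s[train])
        va = merf.evaluate(m2, X[test], y[test], s[test])
        assert tr["mae"] < va["mae"]


def test_split_by_subject_never_splits_visits():
    s = np.repeat([f"P{i}" for i in range(50)], 3)
    train, test = merf.split_by_subject(s, 0.2, seed=0)
    frame = pd.DataFrame({"s": s, "test": test})
    assert (frame.groupby("s")["test"].nunique() == 1).all()
    assert abs(test.sum() / len(s) - 0.2) < 0.05


def test_model_round_trips_through_archive(fitted_merf, tmp_path):
    model, X, *_ = fitted_merf
    merf.save_model(model, tmp_path / "m.pkl")
    loaded = merf.load_model(tmp_path / "m.pkl")
    np.testing.assert_array_equal(merf.predict(loaded, X), merf.predict(model, X))
    assert loaded.gll_trace == model.gll_trace
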