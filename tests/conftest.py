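import numpy as np
import pytest

from hdprog import merf, synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, small enough for fast tests."""
    cfg = sc.SimulationConfig(n_carriers=150, n_controls=120, seed=42)
    visits, baseline, truth = sc.simulate_cohort(cfg)
    return visits, baseline, truth


@pytest.fixture(scope="session")
def fitted_merf(small_cohort):
    """A MERF fitted on the carrier visits of the small cohort."""
    visits, baseline, _ = small_cohort
    carriers = baseline[baseline["group"] == "carrier"]
    X, y, subjects = merf.build_feature_matrix(
        visits[visits["subjid"].isin(carriers["subjid"])], carriers)
    model = merf.fit_merf(X, y, subjects, merf.MerfConfig(n_trees=60, max_iter=8, seed=7))
    return model, X, y, subjects


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
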