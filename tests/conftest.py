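import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cariesflow as cf
from cariesflow.state import CATEGORIES

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_model() -> cf.CariesModel:
    return cf.CariesModel()


@pytest.fixture(scope="session")
def calibration_result(default_model):
    """Progression rates fitted to the reference projections (run once)."""
    return default_model.fit(seed=11, n_starts=6, max_evals=2500)


@pytest.fixture(scope="session")
def calibrated_model(calibration_result):
    return calibration_result.fitted_model()


@pytest.fixture(scope="session")
def scenario_runs(calibrated_model):
    """All three scenario trajectories under the calibrated model."""
    return {
        name: calibrated_model.simulate(name)
        for name in ("base_case", "ssb_tax", "aggressive")
    }


def state_from_category_millions(values: dict, year: float = 2010.0,
                                 treated_fraction: float = 0.09) -> cf.StockState:
    """Build a stock state with given per-category totals in millions."""
    total = sum(values.values()) * 1e6
    shares = {c: values[c] / sum(values.values()) for c in CATEGORIES}
    return cf.build_initial_state(
        total=total, category_shares=shares,
        treated_fraction=treated_fraction, year=year,
    )


@pytest.fixture
def category_state_builder():
    return state_from_category_millions


@pytest.fixture
def quiescent_model() -> cf.CariesModel:
    """A model in which every flow is switched off (constant-state oracle)."""
    inputs = cf.build_population_trajectory(
        {2010: 1.0e6, 2040: 1.0e6}, mortality_config={"mortality_35plus": 0.0}
    )
    care = cf.CareParams(treated_to_untreated=np.zeros((4, 2)))
    uptake = cf.UptakeParams(base_uptake={c: 0.0 for c in CATEGORIES})
    demo = cf.DemographyParams(aging_rate=0.0, mortality_35plus=0.0)
    return cf.CariesModel(
        inputs=inputs,
        rates=cf.ProgressionRates(0.0, 0.0, 0.0),
        care=care,
        uptake=uptake,
        demography=demo,
        initial_state=cf.build_initial_state(total=1.0e6, year=2010),
    )
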