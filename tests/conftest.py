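import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import strokecea as sc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_config() -> sc.RunConfig:
    """The full base-case configuration."""
    return sc.paper_fixture()


@pytest.fixture(scope="session")
def life_table(fixture_config) -> sc.LifeTable:
    return fixture_config.resolve_life_table()


@pytest.fixture(scope="session")
def stand_in_params(fixture_config, life_table) -> sc.CalibratedParams:
    """Transition parameters calibrated to the packaged stand-in targets."""
    return fixture_config.resolve_calibrated_params(life_table)


@pytest.fixture(scope="session")
def base_result(fixture_config, life_table, stand_in_params) -> sc.CEAResult:
    return sc.run_cea(
        fixture_config, life_table=life_table, calibrated=stand_in_params
    )


@pytest.fixture()
def fixed_params_config(fixture_config) -> sc.RunConfig:
    """Config with calibration short-circuited to fixed plausible parameters.

    Keeps tests that only exercise costing/CEA arithmetic independent of the
    calibration stage (and fast).
    """
    cfg = fixture_config.model_copy(deep=True)
    cfg.calibration.params = {
        "rr_mort_mrs02": 2.0,
        "rr_mort_mrs35": 5.0,
        "p_recover_monthly": 0.01,
        "p_worsen_monthly": 0.0,
    }
    return cfg


def random_schedule(rng: np.random.Generator, n_cycles: int = 57, start_month: int = 3):
    """Random valid transition schedule: dirichlet living rows, absorbing death."""
    mats = np.empty((n_cycles, 3, 3))
    mats[:, 0, :] = rng.dirichlet(np.ones(3), size=n_cycles)
    mats[:, 1, :] = rng.dirichlet(np.ones(3), size=n_cycles)
    mats[:, 2, :] = [0.0, 0.0, 1.0]
    months = np.arange(start_month + 1, start_month + n_cycles + 1)
    return sc.TransitionSchedule(matrices=mats, months=months)


def random_distribution(rng: np.random.Generator) -> sc.MRSDistribution:
    p = rng.dirichlet(np.ones(3))
    return sc.MRSDistribution(*p)
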