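import numpy as np
import pytest

from pinkfoot import (
    Climatology,
    Grids,
    UtilityConfig,
    WeightVector,
    calibrate_defaults,
    enumerate_models,
    optimize_policy,
)


@pytest.fixture(scope="session")
def specs():
    return enumerate_models()


@pytest.fixture(scope="session")
def params():
    """Default calibrated parameter set."""
    return calibrate_defaults()


@pytest.fixture(scope="session")
def climatology():
    return Climatology.discretized()


@pytest.fixture(scope="session")
def grids():
    return Grids.default()


@pytest.fixture(scope="session")
def utility_cfg():
    return UtilityConfig()


@pytest.fixture(scope="session")
def uniform_weights():
    return WeightVector.uniform()


@pytest.fixture(scope="session")
def default_policy(specs, params, uniform_weights, grids, utility_cfg, climatology):
    """The optimal policy at uniform model weights under package defaults."""
    return optimize_policy(
        specs, params, uniform_weights, grids, utility_cfg, climatology
    )


@pytest.fixture(scope="session")
def coarse_grids():
    """Small grids for oracle cross-checks that need a tractable state space."""
    return Grids(
        N_grid=np.arange(0.0, 151.0, 25.0),
        days_grid=np.array([6.0, 14.0]),
        action_grid=np.array([0.0, 10.0, 20.0]),
    )
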