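import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popreconstruct.simulate import (SimulationConfig, simulate_population,
                                     simulate_telemetry)
from popreconstruct.turkey import fit_turkey, load_ozarks_east

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("popreconstruct").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def zero_var_pop():
    """A zero-interannual-variation population with six telemetry years."""
    cfg = SimulationConfig(sigma_level=0.0, telemetry_design="6yr", seed=11)
    pop = simulate_population(cfg)
    return pop, simulate_telemetry(pop)


@pytest.fixture(scope="session")
def low_var_pop():
    cfg = SimulationConfig(sigma_level=0.1, telemetry_design="6yr", seed=3)
    pop = simulate_population(cfg)
    return pop, simulate_telemetry(pop)


@pytest.fixture(scope="session")
def turkey_dataset():
    return load_ozarks_east()


@pytest.fixture(scope="session")
def turkey_fit(turkey_dataset):
    """The selected turkey model fitted once for the whole session."""
    return fit_turkey(turkey_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
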