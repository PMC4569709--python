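import numpy as np
import pytest

from codaclans import DemographyParams, Scenario
from codaclans.experiments import initialize_run


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_pop():
    """Factory for small, seeded populations ready for stepping."""

    def make(n0=120, abm_id=1, seed=0, **params):
        scenario = Scenario.from_abm_id(abm_id)
        pop = initialize_run(scenario, DemographyParams(n0=n0, **params), np.random.default_rng(seed))
        return pop, scenario

    return make
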