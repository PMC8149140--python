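import numpy as np
import pytest

from fishtroph.simulate import default_study_configs, simulate_study


@pytest.fixture(scope="session")
def study():
    """One simulated four-population study shared across tests."""
    return simulate_study(seed=7)


@pytest.fixture(scope="session")
def configs():
    return {c.population_id: c for c in default_study_configs()}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
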