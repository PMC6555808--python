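import numpy as np
import pytest

from sleepwake import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated subjects with defaults; shared across tests."""
    return generate_cohort(SimulationConfig(n_subjects=6, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
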