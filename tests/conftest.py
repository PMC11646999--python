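import numpy as np
import pytest

from ctdx import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A moderate default-parameter synthetic cohort shared across tests."""
    return simulate_cohort(GeneratorConfig(n_patients=600, seed=20240601))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
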