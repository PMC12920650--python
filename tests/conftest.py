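import numpy as np
import pytest

from longrrm.simulate import default_kg, default_ki


@pytest.fixture(scope="session")
def printed_kg():
    """Genetic coefficient covariance rebuilt from the published estimates."""
    return default_kg()


@pytest.fixture(scope="session")
def printed_ki():
    return default_ki()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small simulated cohort (N=80) for REML-level tests."""
    from helpers import make_cohort

    return make_cohort(n=80, m=400, seed=11)
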