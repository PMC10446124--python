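import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import measerr as me

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def linear_base():
    return me.LinearScenario()


@pytest.fixture(scope="session")
def logistic_base():
    return me.LogisticScenario()


@pytest.fixture(scope="session")
def linear_data(linear_base):
    """One fixed dataset from the linear base design (n=500, k=3)."""
    return me.generate_linear(linear_base, seed=42)


@pytest.fixture(scope="session")
def logistic_data():
    """One fixed dataset from the logistic design at n=800, k=2."""
    return me.generate_logistic(me.LogisticScenario(n=800), seed=43)


@pytest.fixture(scope="session")
def linear_error_model(linear_data):
    return me.estimate_tau2_replicates(linear_data)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
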