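import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gesnn import SRMParams, default_grammar, make_synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grammar():
    return default_grammar()


@pytest.fixture
def params():
    """Study-default SRM parameters for a 3-class problem (t_end = 18 + 2)."""
    return SRMParams(tau=9.0, theta=1.0, t_end=20.0, dt=0.01, decision_start=10.0)


@pytest.fixture
def blobs2():
    """High-separation 2-class, 2-feature fixture."""
    return make_synthetic(40, 2, 2, separation=8.0, seed=0)


def random_topology_values(rng, n_inputs):
    """Random 2-decimal weights/delays for round-trip style tests."""
    weight = round(float(rng.uniform(-999.99, 999.99)), 2)
    delay = round(float(rng.uniform(0.01, 19.99)), 2)
    return weight, delay
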