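import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230419)


@pytest.fixture
def alpha_monomer(rng):
    """A fixed random 171 bp monomer (alpha-satellite-like length)."""
    from tandemsat import simulate

    return simulate.random_dna(171, rng)
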