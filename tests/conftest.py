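import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150501)


@pytest.fixture
def balanced_newick():
    """Hand-checkable 4-tip ultrametric tree of height 10 Myr."""
    return "((A:3,B:3):7,(C:5,D:5):5);"
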