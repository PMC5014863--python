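import numpy as np
import pytest

from synprune.networks import NetworkSpec, build_single_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A desk-top-sized network: 80 input, 80 exc, 20 inh."""
    return NetworkSpec(scale=0.05)


@pytest.fixture
def tiny_net(tiny_spec):
    return build_single_population(tiny_spec, np.random.default_rng(7))
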