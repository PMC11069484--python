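import numpy as np
import pytest
from hypothesis import settings

from pfokinetics import ReactionParameters

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def all_ones():
    """Factory for the reference parameter set k1 = k-1 = k2 = e0 = 1."""

    def make(s0=0.1, c0=0.0):
        return ReactionParameters(1.0, 1.0, 1.0, 1.0, s0, c0)

    return make


def draw_params(rng, s0_fraction=0.25, low=0.1, high=10.0):
    """Random positive rate constants (log-uniform) with s0 tied to K."""
    k1, km1, k2, e0 = np.exp(rng.uniform(np.log(low), np.log(high), size=4))
    s0 = s0_fraction * k2 / k1
    return ReactionParameters(k1, km1, k2, e0, s0)
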