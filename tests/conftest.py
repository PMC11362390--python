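import numpy as np
import pytest

from lsci.phantom import FlowPhantom


def make_uniform_phantom(x: float, n: int = 128, exposure: float = 5.0) -> FlowPhantom:
    """Uniform-flow phantom with T/tau_c = x everywhere (x = 0 -> static)."""
    tau = np.full((n, n), np.inf if x == 0 else exposure / x)
    zone = np.full((n, n), "well")
    return FlowPhantom(tau_map=tau, zone_map=zone, pixel_size=0.02, exposure=exposure)


@pytest.fixture
def uniform_phantom():
    return make_uniform_phantom
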