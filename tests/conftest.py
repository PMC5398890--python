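import numpy as np
import pytest

from glicgate import build_concerted_scheme, build_default_scheme
from glicgate.sensors import DEFAULT_SENSORS
from glicgate.simulate import StoppedFlowProtocol


@pytest.fixture(scope="session")
def scheme():
    return build_default_scheme()


@pytest.fixture(scope="session")
def concerted_scheme():
    return build_concerted_scheme()


@pytest.fixture(scope="session")
def protocol():
    return StoppedFlowProtocol()


@pytest.fixture(scope="session")
def sensors():
    return DEFAULT_SENSORS


def multiexp_trace(protocol, offset, amplitudes, rates, noise_sd=0.0, seed=0):
    """Synthetic normalized stopped-flow trace from the decay model itself."""
    from glicgate.simulate import StoppedFlowTrace

    t = protocol.time_grid()
    y = np.full(t.shape, float(offset))
    for a, k in zip(amplitudes, rates):
        y = y + a * np.exp(-k * t)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return StoppedFlowTrace(time=t, intensity=y, meta={"synthetic": True})
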