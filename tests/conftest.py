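import numpy as np
import pytest

from ktzlog.model import ModelParams, State


@pytest.fixture(scope="session")
def chaotic_params():
    """Fast-subsystem parameters on the strange attractor."""
    return ModelParams(K=0.89, T=0.009)


@pytest.fixture(scope="session")
def slow_base():
    """Reference slow-subsystem parameter set for phase studies."""
    return ModelParams(K=0.6, T=0.275, delta=0.001, lam=0.001, xR=-0.2)


@pytest.fixture(scope="session")
def unit_init():
    return State(1.0, 1.0, 0.0)
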