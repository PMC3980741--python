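import warnings

import numpy as np
import pytest

import macroquant as mq
from macroquant.errors import ResolutionWarning

warnings.simplefilter("ignore", ResolutionWarning)


@pytest.fixture(scope="session")
def params():
    """Unit macroquantum constants with S0 = 1 (D = 1/2, m = 1)."""
    return mq.MacroParams(D=0.5, m=1.0)


@pytest.fixture(scope="session")
def grid_1d():
    return mq.GridSpec(extent=(16.0,), points=(400,))


@pytest.fixture(scope="session")
def oscillator(params, grid_1d):
    """Unit-frequency harmonic trap centered in the box."""
    return mq.harmonic_potential(params, 1.0)


@pytest.fixture(scope="session")
def oscillator_states(params, grid_1d, oscillator):
    return mq.stationary_states(oscillator, grid_1d, params, n_states=5)


def l2_density_distance(P1, P2):
    return float(np.sqrt(np.sum((P1 - P2) ** 2) / np.sum(P2**2)))
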