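import numpy as np
import pytest

from dmisort import FitnessParams, LinkageArchitecture, SimulationConfig


@pytest.fixture
def default_params():
    """Standard selection parameters: s = 0.001, epsilon = -0.2, codominant."""
    return FitnessParams.symmetric()


@pytest.fixture
def recessive_params():
    return FitnessParams.symmetric(dominance="recessive")


@pytest.fixture
def neutral_params():
    """No direct selection, no epistasis."""
    return FitnessParams.symmetric(s=0.0, epsilon=0.0)


@pytest.fixture
def goldilocks_config(default_params):
    """Adjacent ABAB, equidistant r = 0.1, codominant, symmetric contact."""
    return SimulationConfig(
        params=default_params,
        arch=LinkageArchitecture.equidistant("Adjacent ABAB", 0.1),
        N=5000,
        i_p=0.5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
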