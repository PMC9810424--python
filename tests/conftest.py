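import numpy as np
import pytest

from colonygames import EnvironmentParams, LearningParams


@pytest.fixture
def env_branching():
    """Environment in the branching regime (b1=23, w=0.25, beta=3, b2=-6)."""
    return EnvironmentParams(b1=23, b2=-6, w=0.25, beta=3)


@pytest.fixture
def env_rich():
    """Generous homeostatic environment (easy regulation)."""
    return EnvironmentParams(b1=28, b2=-6, w=0.3, beta=3)


@pytest.fixture
def env_zero_benefit():
    """Benefits identically zero: any effort is pure cost."""
    return EnvironmentParams(b1=0, b2=0, w=0.3, beta=3)


@pytest.fixture
def small_params():
    return LearningParams(n=5, N=20, T=50, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20230104)
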