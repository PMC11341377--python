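import numpy as np
import pytest

from qifks import SynapticKernel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exp_kernel():
    """Exponential synapse (q = 0)."""
    return SynapticKernel(q=0, tau=1.0)


@pytest.fixture
def alpha_kernel():
    """Alpha-function synapse (q = 1)."""
    return SynapticKernel(q=1, tau=0.3)
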