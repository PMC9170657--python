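import numpy as np
import pytest

from neuroksvr import FitConfig, TriangularThetaKernel


@pytest.fixture
def theta_kernel():
    """The standard theta-sequence kernel (N=10000, S=10, f=0.01)."""
    return TriangularThetaKernel(n_neurons=10_000, seq_length=10, sparseness=0.01)


@pytest.fixture
def theta_config(theta_kernel):
    return FitConfig(theta_kernel, cutoff_dimension=300)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
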