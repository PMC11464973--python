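import numpy as np
import pytest
from hypothesis import settings

from y90dose.kernels import load_default_kernel

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water_kernel():
    return load_default_kernel()


@pytest.fixture(scope="session")
def tissue_kernel():
    return load_default_kernel(1.04)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
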