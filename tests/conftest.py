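import numpy as np
import pytest

from mrsdss.basis import build_default_basis
from mrsdss.core import AcquisitionParams
from mrsdss.synthesize import default_class_params


@pytest.fixture(scope="session")
def basis():
    return build_default_basis()


@pytest.fixture(scope="session")
def class_params(basis):
    return default_class_params(basis)


@pytest.fixture(scope="session")
def fast_params():
    """Reduced acquisition for tests that need many fits."""
    return AcquisitionParams(n_points=512, bandwidth_hz=1024.0)


@pytest.fixture(scope="session")
def default_params():
    return AcquisitionParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
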