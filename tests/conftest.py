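import numpy as np
import pytest

from ethanolmrs.quantify import VoxelComposition
from ethanolmrs.spectral_model import AcquisitionParams, default_basis


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def basis(params):
    return default_basis(params)


@pytest.fixture
def occipital_comp():
    # V1 occipital, first cycle: wc 72.3%
    return VoxelComposition(0.46, 0.50, 0.04, 15.6, "occipital_cortex")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
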