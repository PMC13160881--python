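import numpy as np
import pytest

from hbmfit.phantom import build_paper_phantom
from hbmfit.signal_models import dki_scheme, fexi_scheme, get_model


@pytest.fixture(scope="session")
def dki():
    return get_model("dki")


@pytest.fixture(scope="session")
def axr():
    return get_model("axr")


@pytest.fixture(scope="session")
def small_dki_phantom():
    """12x12 DKI phantom (69/75 voxels) at the default SNR."""
    return build_paper_phantom("dki", seed=7, shape=(12, 12))


@pytest.fixture(scope="session")
def small_fexi_phantom():
    return build_paper_phantom("fexi", seed=7, shape=(12, 12))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
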