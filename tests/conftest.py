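import numpy as np
import pytest
from hypothesis import settings

from oximap.optics import SkinParams, default_chromophore_table
from oximap.phantom import make_sensitivity_fixture
from oximap.preprocess import DEFAULT_TARGET_BANDS

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return default_chromophore_table()


@pytest.fixture(scope="session")
def bands():
    return np.array(DEFAULT_TARGET_BANDS)


@pytest.fixture(scope="session")
def sens_clean():
    """Cross-talk-free sensitivity fixture (collapsed matrix is diagonal)."""
    return make_sensitivity_fixture(crosstalk=0.0)


@pytest.fixture(scope="session")
def sens_crosstalk():
    return make_sensitivity_fixture(crosstalk=0.2)


@pytest.fixture
def skin_params():
    return SkinParams(B=2e-3, SO2=0.8, M=0.02, d_e_um=90.0)
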