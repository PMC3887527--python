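import pytest

from triplecross.model import CHROMOSOME_V_MARKERS, RecombinationParams


@pytest.fixture
def markers():
    return CHROMOSOME_V_MARKERS


@pytest.fixture
def oocyte_params():
    """Published oogenesis parameters: 13.1% / 36.2%, complete interference."""
    return RecombinationParams(p_L=0.131, p_R=0.362, interference=100.0)


@pytest.fixture
def sperm_params():
    """Published spermatogenesis parameters: 15.0% / 37.8%, 69.2% interference."""
    return RecombinationParams(p_L=0.150, p_R=0.378, interference=69.2)
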