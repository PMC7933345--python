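import numpy as np
import pytest

from hdclvr import Architecture, DriveParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hdclvr_params():
    """Headline drive: 1 homing gRNA, 4 cleave-and-rescue gRNAs, daisyfield 30."""
    return DriveParams(
        architecture=Architecture.HDCLVR,
        n_grnas_homing=1,
        n_grnas_clvr=4,
        P_n=0.02,
        daisyfield_size=30,
    )


@pytest.fixture
def homing_clvr_params():
    return DriveParams(
        architecture=Architecture.HOMING_CLVR,
        n_grnas_homing=1,
        n_grnas_clvr=4,
        P_n=0.02,
        daisyfield_size=0,
    )
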