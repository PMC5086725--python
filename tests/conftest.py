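import numpy as np
import pytest

from evacsi import (
    CommunityLayout,
    EvacuationState,
    KernelParams,
    LocationParams,
    ModelParameters,
    WarningSchedule,
    params_table1,
)


@pytest.fixture
def table1():
    return params_table1()


@pytest.fixture
def no_forcing_params():
    """One isolated logistic group: no between-community, geographic or
    warning influence (alpha = a2 = 0, w = 0)."""
    return ModelParameters(
        gamma=(0.5, 0.3, 0.2),
        kernel=KernelParams(lambda0=0.25, alpha=0.0, sigma=1.0),
        location=LocationParams(a1=1.0, b1=0.1, a2=0.0, b2=0.01),
        warning=WarningSchedule(breakpoints=(0.0,), pieces=((0.0, 0.0),)),
    )


@pytest.fixture
def single_group_layout():
    """One community whose population sits entirely in type 1."""
    return CommunityLayout(
        dist_to_source=np.array([1.0]),
        pairwise=np.zeros((1, 1)),
        populations=np.array([[100.0], [0.0], [0.0]]),
    )


@pytest.fixture
def single_group_state():
    return EvacuationState(t=0.0, I=np.array([[20.0], [0.0], [0.0]]))
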