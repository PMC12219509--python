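import numpy as np
import pytest

from memfold import DENATURATION_CONTEXT, ROOM_CONTEXT, SIMULATION_CONTEXT


@pytest.fixture
def room_ctx():
    """Experimental room temperature (24.5 C)."""
    return ROOM_CONTEXT


@pytest.fixture
def sim_ctx():
    """MD thermostat temperature (310 K)."""
    return SIMULATION_CONTEXT


@pytest.fixture
def denat_ctx():
    """OmpLA titration incubation temperature (37 C)."""
    return DENATURATION_CONTEXT


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
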