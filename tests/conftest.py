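import numpy as np
import pytest

from paccsim import Parameters, PopulationState, TherapySchedule


@pytest.fixture
def params():
    return Parameters()


@pytest.fixture
def init10():
    return PopulationState(x1=10, x2=0, v=0.0, t=0.0)


@pytest.fixture
def continuous08():
    return TherapySchedule(kind="continuous", dose=0.8, start=200.0, stop=800.0)


@pytest.fixture
def no_therapy():
    return TherapySchedule(kind="none")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
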