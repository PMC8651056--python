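import pytest

from boolmc.engine import SimulationSettings
from boolmc.fixtures import make_toy
from boolmc.model import InitialStateDistribution


@pytest.fixture
def toggle():
    return make_toy("toggle_switch")


@pytest.fixture
def single_node_21():
    """Two-state CTMC with k_up=2, k_down=1: stationary P(on) = 2/3."""
    return make_toy("single_node", k_up=2.0, k_down=1.0)


@pytest.fixture
def repressilator3():
    return make_toy("repressilator", m=3)


@pytest.fixture
def start_off():
    """Initial distribution putting the single node N at 0 with certainty."""
    return InitialStateDistribution.degenerate({"N": 0})


@pytest.fixture
def fast_settings():
    """Small ensemble for structural (non-statistical) checks."""
    return SimulationSettings(sample_count=200, max_time=5.0, time_points=20, seed=11)
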