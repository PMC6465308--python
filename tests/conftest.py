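import numpy as np
import pytest

from tpshoot.synthetic import EngineState, PotentialSpec, ToyEngine
from tpshoot.tps import interval_state


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def double_well_2d():
    return PotentialSpec(kind="double_well_2d", barrier_height=5.0,
                         well_separation=2.0, orthogonal_stiffness=5.0)


@pytest.fixture
def toy_engine(double_well_2d):
    return ToyEngine(double_well_2d, dt=0.01, friction=1.0, temperature=1.0)


@pytest.fixture
def toy_states():
    state_a = interval_state("A", 0, -np.inf, -0.75)
    state_b = interval_state("B", 0, 0.75, np.inf)
    return state_a, state_b


@pytest.fixture
def saddle_point():
    return EngineState([0.0, 0.0], [0.0, 0.0])


def axis_angle_matrix(axis, angle_deg):
    """Independent axis-angle construction used as test oracle:
    R = cos(phi) I + (1 - cos(phi)) e e^T + sin(phi) [e]_x."""
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e)
    phi = np.deg2rad(angle_deg)
    ex = np.array([[0, -e[2], e[1]], [e[2], 0, -e[0]], [-e[1], e[0], 0]], dtype=float)
    return np.cos(phi) * np.eye(3) + (1 - np.cos(phi)) * np.outer(e, e) + np.sin(phi) * ex
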