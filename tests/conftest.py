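import numpy as np
import pytest

from intuifluids.fixtures import toy_scene
from intuifluids.scenes import Scene, Divider
from intuifluids.geometry2d import Circle, Point2


@pytest.fixture(scope="session")
def tall_scene():
    """Obstacle-free, very tall scene so free fall never reaches the floor
    within a few seconds (used for terminal-velocity checks)."""
    return Scene(width=1.0, height=40.0, obstacles=[],
                 liquid_start=Circle(Point2(0.5, 39.5), 0.074),
                 receptacle=Divider(0.5))


@pytest.fixture(scope="session")
def ledge_scene():
    return toy_scene("ledge")


@pytest.fixture(scope="session")
def wedge_scene():
    return toy_scene("wedge_center")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
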