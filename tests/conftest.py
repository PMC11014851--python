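import numpy as np
import pytest

from lving import Calibration, MassFrame
from lving.synthetic import SyntheticScene, _initial_density


@pytest.fixture
def cal():
    return Calibration(pixel_size=0.25, frame_interval=1.0)


@pytest.fixture
def textured_frame(cal):
    """A cell-like density image: smooth disk plus granular contrast."""
    scene = SyntheticScene(shape=(128, 128), pixel_size=cal.pixel_size, seed=7)
    density = _initial_density(scene, np.random.default_rng(7))
    return MassFrame(density, 0.0, cal)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
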