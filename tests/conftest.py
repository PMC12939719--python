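import numpy as np
import pytest

from salmonhsi.hypercube import CalibrationFrames, Hypercube
from salmonhsi.segmentation import SpoilageLabels
from salmonhsi import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def kinetics():
    """Calibrated default kinetics, shared across the session."""
    return synthetic.default_kinetics()


@pytest.fixture()
def small_cube(rng):
    """A 6x7x5 calibrated cube with random reflectance in [5, 40] percent."""
    data = rng.uniform(5.0, 40.0, size=(6, 7, 5))
    return Hypercube(data, np.linspace(400, 1000, 5), "toy", "dorsal",
                     calibrated=True)


@pytest.fixture()
def reference_frames():
    """Flat spectrum references broadcastable over any cube with 5 bands."""
    white = np.full(5, 3000.0)
    dark = np.full(5, 100.0)
    return CalibrationFrames(white, dark)


@pytest.fixture()
def fresh_labels():
    return SpoilageLabels(tvbn=1.29, tvc=2.16, temperature_c=4, day=0)


@pytest.fixture()
def spoiled_labels():
    return SpoilageLabels(tvbn=55.67, tvc=6.91, temperature_c=4, day=11)
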