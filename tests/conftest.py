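import numpy as np
import pytest

from nervequant.ph import BUFFER_LADDER_PH, build_calibration
from nervequant.synth import forward_ratio_model, make_neuron_scene


@pytest.fixture(scope="session")
def neuron_scene():
    """One default neuron field reused across tests that only read it."""
    return make_neuron_scene(seed=42)


@pytest.fixture(scope="session")
def clean_ladder_points():
    """Noiseless (pH, ratio) pairs of the ten-buffer calibration ladder."""
    return [(p, forward_ratio_model(p)) for p in BUFFER_LADDER_PH]


@pytest.fixture(scope="session")
def clean_curve(clean_ladder_points):
    return build_calibration(clean_ladder_points)


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
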