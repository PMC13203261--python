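import numpy as np
import pytest

from nbguide import phantom
from nbguide.types import Box, Detection


@pytest.fixture(scope="session")
def default_scene():
    return phantom.make_scene(seed=0)


@pytest.fixture(scope="session")
def rendered(default_scene):
    """One rendered frame with its ground truth (shared, read-only)."""
    return phantom.render_frame(default_scene)


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale scene used by closed-loop tests (0.25 mm/px at 6 cm)."""
    return phantom.SceneParams(image_height_px=240, image_width_px=160)


def make_box(r0, c0, r1, c1):
    return Box(float(r0), float(c0), float(r1), float(c1))


def make_det(label, box, conf, mask=None):
    return Detection(label, Box(*box), conf, mask=mask)


@pytest.fixture
def boxes():
    return make_box


@pytest.fixture
def dets():
    return make_det
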