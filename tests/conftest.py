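import math

import numpy as np
import pytest

from mammometry.geometry import CalibrationSegment, Midline, PixelPoint


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rigid(p, theta, tx, ty, photo_id=None):
    """Apply a rotation + translation to a PixelPoint (test helper)."""
    c, s = math.cos(theta), math.sin(theta)
    return PixelPoint(
        x=c * p.x - s * p.y + tx,
        y=s * p.x + c * p.y + ty,
        photo_id=photo_id if photo_id is not None else p.photo_id,
    )


@pytest.fixture
def vertical_midline():
    return Midline(superior=PixelPoint(0.0, 0.0), inferior=PixelPoint(0.0, 100.0))


@pytest.fixture
def unit_calibration():
    # 100 px over 2 cm -> 50 px/cm
    return CalibrationSegment(PixelPoint(0.0, 0.0), PixelPoint(100.0, 0.0), 2.0)
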