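import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coccogate.masking import BinaryMask, ObjectImage

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def disk_mask(shape, center, radius, kind="object_tight"):
    yy, xx = np.indices(shape, dtype=float)
    return BinaryMask(
        np.hypot(yy - center[0], xx - center[1]) <= radius, kind
    )


def disk_image(shape=(48, 48), center=(24, 24), radius=10.0, value=200.0,
               background=0.0, pixel_area=0.33):
    yy, xx = np.indices(shape, dtype=float)
    px = np.full(shape, background, dtype=float)
    px[np.hypot(yy - center[0], xx - center[1]) <= radius] = value
    return ObjectImage(px, pixel_area, "disk")


@pytest.fixture
def bright_disk():
    return disk_image()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
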