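import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_disk_image(radius: float, size: int = 128, value: float = 255.0):
    """White disk on black background, centered; returns (image, center)."""
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2.0
    img[(yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2] = value
    return img, c


def make_disk_mask(radius: float, size: int = 128):
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


def circle_contour(radius: float, center: float, n: int = 100):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center + radius * np.sin(t), center + radius * np.cos(t)]
    )
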