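import numpy as np
import pytest

from endoquant import Image2D, ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return Image2D(rng.uniform(0, 100, (48, 48)))


def make_stack(arrays, axis="z", frame_interval=None, pixel_size=1.0, role="other"):
    slices = [Image2D(np.asarray(a, float), pixel_size, role) for a in arrays]
    return ImageStack(slices, axis, frame_interval)


@pytest.fixture
def make_image():
    def _make(pixels, pixel_size=1.0, role="other"):
        return Image2D(np.asarray(pixels, float), pixel_size, role)

    return _make
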