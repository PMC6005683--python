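"""Shared fixtures: small deterministic phantoms reused across test modules."""

import numpy as np
import pytest

from myofq import Image2D
from myofq.phantoms import (
    CrosswisePhantomSpec,
    LengthwisePhantomSpec,
    make_crosswise_phantom,
    make_lengthwise_phantom,
)


@pytest.fixture(scope="session")
def adult_lengthwise():
    """Adult-stage striation phantom: repeat 3.2 um, fibril width 1.0 um."""
    spec = LengthwisePhantomSpec(repeat_um=3.2, fibril_width_um=1.0, seed=1)
    return make_lengthwise_phantom(spec)


@pytest.fixture(scope="session")
def early_lengthwise():
    """Early-pupal striation phantom: repeat 2.0 um, fibril width 0.5 um."""
    spec = LengthwisePhantomSpec(repeat_um=2.0, fibril_width_um=0.5, seed=4)
    return make_lengthwise_phantom(spec)


@pytest.fixture(scope="session")
def small_crosswise():
    """100 disks of 1.0 um in a 1024^2 frame, separation 3x diameter."""
    spec = CrosswisePhantomSpec(
        disk_diameter_um=1.0, n_disks=100, shape_px=(1024, 1024), seed=7
    )
    return make_crosswise_phantom(spec)


@pytest.fixture()
def cosine_image():
    """64x64 pure horizontal cosine of period 16 px, offset to stay positive."""
    x = np.arange(64)
    pattern = 1.0 + np.cos(2 * np.pi * x / 16.0)
    return Image2D(np.tile(pattern, (64, 1)), pixel_size_um=0.05)


@pytest.fixture()
def stripe_image():
    """Horizontal stripes (50% duty) of period 20 px in a 128^2 frame."""
    y = np.arange(128)
    pattern = (y % 20 < 10).astype(float) * 10.0 + 1.0
    return Image2D(np.tile(pattern[:, None], (1, 128)), pixel_size_um=0.05)
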