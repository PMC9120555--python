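import numpy as np
import pytest

from boldpost.postproc import Bold4D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_bold(rng):
    """A small full-mask noise image for operator-level tests."""
    data = rng.standard_normal((8, 8, 6, 60)) + 100.0
    mask = np.ones((8, 8, 6), dtype=bool)
    return Bold4D(data=data, repetition_time=2.0, mask=mask, voxel_size=(3.0, 3.0, 3.0))


@pytest.fixture
def masked_bold(rng):
    """A noise image with an interior mask (edge voxels excluded)."""
    data = rng.standard_normal((10, 10, 8, 50)) + 50.0
    mask = np.zeros((10, 10, 8), dtype=bool)
    mask[2:-2, 2:-2, 2:-2] = True
    return Bold4D(data=data, repetition_time=2.0, mask=mask, voxel_size=(3.0, 3.0, 3.0))
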