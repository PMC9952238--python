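import numpy as np
import pytest

from cine2tag import ImageFrame, PhantomConfig, SegMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def square_8x8():
    """4x4 centred square in an 8x8 grid; the canonical small loss fixture."""
    m = np.zeros((8, 8), dtype=np.uint8)
    m[2:6, 2:6] = 1
    return m


@pytest.fixture
def small_phantom_config():
    return PhantomConfig(image_size=64, r_endo_ed=10.0, r_epi_ed=18.0, n_frames=5, noise_sd=0.0, seed=7)


@pytest.fixture
def phantom_pair(small_phantom_config):
    from cine2tag import generate_phantom_frame

    return generate_phantom_frame(small_phantom_config, 0)


@pytest.fixture
def uniform_image():
    return ImageFrame(np.ones((256, 256)))


@pytest.fixture
def empty_mask_256():
    return SegMask(np.zeros((256, 256), dtype=np.uint8))
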