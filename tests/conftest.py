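import numpy as np
import pytest

from nctquant import ChannelImage, MarkerSpec, SceneSpec, generate_scene


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def cn_scene():
    """Noise-free scene with planted C/N = 2 (nucleus 100, cytosol 200)."""
    spec = SceneSpec(
        n_cells=5,
        seed=3,
        markers=[MarkerSpec(name="m", nucleus_level=100, cytosol_level=200)],
    )
    channels, gt = generate_scene(spec)
    return spec, channels, gt


@pytest.fixture(scope="session")
def ring_scene():
    """Noise-free scene with a gapped envelope ring (gap fraction 0.25)."""
    spec = SceneSpec(
        n_cells=5,
        seed=7,
        image_shape=(300, 300),
        markers=[MarkerSpec(name="ring", ring_level=300, gap_fraction=0.25)],
    )
    channels, gt = generate_scene(spec)
    return spec, channels, gt


def make_image(pixels, pixel_size=1.0, name="test"):
    return ChannelImage(np.asarray(pixels, dtype=float), pixel_size, channel_name=name)
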