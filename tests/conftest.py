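import numpy as np
import pytest

from stapull import DetectionParams, Image2D, SceneSpec, simulate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_image(rng):
    """Flat Gaussian background, mean 100 SD 5, no structure."""
    return Image2D(rng.normal(100, 5, (64, 64)), pixel_size_um=0.1)


def psf_image(positions, amplitudes, shape=(64, 64), sigma=1.3, background=None, rng=None):
    """Noisy image with Gaussian peaks of given peak amplitudes at (x, y)."""
    if background is None:
        background = np.zeros(shape)
    img = background.astype(float).copy()
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (x, y), a in zip(positions, amplitudes):
        img += a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return Image2D(img, pixel_size_um=0.1)


@pytest.fixture()
def monomer_scene():
    """Sparse single-label scene with its ground truth."""
    spec = SceneSpec(
        fov_shape_px=(128, 128),
        n_frames=2,
        monomer_density_per_um2=0.05,
        oligomer_density_per_um2=0.0,
        seed=42,
    )
    return simulate_scene(spec)


@pytest.fixture()
def default_det():
    return DetectionParams()
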