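import numpy as np
import pytest

from oligocount.simulate import _pixel_integrated_psf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def render_spots(shape, spots, background=0.0, noise_sd=0.0, rng=None):
    """Render pixel-integrated Gaussian spots: spots = [(row, col, volume, sigma)]."""
    img = np.full(shape, float(background))
    yy = np.arange(shape[0], dtype=float)[:, None]
    xx = np.arange(shape[1], dtype=float)[None, :]
    for r0, c0, vol, sigma in spots:
        img += vol * _pixel_integrated_psf(r0, c0, sigma, yy, xx)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return img


@pytest.fixture()
def spot_renderer():
    return render_spots
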