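import numpy as np
import pytest

from desmomap.io import RenderedImage
from desmomap.pipeline import JunctionProfile


def two_gaussian_profile(
    centers=(-96.0, 96.0), sigma=20.0, spacing=4.0, halfwidth=200.0, amplitudes=(1.0, 1.0)
) -> JunctionProfile:
    """Analytic two-Gaussian cross-junction profile on a uniform grid."""
    x = np.arange(-halfwidth, halfwidth + spacing / 2, spacing)
    y = np.zeros_like(x)
    for c, a in zip(centers, amplitudes):
        y += a * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return JunctionProfile(positions=x, raw_intensity=y)


def stripe_image(
    separation=192.0, pixel_size=4.0, size_nm=1000.0, stripe_px=3, value=10.0
) -> RenderedImage:
    """Noise-free image of two uniform horizontal stripes at ±separation/2
    about the image centre."""
    n = int(size_nm / pixel_size)
    data = np.zeros((n, n), dtype=np.float32)
    c = size_nm / 2
    for off in (-separation / 2, separation / 2):
        row = int(round((c + off) / pixel_size))
        data[row - stripe_px // 2 : row + stripe_px // 2 + 1, :] = value
    return RenderedImage(data=data, pixel_size=pixel_size, origin=(0.0, 0.0))


@pytest.fixture
def gauss_pair():
    return two_gaussian_profile()
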