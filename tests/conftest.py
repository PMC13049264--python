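import numpy as np
import pytest


def make_smooth_image(n: int, seed: int, sigma: float = 3.0) -> np.ndarray:
    """Deterministic band-limited complex test image.

    Built directly in k-space (Gaussian envelope x complex white noise) so
    the spectrum genuinely decays toward the grid border — periodic and
    band-limited by construction, which is what the interpolation-free
    k-space transforms assume.
    """
    from kccmoco.kspace import inverse_transform

    rng = np.random.default_rng(seed)
    sigma_k = n / (2.0 * np.pi * sigma)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    r2 = (yy - n // 2) ** 2 + (xx - n // 2) ** 2
    envelope = np.exp(-r2 / (2.0 * sigma_k**2))
    spectrum = envelope * (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)))
    img = inverse_transform(spectrum)
    # apodize: content concentrated inside the field of view (like an object
    # surrounded by air), so rotations do not wrap it across the borders
    window = np.exp(-r2 / (2.0 * (n / 10.0) ** 2))
    return img * window


@pytest.fixture
def smooth_image():
    """Deterministic band-limited complex test image (64 x 64)."""
    return make_smooth_image(64, 42)
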