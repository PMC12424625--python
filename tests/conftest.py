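"""Shared fixtures: small synthetic contact maps and bar images.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pytest

from chromjet.config import JetConfig
from chromjet.synthetic import BackgroundSpec, JetSpec, simulate


@pytest.fixture(scope="session")
def planted_fixture():
    """A 400-bin map with two perpendicular jets of contrast 5, plus truth."""
    bg = BackgroundSpec(p=400, seed=3)
    jets = [JetSpec(origin_bin=120, length_bins=60, contrast=5.0,
                    width_start=2, width_end=5),
            JetSpec(origin_bin=280, length_bins=80, contrast=5.0,
                    width_start=2, width_end=6)]
    cm, truths = simulate(bg, jets, window_bins=100)
    return cm, truths


@pytest.fixture(scope="session")
def small_config():
    return JetConfig(resolution=25_000, window=100 * 25_000)


def gaussian_bar(shape=(64, 64), center=None, sigma=3.0, angle_deg=90.0,
                 amplitude=1.0, noise=0.0, seed=0):
    """Image with a straight Gaussian-profile bar through the image center at
    the given tangent angle (90 = vertical)."""
    m, n = shape
    if center is None:
        center = n / 2.0
    yy, xx = np.indices(shape).astype(float)
    theta = np.radians(angle_deg)
    # signed distance from the line through (m/2, center) with tangent theta
    dist = (xx - center) * np.sin(theta) - (yy - m / 2.0) * np.cos(theta)
    img = amplitude * np.exp(-dist ** 2 / (2.0 * sigma ** 2))
    if noise:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise, size=shape)
    return img


def boxcar_bar(shape=(64, 96), col=48, width=3, amplitude=1.0, noise=0.0, seed=0):
    """Vertical boxcar bar of the given width in columns."""
    img = np.zeros(shape)
    half = width / 2.0
    lo = int(np.ceil(col - half))
    img[:, lo:lo + width] = amplitude
    if noise:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise, size=shape)
    return img
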