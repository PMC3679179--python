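"""Restoration quality metrics: PSNR and SSIM.

PSNR is reported in dB against a peak of 1.0 on the internal intensity
scale (pass ``peak=255`` for integer-scale comparison).  SSIM uses the
standard 11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03, population
(weighted) moments, and averages the local index over every pixel with
symmetric boundary reflection.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .degradation import as_image

__all__ = ["psnr", "ssim", "ssim_map"]


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(peak^2 / MSE)`` in dB.

    Returns ``inf`` when the images are identical (MSE = 0).
    """
    reference = as_image(reference)
    test = as_image(test)
    if reference.shape != test.shape:
        raise ValueError("reference and test must share a shape")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def _ssim_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = size // 2
    ax = np.arange(-r, r + 1)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def ssim_map(
    reference: np.ndarray,
    test: np.ndarray,
    data_range: float = 1.0,
    k1: float = 0.01,
    k2: float = 0.03,
) -> np.ndarray:
    """Per-pixel structural similarity map (11x11 Gaussian window)."""
    x = as_image(reference)
    y = as_image(test)
    if x.shape != y.shape:
        raise ValueError("reference and test must share a shape")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    G = _ssim_window()

    def filt(a):
        return ndimage.correlate(a, G, mode="reflect")

    mx, my = filt(x), filt(y)
    vx = filt(x * x) - mx * mx
    vy = filt(y * y) - my * my
    cov = filt(x * y) - mx * my
    num = (2 * mx * my + c1) * (2 * cov + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return num / den


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity index in [-1, 1]; 1 iff the images match."""
    return float(ssim_map(reference, test, data_range=data_range).mean())
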