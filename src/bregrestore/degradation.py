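"""Forward degradation model: blur kernels, circular convolution, additive noise, phantoms.

The acquisition model is ``f = A u + n``: a spatially invariant blur ``A``
(a small normalized point-spread function applied with periodic boundary
conditions) followed by additive zero-mean Gaussian white noise of standard
deviation ``noise_sigma``.  Intensities live in ``[0, 1]``; the noisy
observation is deliberately *not* clipped, since the model is additive.

Periodic boundaries make ``A`` circulant, so it diagonalizes under the 2-D
DFT; the solver module exploits this for an exact normal-equation solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PSFKernel",
    "DegradationSpec",
    "as_image",
    "gaussian_kernel",
    "average_kernel",
    "convolve",
    "adjoint_convolve",
    "psf_otf",
    "degrade",
    "make_phantom",
]


def as_image(u) -> np.ndarray:
    """Validate and return ``u`` as a 2-D float array.

    Raises ``ValueError`` for non-2-D input or non-finite values.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[0] < 1 or u.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {u.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError("image contains non-finite values")
    return u


@dataclass(frozen=True)
class PSFKernel:
    """A small non-negative blur stencil with odd side lengths, summing to 1.

    The anchor is the central tap; ``taps[c + di, c + dj]`` weights the
    contribution of the pixel at offset ``(di, dj)`` from the output pixel.
    """

    taps: np.ndarray

    def __post_init__(self):
        taps = np.asarray(self.taps, dtype=float)
        if taps.ndim != 2:
            raise ValueError("kernel taps must be 2-D")
        if taps.shape[0] % 2 == 0 or taps.shape[1] % 2 == 0:
            raise ValueError(f"kernel side lengths must be odd, got {taps.shape}")
        if np.any(taps < 0):
            raise ValueError("kernel taps must be non-negative")
        if abs(taps.sum() - 1.0) > 1e-12:
            raise ValueError(f"kernel taps must sum to 1, got {taps.sum()!r}")
        object.__setattr__(self, "taps", taps)

    @property
    def shape(self) -> tuple[int, int]:
        return self.taps.shape

    def rotated(self) -> "PSFKernel":
        """The 180-degree rotated kernel (defines the adjoint operator)."""
        return PSFKernel(self.taps[::-1, ::-1].copy())

    @classmethod
    def from_array(cls, taps) -> "PSFKernel":
        """Build a kernel from a raw non-negative array, normalizing to sum 1."""
        taps = np.asarray(taps, dtype=float)
        s = taps.sum()
        if s <= 0:
            raise ValueError("kernel must have positive mass")
        return cls(taps / s)


@dataclass(frozen=True)
class DegradationSpec:
    """Blur kernel, noise level and RNG seed defining one degradation."""

    kernel: PSFKernel
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def gaussian_kernel(size: int, sigma: float) -> PSFKernel:
    """Isotropic Gaussian PSF of odd side ``size`` and standard deviation ``sigma``.

    ``taps[i, j]`` is proportional to ``exp(-((i-c)^2 + (j-c)^2) / (2 sigma^2))``
    with ``c = (size - 1) / 2``, normalized to unit sum.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    c = (size - 1) / 2.0
    ii, jj = np.mgrid[0:size, 0:size]
    taps = np.exp(-(((ii - c) ** 2 + (jj - c) ** 2) / (2.0 * sigma**2)))
    return PSFKernel.from_array(taps)


def average_kernel(size: int) -> PSFKernel:
    """Uniform box PSF: every tap equals ``1 / size**2``."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    return PSFKernel(np.full((size, size), 1.0 / size**2))


def _check_kernel_fits(image: np.ndarray, kernel: PSFKernel) -> None:
    kh, kw = kernel.shape
    if kh > image.shape[0] or kw > image.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} larger than image {image.shape}"
        )


def convolve(image: np.ndarray, kernel: PSFKernel) -> np.ndarray:
    """Apply the blur operator ``A``: circular convolution with the PSF.

    Linear, shift invariant, same output size; preserves the mean exactly
    because the taps sum to 1.
    """
    image = as_image(image)
    _check_kernel_fits(image, kernel)
    return ndimage.convolve(image, kernel.taps, mode="wrap")


def adjoint_convolve(image: np.ndarray, kernel: PSFKernel) -> np.ndarray:
    """Apply ``A^T``: circular convolution with the 180-degree rotated PSF.

    Satisfies ``<A u, v> = <u, A^T v>`` exactly under periodic boundaries.
    """
    image = as_image(image)
    _check_kernel_fits(image, kernel)
    return ndimage.convolve(image, kernel.rotated().taps, mode="wrap")


def psf_otf(kernel: PSFKernel, shape: tuple[int, int]) -> np.ndarray:
    """Optical transfer function: 2-D DFT of the PSF zero-padded to ``shape``.

    Centers the kernel anchor at the origin so that
    ``convolve(u, k) == irfft-style ifft2(fft2(u) * psf_otf(k, u.shape)).real``.
    """
    kh, kw = kernel.shape
    if kh > shape[0] or kw > shape[1]:
        raise ValueError(f"kernel {kernel.shape} larger than image {shape}")
    pad = np.zeros(shape)
    pad[:kh, :kw] = kernel.taps
    pad = np.roll(pad, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return np.fft.fft2(pad)


def degrade(image: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Simulate observation ``f = A u + n`` with seeded Gaussian noise.

    The output is not clipped to ``[0, 1]``: the additive model is kept exact
    and all metrics compare against the unclipped observation.
    """
    image = as_image(image)
    blurred = convolve(image, spec.kernel)
    if spec.noise_sigma == 0:
        return blurred
    rng = np.random.default_rng(spec.seed)
    return blurred + rng.normal(0.0, spec.noise_sigma, size=image.shape)


def _rescale01(u: np.ndarray) -> np.ndarray:
    lo, hi = u.min(), u.max()
    if hi - lo < 1e-15:
        return np.zeros_like(u)
    return (u - lo) / (hi - lo)


def _bandlimited_texture(size: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic band-limited random field in [-1, 1].

    White noise filtered by a narrow radial annulus in the Fourier domain,
    so nearby patches share the dominant oscillation — the regime in which
    patch-similarity methods have structure to exploit.
    """
    noise = rng.standard_normal((size, size))
    F = np.fft.fft2(noise)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    r = np.hypot(fy, fx)
    band = np.exp(-((r - 0.15) ** 2) / (2 * 0.02**2))
    tex = np.fft.ifft2(F * band).real
    m = np.abs(tex).max()
    return tex / m if m > 0 else tex


def make_phantom(kind: str, size: int, seed: int = 0) -> np.ndarray:
    """Deterministic synthetic test image in ``[0, 1]``.

    Parameters
    ----------
    kind : {"smooth", "piecewise", "textured"}
        ``smooth``: sum of low-frequency sinusoids rescaled to [0, 1].
        ``piecewise``: flat background (0.2) with a rectangle (0.7) and a
        disjoint disk (0.95) — exactly three intensity levels.
        ``textured``: the piecewise phantom with a seeded band-limited
        texture added inside the rectangle.
    size : int
        Side length, at least 16.
    seed : int
        Seeds the sinusoid phases and the texture field.
    """
    if size < 16:
        raise ValueError(f"phantom size must be >= 16, got {size}")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:size, 0:size] / float(size)

    if kind == "smooth":
        phases = rng.uniform(0, 2 * np.pi, size=3)
        u = (
            np.sin(2 * np.pi * x + phases[0])
            + 0.8 * np.sin(2 * np.pi * y + phases[1])
            + 0.4 * np.sin(2 * np.pi * (x + y) + phases[2])
        )
        return _rescale01(u)

    if kind in ("piecewise", "textured"):
        u = np.full((size, size), 0.2)
        rect = (y >= 0.15) & (y <= 0.45) & (x >= 0.10) & (x <= 0.50)
        u[rect] = 0.7
        disk = (y - 0.65) ** 2 + (x - 0.65) ** 2 <= 0.18**2
        u[disk] = 0.95
        if kind == "textured":
            tex = _bandlimited_texture(size, rng)
            u[rect] += 0.15 * tex[rect]
            u = np.clip(u, 0.0, 1.0)
        return u

    raise ValueError(f"unknown phantom kind {kind!r}")
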