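"""Image and kernel I/O.

Grayscale TIFF/PNG/PGM and NPY arrays are read into float images on the
internal ``[0, 1]`` scale: integer files are divided by the maximum of
their dtype, float files pass through untouched.  On write, float TIFF
keeps values exact; integer formats rescale and clip.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .degradation import PSFKernel, as_image, average_kernel, gaussian_kernel

__all__ = ["read_image", "write_image", "kernel_from_spec"]


def read_image(path) -> np.ndarray:
    """Read a 2-D grayscale image, rescaling integer data to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] not in (1, 3, 4):
            raise ValueError(f"cannot interpret image of shape {arr.shape} as grayscale")
        arr = arr[..., :3].mean(axis=2) if arr.shape[2] > 1 else arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return as_image(arr)


def write_image(path, image: np.ndarray) -> None:
    """Write an image; float32 TIFF/NPY preserve values, PNG writes 16-bit."""
    path = Path(path)
    image = as_image(image)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, image)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.float32))
    elif suffix == ".png":
        scaled = np.clip(image, 0.0, 1.0) * np.iinfo(np.uint16).max
        iio.imwrite(path, np.round(scaled).astype(np.uint16))
    else:
        raise ValueError(f"unsupported image format {suffix!r}")


def kernel_from_spec(spec: str) -> PSFKernel:
    """Parse a kernel spec: ``gaussian:SIZE:SIGMA``, ``average:SIZE``,
    ``identity``, or a path to a small kernel image (normalized on load)."""
    parts = spec.split(":")
    if parts[0] == "gaussian" and len(parts) == 3:
        return gaussian_kernel(int(parts[1]), float(parts[2]))
    if parts[0] == "average" and len(parts) == 2:
        return average_kernel(int(parts[1]))
    if parts[0] == "identity" and len(parts) == 1:
        return PSFKernel(np.array([[1.0]]))
    p = Path(spec)
    if p.exists():
        return PSFKernel.from_array(read_image(p))
    raise ValueError(f"cannot parse kernel spec {spec!r}")
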