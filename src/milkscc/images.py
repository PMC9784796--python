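"""Image containers and validation.

Images are plain numpy arrays throughout the package:

* RGB micrograph: ``uint8`` array of shape ``(H, W, 3)`` in **R, G, B**
  channel order (the convention of :mod:`imageio`).  Loaders normalise
  file data to this order so the grayscale weights always hit the
  intended channels.
* grayscale image: ``uint8`` array of shape ``(H, W)``.
* binary image: ``bool`` array of shape ``(H, W)``.

The helpers below validate these contracts at module boundaries.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "as_rgb",
    "as_gray",
    "as_binary",
    "load_rgb",
    "save_image",
    "InvalidImageError",
]


class InvalidImageError(ValueError):
    """Raised when an array does not satisfy an image contract."""


def as_rgb(img: np.ndarray) -> np.ndarray:
    """Validate and return an H×W×3 uint8 RGB image."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidImageError(f"expected H×W×3 RGB array, got shape {img.shape}")
    if img.size == 0:
        raise InvalidImageError("empty image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise InvalidImageError(f"expected uint8 channels, got dtype {img.dtype}")
    return img


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate and return an H×W uint8 grayscale image."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise InvalidImageError(f"expected H×W grayscale array, got shape {img.shape}")
    if img.size == 0:
        raise InvalidImageError("empty image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise InvalidImageError(f"expected uint8 intensities, got dtype {img.dtype}")
    return img


def as_binary(img: np.ndarray) -> np.ndarray:
    """Validate and return an H×W boolean image."""
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise InvalidImageError(f"expected non-empty H×W binary array, got shape {img.shape}")
    if img.dtype != bool:
        uniq = np.unique(img)
        if not np.isin(uniq, (0, 1)).all():
            raise InvalidImageError("binary image must contain only {0, 1}")
        img = img.astype(bool)
    return img


def load_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/BMP file as an RGB uint8 image.

    Grayscale files are broadcast to three identical channels; an alpha
    channel, if present, is dropped.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return as_rgb(arr)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write an RGB, grayscale or binary image to disk (format from suffix)."""
    img = np.asarray(img)
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    iio.imwrite(path, img)
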