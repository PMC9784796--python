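"""Six-stage image preparation for stained-milk micrographs.

A raw colour micrograph of Wright's-stained milk (blue-purple nuclei on a
light-pink background) is converted into a denoised, contrast-enhanced
grayscale image in a fixed order:

1. weighted grayscale conversion,
2. median filtering (suppresses impulse noise),
3. bilateral filtering (suppresses Gaussian noise while preserving edges),
4. unsharp masking (raises local contrast),
5. contrast-limited adaptive histogram equalization (CLAHE).

Every stage maps an 8-bit image to an 8-bit image of the same size, and the
whole chain is deterministic: identical input and configuration produce a
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, restoration

from .images import as_gray, as_rgb

__all__ = [
    "PreprocessConfig",
    "ConfigError",
    "to_grayscale",
    "median_filter",
    "bilateral_filter",
    "sharpen_mask",
    "clahe",
    "preprocess",
]

# luminance weights of the weighted-value grayscale conversion
GRAY_WEIGHT_RED = 0.299
GRAY_WEIGHT_GREEN = 0.587
GRAY_WEIGHT_BLUE = 0.114


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration values."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the grayscale/denoise/enhance chain.

    The operators themselves are fixed; these are their conventional knobs.

    Parameters
    ----------
    median_kernel:
        Odd window size (pixels) of the median filter.
    bilateral_diameter:
        Window size (pixels) of the bilateral filter.
    bilateral_sigma_color:
        Range (intensity) sigma of the bilateral filter, on the 0–255 scale.
    bilateral_sigma_space:
        Spatial sigma of the bilateral filter, in pixels.
    sharpen_strength:
        Gain of the unsharp mask; 0 disables sharpening.
    clahe_clip_limit:
        CLAHE clipping threshold as a fraction of each tile histogram
        (scikit-image convention, in (0, 1]).
    clahe_tile_grid:
        Number of (rows, cols) of CLAHE tiles.
    clahe_flat_std:
        Contrast floor (gray levels): an input whose global intensity SD is
        below this is considered signal-free and passed through unchanged.
        After median + bilateral denoising a cell-free field retains only a
        sub-graylevel noise residue; equalizing it would amplify pure
        sensor noise into spurious full-range structure.
    """

    median_kernel: int = 3
    bilateral_diameter: int = 9
    bilateral_sigma_color: float = 50.0
    bilateral_sigma_space: float = 50.0
    sharpen_strength: float = 1.0
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    clahe_flat_std: float = 1.0

    def __post_init__(self) -> None:
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ConfigError(f"median_kernel must be odd and ≥ 3, got {self.median_kernel}")
        if self.bilateral_diameter < 1:
            raise ConfigError("bilateral_diameter must be positive")
        if self.bilateral_sigma_color <= 0 or self.bilateral_sigma_space <= 0:
            raise ConfigError("bilateral sigmas must be positive")
        if self.sharpen_strength < 0:
            raise ConfigError("sharpen_strength must be non-negative")
        if self.clahe_clip_limit <= 0:
            raise ConfigError("clahe_clip_limit must be positive")
        if self.clahe_flat_std < 0:
            raise ConfigError("clahe_flat_std must be ≥ 0")
        rows, cols = self.clahe_tile_grid
        if rows < 1 or cols < 1:
            raise ConfigError("clahe_tile_grid dimensions must be ≥ 1")


def _round_half_up(values: np.ndarray) -> np.ndarray:
    """Round non-negative floats half away from zero and cast to uint8."""
    return np.floor(np.clip(values, 0, 255) + 0.5).astype(np.uint8)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Weighted-value grayscale conversion.

    ``gray = 0.114·B + 0.587·G + 0.299·R``, rounded half away from zero.
    The weights sum to exactly one, so gray inputs are fixed points.
    """
    img = as_rgb(img)
    r, g, b = img[..., 0].astype(np.float64), img[..., 1].astype(np.float64), img[..., 2].astype(np.float64)
    gray = GRAY_WEIGHT_RED * r + GRAY_WEIGHT_GREEN * g + GRAY_WEIGHT_BLUE * b
    return _round_half_up(gray)


def median_filter(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with edge replication at the borders."""
    img = as_gray(img)
    if kernel < 3 or kernel % 2 == 0:
        raise ConfigError(f"median kernel must be odd and ≥ 3, got {kernel}")
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def bilateral_filter(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Edge-preserving smoothing.

    Each pixel becomes a normalised average of its window, weighted by a
    spatial Gaussian (``bilateral_sigma_space``) times an intensity Gaussian
    (``bilateral_sigma_color``): pixels across a strong edge get nearly zero
    weight, so edges survive while Gaussian noise inside flat regions is
    averaged away.
    """
    img = as_gray(img)
    cfg = cfg or PreprocessConfig()
    out = restoration.denoise_bilateral(
        img.astype(np.float64) / 255.0,
        win_size=cfg.bilateral_diameter,
        sigma_color=cfg.bilateral_sigma_color / 255.0,
        sigma_spatial=cfg.bilateral_sigma_space,
        mode="edge",
    )
    return _round_half_up(out * 255.0)


def sharpen_mask(img: np.ndarray, strength: float = 1.0) -> np.ndarray:
    """Unsharp masking: ``out = img + strength · (img − blur(img))``.

    The blur is a 3×3 box mean with edge replication; ``strength`` 0 is the
    identity and constant images are always fixed points.
    """
    img = as_gray(img)
    if strength < 0:
        raise ConfigError("sharpen strength must be non-negative")
    f = img.astype(np.float64)
    blur = ndimage.uniform_filter(f, size=3, mode="nearest")
    return _round_half_up(f + strength * (f - blur))


def clahe(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into ``clahe_tile_grid`` tiles; each tile's
    histogram is clipped at ``clahe_clip_limit`` and equalized, and the tile
    mappings are blended by bilinear interpolation.

    Degenerate input: an image with essentially no contrast (global SD below
    ``clahe_flat_std``) is returned unchanged — there is nothing to enhance,
    and equalizing a flat noise field would only fabricate structure.
    """
    img = as_gray(img)
    cfg = cfg or PreprocessConfig()
    rows, cols = cfg.clahe_tile_grid
    h, w = img.shape
    if rows > h or cols > w:
        raise ConfigError(f"CLAHE tile grid {cfg.clahe_tile_grid} larger than image {img.shape}")
    if float(img.std()) < cfg.clahe_flat_std:
        return img.copy()
    kernel = (max(1, int(np.ceil(h / rows))), max(1, int(np.ceil(w / cols))))
    out = exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=cfg.clahe_clip_limit)
    return _round_half_up(out * 255.0)


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Run the full chain: grayscale → median → bilateral → sharpen → CLAHE."""
    cfg = cfg or PreprocessConfig()
    gray = to_grayscale(img)
    gray = median_filter(gray, cfg.median_kernel)
    gray = bilateral_filter(gray, cfg)
    gray = sharpen_mask(gray, cfg.sharpen_strength)
    return clahe(gray, cfg)
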