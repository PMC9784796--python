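"""Cell-contour extraction and connected-domain counting.

The enhanced grayscale image is turned into a binary edge map with the
Canny detector; residual specks are filtered by morphological opening and
a minimum component size; every remaining connected domain — one closed
cell contour — counts as one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, measure, morphology

from .images import as_binary, as_gray
from .preprocessing import ConfigError, PreprocessConfig, preprocess

__all__ = [
    "SegmentConfig",
    "Component",
    "ComponentSet",
    "CountResult",
    "auto_canny_thresholds",
    "canny_edges",
    "morphological_open",
    "label_components",
    "count_cells",
    "count_pipeline",
]

# fallback hysteresis thresholds when the automatic rule degenerates
# (e.g. an all-black image whose median is 0)
FALLBACK_THRESHOLDS = (50, 150)


@dataclass(frozen=True)
class SegmentConfig:
    """Parameters of the edge-extraction and counting stages.

    ``canny_low``/``canny_high`` may be numeric hysteresis thresholds on the
    0–255 intensity scale or ``"auto"``, in which case they are derived from
    the image median (see :func:`auto_canny_thresholds`).  ``open_size`` is
    the radius/half-width of the opening structuring element in pixels; the
    default 0 disables opening because Canny contours are single-pixel
    curves that any non-trivial erosion would delete — speck removal is
    then carried by ``min_component_px``.
    """

    canny_low: float | str = "auto"
    canny_high: float | str = "auto"
    auto_sigma: float = 0.33
    canny_gaussian_sigma: float = 1.0
    open_shape: str = "square"
    open_size: int = 0
    open_iterations: int = 1
    connectivity: int = 8
    min_component_px: int = 15
    count_border_touching: bool = True

    def __post_init__(self) -> None:
        auto = self.canny_low == "auto" or self.canny_high == "auto"
        if not auto:
            if not (0 <= self.canny_low < self.canny_high <= 255):
                raise ConfigError(
                    f"need 0 ≤ canny_low < canny_high ≤ 255, got ({self.canny_low}, {self.canny_high})"
                )
        if not 0 < self.auto_sigma < 1:
            raise ConfigError("auto_sigma must lie in (0, 1)")
        if self.open_shape not in ("square", "ellipse"):
            raise ConfigError(f"open_shape must be 'square' or 'ellipse', got {self.open_shape!r}")
        if self.open_size < 0 or self.open_iterations < 1:
            raise ConfigError("open_size must be ≥ 0 and open_iterations ≥ 1")
        if self.connectivity not in (4, 8):
            raise ConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.min_component_px < 0:
            raise ConfigError("min_component_px must be ≥ 0")


@dataclass(frozen=True)
class Component:
    """One connected domain of foreground pixels."""

    id: int
    pixel_count: int
    bounding_box: tuple[int, int, int, int]  # row0, col0, row1, col1 (exclusive)
    centroid: tuple[float, float]


@dataclass(frozen=True)
class ComponentSet:
    """Connected-domain labelling of a binary image."""

    labels: np.ndarray  # H×W int raster, 0 = background
    components: tuple[Component, ...]

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class CountResult:
    """Outcome of counting one image."""

    count: int
    components: ComponentSet
    stage_images: dict[str, np.ndarray] = field(default_factory=dict)


def auto_canny_thresholds(img: np.ndarray, sigma: float = 0.33) -> tuple[int, int]:
    """Median-based automatic hysteresis thresholds.

    ``low = max(0, (1−sigma)·median)``, ``high = min(255, (1+sigma)·median)``,
    both truncated to integers.  A degenerate result (``low == high``, e.g.
    on a constant dark image) signals the caller to fall back to fixed
    thresholds.
    """
    img = as_gray(img)
    if not 0 < sigma < 1:
        raise ConfigError("sigma must lie in (0, 1)")
    med = float(np.median(img))
    low = int(max(0.0, (1.0 - sigma) * med))
    high = int(min(255.0, (1.0 + sigma) * med))
    return low, high


def _resolve_thresholds(img: np.ndarray, cfg: SegmentConfig) -> tuple[float, float]:
    if cfg.canny_low == "auto" or cfg.canny_high == "auto":
        low, high = auto_canny_thresholds(img, cfg.auto_sigma)
        if low >= high:
            return FALLBACK_THRESHOLDS
        return low, high
    return float(cfg.canny_low), float(cfg.canny_high)


def canny_edges(img: np.ndarray, cfg: SegmentConfig | None = None) -> np.ndarray:
    """Binary edge map via the Canny detector.

    Gaussian smoothing, Sobel gradients, non-maximum suppression and
    double-threshold hysteresis; thresholds are on the 0–255 intensity
    scale (scaled internally to the gradient of the unit-range image).
    """
    img = as_gray(img)
    cfg = cfg or SegmentConfig()
    low, high = _resolve_thresholds(img, cfg)
    return feature.canny(
        img,
        sigma=cfg.canny_gaussian_sigma,
        low_threshold=low,
        high_threshold=high,
        mode="nearest",
    )


def _structuring_element(shape: str, size: int) -> np.ndarray:
    if shape == "ellipse":
        return morphology.disk(size)
    return morphology.footprint_rectangle((2 * size + 1, 2 * size + 1))


def morphological_open(img: np.ndarray, cfg: SegmentConfig | None = None) -> np.ndarray:
    """Opening (erosion then dilation) of a binary image.

    Removes foreground structures smaller than the structuring element;
    idempotent, and never increases the foreground pixel count.  With the
    default ``open_size`` 0 the element is a single pixel and the image
    passes through unchanged.
    """
    img = as_binary(img)
    cfg = cfg or SegmentConfig()
    if cfg.open_size == 0:
        return img.copy()
    selem = _structuring_element(cfg.open_shape, cfg.open_size)
    if selem.shape[0] > img.shape[0] or selem.shape[1] > img.shape[1]:
        raise ConfigError("structuring element larger than image")
    out = img
    for _ in range(cfg.open_iterations):
        out = morphology.opening(out, selem)
    return out


def label_components(img: np.ndarray, connectivity: int = 8) -> ComponentSet:
    """Label connected domains of foreground pixels.

    Two pixels share a label iff they are reachable through adjacent
    positions under the chosen connectivity (4 = edge-adjacent,
    8 = edge- or corner-adjacent).  Labels are contiguous ``1..K``.
    """
    img = as_binary(img)
    if connectivity not in (4, 8):
        raise ConfigError(f"connectivity must be 4 or 8, got {connectivity}")
    labels = measure.label(img, connectivity=1 if connectivity == 4 else 2)
    comps = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        comps.append(
            Component(
                id=int(region.label),
                pixel_count=int(region.area),
                bounding_box=(int(r0), int(c0), int(r1), int(c1)),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
            )
        )
    return ComponentSet(labels=labels, components=tuple(comps))


def count_cells(img: np.ndarray, cfg: SegmentConfig | None = None) -> CountResult:
    """Count connected domains surviving the size/border filters.

    A component is counted when its pixel count is at least
    ``min_component_px`` and, unless ``count_border_touching``, its bounding
    box does not touch the image border.
    """
    img = as_binary(img)
    cfg = cfg or SegmentConfig()
    comps = label_components(img, cfg.connectivity)
    h, w = img.shape
    kept = []
    for comp in comps.components:
        if comp.pixel_count < cfg.min_component_px:
            continue
        if not cfg.count_border_touching:
            r0, c0, r1, c1 = comp.bounding_box
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                continue
        kept.append(comp)
    return CountResult(count=len(kept), components=ComponentSet(comps.labels, tuple(kept)))


def count_pipeline(
    img: np.ndarray,
    pre_cfg: PreprocessConfig | None = None,
    seg_cfg: SegmentConfig | None = None,
    keep_stages: bool = False,
) -> CountResult:
    """Full chain: preprocess → Canny edges → opening → component count."""
    pre_cfg = pre_cfg or PreprocessConfig()
    seg_cfg = seg_cfg or SegmentConfig()
    enhanced = preprocess(img, pre_cfg)
    edges = canny_edges(enhanced, seg_cfg)
    opened = morphological_open(edges, seg_cfg)
    result = count_cells(opened, seg_cfg)
    if keep_stages:
        stages = {"enhanced": enhanced, "edges": edges, "opened": opened}
        result = CountResult(result.count, result.components, stages)
    return result
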