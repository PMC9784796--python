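"""Distribution-uniformity statistics for per-cavity cell counts.

The chip exposes nine observation cavities per milk sample; if the cells
are well mixed, the nine per-image counts should be nearly equal.  The
evenness metric is the standard deviation coefficient (coefficient of
variation): sample standard deviation over mean, as a percent.  The same
metric applied to the 81 sub-images obtained by cutting each image into a
3×3 grid probes uniformity *within* each cavity.

Conventions pinned here (both established by exact reproduction of the
published per-group table): the standard deviation uses the n−1 sample
denominator, and percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .images import as_rgb
from .preprocessing import PreprocessConfig
from .segmentation import SegmentConfig, count_pipeline

__all__ = [
    "CavityCountSet",
    "UniformityStats",
    "StudySummary",
    "std_dev_coefficient",
    "tile_3x3",
    "subtile_uniformity",
    "study_summary",
    "load_counts_csv",
    "write_counts_csv",
    "load_reference_counts",
]

CAVITIES_PER_SAMPLE = 9


class UndefinedCVError(ValueError):
    """CV is undefined when the mean count is zero."""


@dataclass(frozen=True)
class CavityCountSet:
    """Per-image somatic-cell counts for one milk sample (one cow)."""

    group_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != CAVITIES_PER_SAMPLE:
            raise ValueError(
                f"expected {CAVITIES_PER_SAMPLE} counts, got {len(self.counts)}"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class UniformityStats:
    """Mean, sample SD and standard deviation coefficient of a count set."""

    mean: float
    sd: float
    cv_percent: float  # rounded half-up to 2 decimals
    cv_exact: float


@dataclass(frozen=True)
class StudySummary:
    """Per-group CVs plus their max/min/mean across a study."""

    per_group: tuple[UniformityStats, ...]
    max_cv: float
    min_cv: float
    mean_cv: float  # mean of the rounded per-group CVs, itself rounded
    mean_cv_exact: float


def _round2(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def std_dev_coefficient(counts) -> UniformityStats:
    """Standard deviation coefficient of a set of counts, in percent.

    ``cv = 100 · sd / mean`` with the sample (n−1) standard deviation.
    Raises :class:`UndefinedCVError` when the mean is zero.
    """
    arr = np.asarray(counts, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least 2 counts")
    mean = float(arr.mean())
    if mean == 0:
        raise UndefinedCVError("CV undefined: mean count is zero")
    sd = float(arr.std(ddof=1))
    cv = 100.0 * sd / mean
    return UniformityStats(mean=mean, sd=sd, cv_percent=_round2(cv), cv_exact=cv)


def tile_3x3(img: np.ndarray) -> list[np.ndarray]:
    """Cut an image into a 3×3 grid of tiles, row-major.

    Boundaries sit at ``floor(i·H/3)`` / ``floor(j·W/3)``, so the nine crops
    partition the image exactly even when H or W is not divisible by 3.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h < 3 or w < 3:
        raise ValueError(f"image too small to tile: {h}×{w}")
    rb = [h * i // 3 for i in range(4)]
    cb = [w * j // 3 for j in range(4)]
    return [img[rb[i] : rb[i + 1], cb[j] : cb[j + 1]] for i in range(3) for j in range(3)]


def subtile_uniformity(
    images,
    pre_cfg: PreprocessConfig | None = None,
    seg_cfg: SegmentConfig | None = None,
) -> UniformityStats:
    """Within-cavity uniformity: CV over the 81 counts of 9 images × 9 tiles."""
    images = list(images)
    if len(images) != CAVITIES_PER_SAMPLE:
        raise ValueError(f"expected {CAVITIES_PER_SAMPLE} images, got {len(images)}")
    counts = [
        count_pipeline(as_rgb(tile), pre_cfg, seg_cfg).count
        for img in images
        for tile in tile_3x3(img)
    ]
    return std_dev_coefficient(counts)


def study_summary(groups) -> StudySummary:
    """Summarise per-group CVs across a whole study.

    The reported mean is the arithmetic mean of the *rounded* per-group
    percentages (matching how published tables are typically averaged);
    the unrounded mean is also retained.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("need at least one group")
    per_group = tuple(std_dev_coefficient(g.counts) for g in groups)
    cvs = [s.cv_percent for s in per_group]
    exact = [s.cv_exact for s in per_group]
    return StudySummary(
        per_group=per_group,
        max_cv=max(cvs),
        min_cv=min(cvs),
        mean_cv=_round2(sum(cvs) / len(cvs)),
        mean_cv_exact=float(np.mean(exact)),
    )


_COUNT_COLS = [f"c{i}" for i in range(1, 10)]


def load_counts_csv(path: str | Path) -> list[CavityCountSet]:
    """Read a per-group counts table (``group_id,c1..c9[,cv_percent]``)."""
    df = pd.read_csv(path, dtype={"group_id": str})
    missing = [c for c in ("group_id", *_COUNT_COLS) if c not in df.columns]
    if missing:
        raise ValueError(f"counts CSV {path} missing columns: {missing}")
    out = []
    for idx, row in df.iterrows():
        vals = row[_COUNT_COLS]
        if vals.isna().any():
            raise ValueError(f"counts CSV {path}: row {idx + 1} has missing counts")
        out.append(CavityCountSet(group_id=str(row["group_id"]), counts=tuple(int(v) for v in vals)))
    return out


def write_counts_csv(path: str | Path, groups) -> None:
    """Write groups (and their computed CVs) as a counts CSV."""
    rows = []
    for g in groups:
        stats = std_dev_coefficient(g.counts)
        rows.append({"group_id": g.group_id, **dict(zip(_COUNT_COLS, g.counts)), "cv_percent": stats.cv_percent})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_reference_counts() -> list[CavityCountSet]:
    """The packaged 20-cow field study: nine per-cavity counts per cow."""
    ref = importlib.resources.files("milkscc.data") / "table1_counts.csv"
    with importlib.resources.as_file(ref) as path:
        return load_counts_csv(path)
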