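"""SCC per millilitre, udder-health classification and herd planning.

A per-image cell count becomes a concentration through the chip geometry:
one micrograph images a liquid slab of (field-of-view length × width ×
channel height), so

    SCC [cells/mL] = mean count per image / V_fov [μL] × 1000.

With the default geometry (5802 μm × 4050 μm × 40 μm) the imaged volume is
9.39924×10⁸ μm³ ≈ 0.94 μL.  The concentration is then mapped onto health
bands — elevated SCC indicates mastitis — and the herd is ordered: healthy
or suspect cows are milked cleanest-first, infected cows treated
worst-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

__all__ = [
    "ChipGeometry",
    "HealthBand",
    "HealthThresholds",
    "SCCResult",
    "HerdPlan",
    "fov_volume",
    "scc_per_ml",
    "classify_udder",
    "plan_herd",
]

UM3_PER_UL = 1e9


@dataclass(frozen=True)
class ChipGeometry:
    """Dimensions (μm) of the imaged liquid slab in one observation cavity."""

    fov_length: float = 5802.0
    fov_width: float = 4050.0
    channel_height: float = 40.0

    def __post_init__(self) -> None:
        if min(self.fov_length, self.fov_width, self.channel_height) <= 0:
            raise ValueError("all chip dimensions must be positive")

    @property
    def volume_um3(self) -> float:
        return self.fov_length * self.fov_width * self.channel_height

    @property
    def volume_ul(self) -> float:
        return self.volume_um3 / UM3_PER_UL


@dataclass(frozen=True)
class HealthBand:
    """One udder-health category: applies for SCC in [lower, upper)."""

    upper_bound: float  # cells/mL, exclusive
    category: str
    action: str  # "milk" or "treat"


@dataclass(frozen=True)
class HealthThresholds:
    """Ordered, exhaustive SCC bands with half-open [low, high) membership.

    The default scheme is reconstructed from the herd-ordering behaviour of
    the reference study rather than transcribed from a published table:
    below 5×10⁵ cells/mL a cow joins the milking queue; between 5×10⁵ and
    10⁶ she is treated for subclinical mastitis; above 10⁶ for clinical
    mastitis.  All bounds are configuration-overridable.
    """

    bands: tuple[HealthBand, ...] = (
        HealthBand(5e5, "healthy or suspect", "milk"),
        HealthBand(1e6, "subclinical mastitis", "treat"),
        HealthBand(inf, "clinical mastitis", "treat"),
    )

    def __post_init__(self) -> None:
        bounds = [b.upper_bound for b in self.bands]
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ValueError("band upper bounds must be strictly increasing")
        if bounds[-1] != inf:
            raise ValueError("last band must be unbounded (upper_bound = inf)")
        if any(b.action not in ("milk", "treat") for b in self.bands):
            raise ValueError("band actions must be 'milk' or 'treat'")


@dataclass(frozen=True)
class SCCResult:
    """Concentration derived from one cow's mean per-image count."""

    cow_id: str
    mean_count: float
    scc_per_ml: float
    volume_ul: float
    category: str = ""
    action: str = ""


@dataclass(frozen=True)
class HerdPlan:
    """Milking queue (ascending SCC) and treatment queue (descending SCC)."""

    milking_order: tuple[str, ...]
    treatment_order: tuple[str, ...]
    results: tuple[SCCResult, ...] = field(default_factory=tuple)


def fov_volume(geom: ChipGeometry | None = None) -> float:
    """Imaged volume of one field of view, in μL (unrounded)."""
    geom = geom or ChipGeometry()
    return geom.volume_ul


def scc_per_ml(mean_count: float, geom: ChipGeometry | None = None) -> float:
    """Cells per millilitre from a mean per-image count.

    Uses the exact (unrounded) field-of-view volume; with the default
    geometry, 1 count/image ≈ 1064 cells/mL.
    """
    if mean_count < 0:
        raise ValueError("mean_count must be ≥ 0")
    geom = geom or ChipGeometry()
    return mean_count / geom.volume_ul * 1000.0


def classify_udder(scc: float, thresholds: HealthThresholds | None = None) -> HealthBand:
    """Return the health band containing an SCC value ([low, high) bands)."""
    if scc < 0:
        raise ValueError("scc must be ≥ 0")
    thresholds = thresholds or HealthThresholds()
    for band in thresholds.bands:
        if scc < band.upper_bound:
            return band
    raise AssertionError("bands are exhaustive")  # unreachable


def plan_herd(results, thresholds: HealthThresholds | None = None) -> HerdPlan:
    """Order a herd for milking and treatment by udder health.

    Cows whose band action is ``milk`` are queued by ascending SCC (cleanest
    milked first); cows needing treatment by descending SCC (sickest
    treated first).  Ties break by cow id.
    """
    thresholds = thresholds or HealthThresholds()
    results = list(results)
    ids = [r.cow_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cow ids in herd")

    classified = []
    for r in results:
        band = classify_udder(r.scc_per_ml, thresholds)
        classified.append(
            SCCResult(r.cow_id, r.mean_count, r.scc_per_ml, r.volume_ul, band.category, band.action)
        )

    def id_key(r: SCCResult):
        # numeric ids sort numerically ("2" before "10"), others lexically
        try:
            return (0, int(r.cow_id), r.cow_id)
        except ValueError:
            return (1, 0, r.cow_id)

    milk = sorted((r for r in classified if r.action == "milk"), key=lambda r: (r.scc_per_ml, id_key(r)))
    treat = sorted(
        (r for r in classified if r.action == "treat"),
        key=lambda r: (-r.scc_per_ml, id_key(r)),
    )
    return HerdPlan(
        milking_order=tuple(r.cow_id for r in milk),
        treatment_order=tuple(r.cow_id for r in treat),
        results=tuple(classified),
    )
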