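"""Synthetic Wright's-stain cavity micrographs with exact ground truth.

Real chip images show blue-purple granular nuclei on a light-pink milk
background, contaminated by impulse (salt/pepper) and Gaussian sensor
noise.  The generator reproduces those features — cells as filled disks
with multiplicative speckle texture, jittered colours and radii, seeded
noise — while recording every cell's centre and radius, so the counting
pipeline can be scored against an exact truth that real micrographs never
provide.

All randomness flows from explicit seeds; regeneration with the same
arguments is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import as_rgb

__all__ = [
    "AppearanceConfig",
    "NoiseConfig",
    "SyntheticScene",
    "PackingError",
    "generate_cavity",
    "generate_group",
    "add_noise",
]

# rejection-sampling budget for non-overlapping placement
_MAX_REJECTIONS = 100_000
# extra clearance (px) between non-overlapping disks so that two cells'
# edge contours can never fuse into one connected domain
_SEPARATION_PX = 4


class PackingError(RuntimeError):
    """Raised when non-overlapping cells cannot be placed in the image."""


@dataclass(frozen=True)
class AppearanceConfig:
    """Colours and sizes of the rendered scene (RGB, 8-bit).

    Defaults mimic a Wright's-stained micrograph: light-pink background,
    blue-purple nuclei, cell radii jittered uniformly in
    ``[cell_radius_px − cell_radius_jitter, cell_radius_px + cell_radius_jitter]``.
    ``granularity_sigma`` is the relative standard deviation of the
    multiplicative speckle that imitates nuclear granularity.
    """

    background_color: tuple[int, int, int] = (255, 182, 193)
    nucleus_color: tuple[int, int, int] = (120, 60, 180)
    color_jitter: int = 10
    cell_radius_px: float = 7.0
    cell_radius_jitter: float = 2.0
    granularity_sigma: float = 0.08

    def __post_init__(self) -> None:
        for c in (*self.background_color, *self.nucleus_color):
            if not 0 <= c <= 255:
                raise ValueError("colors must be 8-bit")
        if self.cell_radius_px - self.cell_radius_jitter < 2:
            raise ValueError("minimum cell radius must be ≥ 2 px")
        if self.granularity_sigma < 0:
            raise ValueError("granularity_sigma must be ≥ 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor-noise model: per-pixel impulse noise plus additive Gaussian.

    ``impulse_prob`` is the probability that a pixel is replaced by salt
    (255) or pepper (0) — each with probability ``impulse_prob / 2``;
    ``gaussian_sigma`` is the per-channel standard deviation in intensity
    units of the additive noise.
    """

    impulse_prob: float = 0.002
    gaussian_sigma: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.impulse_prob <= 1:
            raise ValueError("impulse_prob must be a probability")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be ≥ 0")


@dataclass(frozen=True)
class SyntheticScene:
    """One generated cavity image plus its exact ground truth."""

    image: np.ndarray  # H×W×3 uint8 RGB
    cells: tuple[dict, ...]  # {"center": (row, col), "radius": px}
    seed: int
    true_count: int


def add_noise(img: np.ndarray, noise: NoiseConfig, seed: int) -> np.ndarray:
    """Apply salt/pepper and additive Gaussian noise, seeded."""
    img = as_rgb(img)
    rng = np.random.default_rng(seed)
    out = img.astype(np.float64)
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, size=out.shape)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if noise.impulse_prob > 0:
        u = rng.random(img.shape[:2])
        salt = u < noise.impulse_prob / 2
        pepper = (u >= noise.impulse_prob / 2) & (u < noise.impulse_prob)
        out[salt] = 255
        out[pepper] = 0
    return out


def _place_cells(
    n_cells: int,
    dims: tuple[int, int],
    radii: np.ndarray,
    rng: np.random.Generator,
    non_overlapping: bool,
) -> list[tuple[float, float]]:
    h, w = dims
    if non_overlapping:
        # feasibility check: exclusion discs must fit with slack
        area = sum(np.pi * (r + _SEPARATION_PX / 2) ** 2 for r in radii)
        if area > 0.5 * h * w:
            raise PackingError(
                f"cannot place {n_cells} non-overlapping cells of mean radius "
                f"{radii.mean():.1f} px in a {h}×{w} image"
            )
    centers: list[tuple[float, float]] = []
    rejections = 0
    for i in range(n_cells):
        r = radii[i]
        while True:
            row = rng.uniform(r, h - r)
            col = rng.uniform(r, w - r)
            if not non_overlapping:
                centers.append((row, col))
                break
            ok = all(
                (row - cr) ** 2 + (col - cc) ** 2 > (r + radii[j] + _SEPARATION_PX) ** 2
                for j, (cr, cc) in enumerate(centers)
            )
            if ok:
                centers.append((row, col))
                break
            rejections += 1
            if rejections > _MAX_REJECTIONS:
                raise PackingError(
                    f"placement exceeded {_MAX_REJECTIONS} rejections at cell {i + 1}/{n_cells}"
                )
    return centers


def generate_cavity(
    n_cells: int,
    dims: tuple[int, int] = (480, 640),
    appearance: AppearanceConfig | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    non_overlapping: bool = True,
) -> SyntheticScene:
    """Render one observation-cavity micrograph with known cell positions.

    Cells are placed uniformly at random (rejection sampling keeps disks
    disjoint when ``non_overlapping``), drawn as filled nucleus-coloured
    disks with speckle texture, then impulse and Gaussian noise are applied.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be ≥ 0")
    appearance = appearance or AppearanceConfig()
    noise = noise or NoiseConfig()
    h, w = dims
    rng = np.random.default_rng(seed)

    radii = rng.uniform(
        appearance.cell_radius_px - appearance.cell_radius_jitter,
        appearance.cell_radius_px + appearance.cell_radius_jitter,
        size=n_cells,
    )
    centers = _place_cells(n_cells, (h, w), radii, rng, non_overlapping)

    img = np.empty((h, w, 3), dtype=np.float64)
    bg = np.array(appearance.background_color, dtype=np.float64)
    img[:] = bg + rng.normal(0.0, appearance.color_jitter / 4, size=(h, w, 3))

    rows, cols = np.mgrid[0:h, 0:w]
    for (row, col), r in zip(centers, radii):
        jitter = rng.uniform(-appearance.color_jitter, appearance.color_jitter, size=3)
        color = np.clip(np.array(appearance.nucleus_color, dtype=np.float64) + jitter, 0, 255)
        r0, r1 = max(0, int(row - r) - 1), min(h, int(row + r) + 2)
        c0, c1 = max(0, int(col - r) - 1), min(w, int(col + r) + 2)
        mask = (rows[r0:r1, c0:c1] - row) ** 2 + (cols[r0:r1, c0:c1] - col) ** 2 <= r**2
        npx = int(mask.sum())
        speckle = 1.0 + rng.normal(0.0, appearance.granularity_sigma, size=(npx, 1))
        img[r0:r1, c0:c1][mask] = np.clip(color[None, :] * speckle, 0, 255)

    clean = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    noisy = add_noise(clean, noise, seed=int(rng.integers(0, 2**31 - 1)))
    cells = tuple(
        {"center": (float(r_), float(c_)), "radius": float(rad)}
        for (r_, c_), rad in zip(centers, radii)
    )
    return SyntheticScene(image=noisy, cells=cells, seed=seed, true_count=n_cells)


def draw_group_counts(
    mean_count: float, dispersion: str, n_images: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the per-image true counts of a group.

    ``"poisson"`` models perfectly mixed cells (CV = 1/√mean); ``"fixed"``
    gives identical counts (CV = 0), mirroring the near-zero dispersion a
    well-stirred chip achieves.
    """
    if dispersion == "poisson":
        return rng.poisson(mean_count, size=n_images)
    if dispersion == "fixed":
        return np.full(n_images, int(round(mean_count)))
    raise ValueError(f"dispersion must be 'poisson' or 'fixed', got {dispersion!r}")


def generate_group(
    mean_count: float,
    dispersion: str = "poisson",
    n_images: int = 9,
    dims: tuple[int, int] = (480, 640),
    appearance: AppearanceConfig | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> list[SyntheticScene]:
    """Generate one sample's worth of cavity images (default nine).

    ``dispersion`` selects the per-image true counts: ``"poisson"`` draws
    them from Poisson(``mean_count``) — the null model of perfectly mixed
    cells — while ``"fixed"`` makes all counts equal, reproducing the
    near-zero dispersion observed on the chip.
    """
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    if dispersion not in ("poisson", "fixed"):
        raise ValueError(f"dispersion must be 'poisson' or 'fixed', got {dispersion!r}")
    rng = np.random.default_rng(seed)
    counts = draw_group_counts(mean_count, dispersion, n_images, rng)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    return [
        generate_cavity(
            int(n),
            dims=dims,
            appearance=appearance,
            noise=noise,
            seed=int(s),
            non_overlapping=True,
        )
        for n, s in zip(counts, scene_seeds)
    ]
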