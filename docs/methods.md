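# Methods

## The counting model

A stained micrograph of milk in a chip observation cavity is reduced to a
cell count in six stages, in a fixed order:

1. **Weighted grayscale.** `Gray = 0.114·B + 0.587·G + 0.299·R`, rounded
   half away from zero.  The weights sum to one, so gray inputs are fixed
   points; the rounding rule is pinned because the downstream tests
   compare rasters byte-for-byte.
2. **Median filter** (3×3 default) — removes impulse (salt/pepper)
   noise.
3. **Bilateral filter** (window 9, σ_color 50 gray levels, σ_space 50 px)
   — removes Gaussian noise while preserving the nucleus contours the
   detector needs.
4. **Unsharp mask** (`out = img + s·(img − box₃(img))`, s = 1) — restores
   the local contrast the smoothing stages blur away.
5. **CLAHE** (8×8 tiles, clip limit 0.01 in the scikit-image fractional
   convention) — normalises brightness and stretches stain contrast
   per-region, which makes the edge detector robust to uneven staining.
6. **Canny + opening + connected-domain count.** Hysteresis thresholds
   default to the median rule `low = (1−σ)·median`, `high = (1+σ)·median`
   with σ = 0.33 on the enhanced image (fixed fallback (50, 150) when the
   rule degenerates, e.g. on an all-dark image); the edge map is opened,
   then every connected domain with at least `min_component_px` = 15
   pixels counts as one cell.  Connectivity is 8 because cell contours are
   curved and 4-connectivity fragments their diagonal runs.

All convolution-like stages replicate the border pixel, avoiding the dark
frame a zero border would create — a zero frame would produce a spurious
rectangle of Canny edges around every image.

### Numerical and degenerate-input choices

* **Opening element.** Canny outputs contours one pixel wide, and erosion
  with any element larger than a single pixel deletes a one-pixel curve
  entirely.  The opening stage therefore defaults to a unit element
  (identity) and the speck-removal duty falls to `min_component_px`;
  `open_size` ≥ 1 remains available in configuration for solid-blob masks
  where opening is meaningful.
* **Flat-field guard in CLAHE.** After denoising, a field with no cells
  retains only a sub-graylevel noise residue (SD ≈ 0.6 across image
  sizes), while a single stained cell in a 1.2-megapixel frame already
  lifts the global SD above 1.1.  Equalizing a residue-only image would
  amplify sensor noise into full-range structure and produce hundreds of
  phantom domains, so CLAHE passes an input through unchanged when its
  global SD is below `clahe_flat_std` = 1.0 gray level.  This is a
  degenerate-input rule, not a cell detector: any image with real content
  clears the floor by ~2×.
* **Counting rule.** One connected domain = one cell.  Overlapping or
  adherent cells would merge into one domain and undercount; the physical
  workflow prevents adhesion by stirring, and the generator's
  non-overlapping mode enforces a 4 px clearance between disks so that
  two contours can never fuse through 8-adjacency.
* **Half-open health bands.** Band membership is `[low, high)`; no
  reference cow sits on a boundary, but the rule must be pinned for
  determinism.
* **Tie-breaks.** Equal SCC values order by cow id (numerically when the
  id parses as an integer).

## Uniformity statistics

The evenness metric is the standard deviation coefficient
`CV% = 100·s/x̄` with the **sample (n−1)** standard deviation, rounded
**half-up to two decimals**.  Both conventions are established by exact
reproduction of the reference 20-row table: with the population (n)
denominator the first row would give 1.02 % instead of the printed
1.08 %.  The study-level mean CV averages the rounded per-group values
(0.6885 → 0.69, matching the published arithmetic); the unrounded mean is
also exposed.  The 3×3 tiling uses boundaries at `floor(i·H/3)`, so the
nine crops partition the raster exactly even for dimensions not divisible
by three.

## Quantification

One micrograph images a liquid slab of field-of-view length × width ×
channel height; with the default chip geometry
`V = 5802 × 4050 × 40 μm³ = 9.39924×10⁸ μm³ ≈ 0.94 μL`, and
`SCC = mean count / V[μL] × 1000`.  The conversion uses the unrounded
volume — rounding to 0.94 μL first would bias every concentration by
about 0.01 %.

The default health bands (5×10⁵ and 10⁶ cells/mL) are reconstructed from
the reference herd's published milking/treatment split rather than
transcribed from a criteria table: the split falls between the cow at
≈4.99×10⁵ cells/mL (last milked) and the cow at ≈5.59×10⁵ (treated), and
the one cow above 10⁶ is described as clinical.  They are deliberately
configuration-overridable, since SCC criteria differ between studies and
jurisdictions.

## The synthetic generator

`generate_cavity` emulates what the counting method actually consumes:
blue-purple granular nuclei on a light-pink background.  Cells are filled
disks (radius 7 ± 2 px) with multiplicative Gaussian speckle
(σ = 0.08) for nuclear granularity and jittered colours; the image then
receives per-pixel impulse noise (p = 0.002) and additive Gaussian noise
(σ = 5 intensity units).  Placement is uniform, with rejection sampling
(bounded at 10⁵ rejections, after an area feasibility check) when
non-overlap is requested.  All randomness flows from explicit
`numpy.random.default_rng` seeds; regeneration is byte-identical.

Per-group counts come from either a Poisson(mean) draw — the null model
of perfectly mixed cells, CV = 1/√mean — or a fixed count reproducing the
near-zero dispersion a well-stirred chip achieves (the reference study's
CVs ≤ 1.61 % are far below the Poisson CV at the same means).

What the generator does **not** model: optical point-spread blur,
illumination gradients, fat globules and debris, partial staining, and
true cell adhesion.  Passing the synthetic accuracy tests therefore
demonstrates that the pipeline's stages compose correctly and that closed
contours are counted exactly; it does not certify accuracy on real
micrographs, which the physical system validated against flow cytometry.

## Problem sizes

Unit tests run on 240×320 to 480×640 rasters.  The end-to-end accuracy
check uses twenty 960×1280 scenes of 100–800 non-overlapping cells —
cell densities up to ~10 % of the frame area, matching the clinical upper
range at the default cell radius — and requires every image within 3 %
of truth with a mean absolute relative error ≤ 2 %.

## Known limitations

* Overlapping cells count as one domain; watershed-style splitting is out
  of scope.
* A cell contour broken by hysteresis could split into fragments; the
  min-size filter absorbs small fragments but a pathological break could
  double-count.  Not observed on the synthetic corpus.
* The CLAHE flat-field floor assumes denoised sensor noise below one gray
  level; grossly noisier optics would need `clahe_flat_std` retuned.
* The health-band defaults are reconstructed, not transcribed (see
  above); users should supply jurisdiction-specific thresholds.
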