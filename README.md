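# milkscc

Somatic cell counting in raw cow's milk from stained micrographs.

The somatic cell count (SCC, cells per millilitre) of raw milk is the
standard indicator of bovine mastitis: roughly, below 5×10⁵ cells/mL an
udder is healthy or merely suspect, between 5×10⁵ and 10⁶ it suggests
subclinical mastitis, and above 10⁶ clinical mastitis.  One practical way
to measure SCC on-site is to stain a milk sample (Wright's stain renders
cell nuclei blue-purple on a light-pink background), load it into a
microfluidic chip whose channel widens into nine shallow observation
cavities, photograph each cavity under a microscope, and count the cells
in the images.

`milkscc` implements the computational side of that workflow:

* **Counting pipeline** — grayscale conversion
  (`Gray = 0.114·B + 0.587·G + 0.299·R`), median and bilateral filtering,
  unsharp masking, CLAHE, Canny edge detection, morphological opening, and
  connected-domain counting: each closed cell contour is one connected
  domain, so the number of surviving domains is the cell count of the
  image.
* **Uniformity statistics** — the standard deviation coefficient
  (coefficient of variation, `CV = 100·s/x̄` with the sample n−1 standard
  deviation) over a sample's nine per-cavity counts, and over the 81
  counts obtained by cutting each image into a 3×3 grid, quantifies how
  evenly the cells are distributed.
* **Quantification and herd planning** — a mean per-image count converts
  to cells/mL through the imaged volume `V = L × W × h` (default
  5802 × 4050 × 40 μm = 9.39924×10⁸ μm³ ≈ 0.94 μL); cows are classified
  by SCC band and ordered for milking (ascending SCC) and treatment
  (descending SCC).
* **Synthetic image generator** — seeded Wright's-stain-like cavity
  images with exact per-cell ground truth, so every pipeline stage is
  testable without physical samples.

A 20-cow field study (nine counts per cow) ships as a reference counts
table and drives the worked examples.

## Worked example

```sh
$ python examples/count_synthetic_cavity.py
ground truth : 150 cells
pipeline     : 150 connected domains counted
rel. error   : 0.00%
```

The generator drew 150 non-overlapping stained cells plus impulse and
Gaussian noise; the pipeline recovered all 150 as distinct connected
domains.

```sh
$ python examples/herd_plan_from_counts.py
field-of-view volume: 9.39924e+08 um^3 = 0.94 uL
cow 16: 8.34e+05 cells/mL -> subclinical mastitis (treat)
cow 13: 9.6e+05 cells/mL -> subclinical mastitis (treat)
cow 11: 1.16e+06 cells/mL -> clinical mastitis (treat)
milking order  : 20, 6, 9, 2, 12, 4, 1, 18, 3, 14, 5, 10, 15, 17
treatment order: 11, 13, 16, 7, 19, 8
```

Fourteen cows fall below the 5×10⁵ cells/mL split and are queued for
milking, cleanest first; six need treatment, sickest first — cow 11, the
one clinical case at ≈1.16×10⁶ cells/mL, heads the treatment queue.

`examples/uniformity_of_reference_study.py` prints the per-cow CVs of the
reference study (max 1.61 %, min 0.21 %, mean 0.69 % — cells settle evenly
across the nine cavities), and `examples/subtile_uniformity.py` shows the
within-cavity analysis on synthetic groups.

## Command line

The same operations are exposed as a thin CLI:

```sh
scc synth --cells 150 --seed 11 --out cavity.png --truth truth.json
scc count img_1.png ... img_9.png --group cow1 --out-json report.json
scc uniformity counts.csv
scc herd counts.csv --out-csv herd.csv
```

All parameters (filter kernels, Canny thresholds, chip geometry, health
bands) live in a YAML config passed via `--config`; unknown keys are
rejected.

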