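# pcmorph — pavement-cell morphometry

Leaf-epidermis pavement cells grow into jigsaw-puzzle shapes: convex
**lobes** interdigitate with the concave **necks** of neighbouring cells,
and mutants in the pathways that restrict growth at necks develop rounder,
less complex cells with reduced cell-wall deposition.  `pcmorph` is a
tested, reusable pipeline for quantifying this phenotype from
membrane/wall-stained 2-D micrographs:

* **synthcell** — a synthetic generator of lobed-cell mosaics rendered as
  wall-stain and outline-stain TIFF channels with complete ground truth
  (label masks, lobe tips, per-cell wall intensities, flank asymmetries), so
  every downstream stage is testable without microscopy data;
* **segment** — ridge-filter + hysteresis + skeleton segmentation of bright
  anticlinal walls into labeled cell regions, with the standard physical
  size filter (240 µm² default, 75 µm² for very young tissue) and
  border-cell removal;
* **morphometry** — per-cell shape features: area, perimeter, circularity
  `4πA/P²`, lobe count and lobe/basal-lobe lengths from smoothed contour
  curvature, margin roughness (circle-normalized mean |curvature|), and
  min/max core width from the medial axis of the lobe-excised core polygon,
  plus size-class assignment (tiny/small/medium/large at 240/1400/4042 µm²);
* **wallsignal** — per-cell mean boundary fluorescence by 15×15-px window
  attribution of wall-pixel intensities, and convex/concave lobe-flank
  intensity measurement;
* **groupstats** — Kruskal–Wallis + Dunn post-hoc + Benjamini–Hochberg
  comparisons, Welch t-tests, and violin-plot summary statistics;
* **pipeline / CLI** — reproducible end-to-end runs with a YAML config,
  stable CSV contracts and a JSON manifest.

## Worked example

Simulate a two-genotype experiment (wild-type-like: 6 lobes of amplitude
0.35 on a 20 µm core; mutant-like: 4 lobes of amplitude 0.15 on a 23 µm
core with 55% wall intensity), segment and measure it, and compare groups:

```bash
python analysis/01_simulate_dataset.py   # writes TIFFs + ground truth
python analysis/02_shape_pipeline.py     # segment -> features -> statistics
python analysis/03_wall_intensity.py     # boundary + flank intensities
python analysis/04_null_calibration.py   # false-positive rate under the null
```

`02_shape_pipeline.py` prints:

```
segmented 80 cells from 20 images

per-genotype feature means:
          circularity  lobe_count  avg_lobe_length_um  max_core_width_um
genotype
mut             0.952       4.425               3.933             42.138
wt              0.708       6.050               6.467             37.157

genotype comparison (Dunn z, BH-adjusted p):
  circularity              z=+7.70  p_adj=1.38e-14
  lobe_count               z=-8.00  p_adj=1.26e-15
  avg_lobe_length_um       z=-7.70  p_adj=1.38e-14
  max_core_width_um        z=+6.25  p_adj=4.24e-10
```

The mutant-like group is rounder (higher circularity), initiates fewer and
shorter lobes, and has wider cellular cores — each effect recovered with the
programmed sign and significant after multiplicity adjustment.
`03_wall_intensity.py` recovers the programmed intensity contrasts:

```
background-corrected mut/wt ratio: 0.550 (programmed: 0.55)
flank asymmetry over 411 lobes: convex/concave = 1.598 (programmed: 1.6)
```

The same runs are available through the CLI
(`pcmorph simulate`, `pcmorph all --config run.yaml`, `pcmorph segment`,
`pcmorph measure`, `pcmorph compare`); see `pcmorph --help`.

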