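# Methods

`pcmorph` quantifies the shape and wall fluorescence of leaf-epidermis
pavement cells — the jigsaw-puzzle-shaped cells whose interdigitating lobes
and necks are a classic readout of plant cell morphogenesis — and provides a
synthetic image generator so that every stage of the pipeline can be
validated against known ground truth without microscopy data.

## Synthetic cell model

A cell outline is the star-shaped polar curve

    r(θ) = R · (1 + a · b(θ)),   b(θ) ∈ [0, 1],

where `b` is a min–max-normalized sum of `k` periodic von-Mises-like bumps
`exp(κ·(cos(θ−θ_j)−1))` at jittered, equally spaced angles θ_j.  Lobes
protrude *outward* from the base circle: necks lie on radius `R` (so the
lobe-free core is a near-circle of diameter `2R`, making `R` the natural
neck-width control), and tips reach `R·(1+a)`.  Key parameters:

| parameter | unit | default | meaning |
|---|---|---|---|
| `base_radius` | µm | 20 | core/neck radius |
| `lobe_count_true` | – | 6 | number of lobes (0 = circle) |
| `lobe_amplitude` | – | 0.3 | lobe height as fraction of `R`, in [0, 0.9] |
| `lobe_sharpness` | – | 1.5 | bump concentration scale; κ = max(2, sharpness·max(k², 14)) |
| `wall_thickness_um` | µm | 1.2 | rendered anticlinal-wall width |
| `pixel_size` | µm/px | 0.4 | raster resolution |
| `noise_sd` | – | 2 | additive Gaussian noise, clipped at 0 |

Because `r > 0` everywhere the outline is always a simple polygon, and with
`a = 0` it is an exact circle — the analytic anchor used throughout the
tests.  κ scales with `k²` so lobe width tracks lobe spacing; the floor at
`k² = 14` keeps the lobes of few-lobed cells distinct protrusions rather
than broad undulations.  Per-lobe angular (±25% of spacing) and height
(±15%) jitter is seeded; if jitter merges two bumps, the generator retries
with reduced jitter so the outline always has exactly `k` radial maxima
about its centroid.

Mosaics place cells on a grid with spacing derived from the maximal cell
radius plus wall and flank-band widths.  Rendering is fully deterministic
given the spec: the wall band is the set of pixels within half a wall
thickness of the polygon boundaries (per-cell wall intensity is *added* to
the background in the wall-stain channel); the outline channel adds a
flank band adjacent to the wall whose inside:outside intensity ratio is
`flank_asymmetry`, emulating proteins that accumulate on the convex side of
lobes.  Anti-aliasing is off so that noiseless renders are exactly testable.

Two canonical genotype regimes define the simulated experiments: a
wild-type-like regime (6 lobes, amplitude 0.35, R = 20 µm) and a
mutant-like regime (4 lobes, amplitude 0.15, R = 23 µm, 55% wall
intensity).  The mutant-like values were chosen once to mirror the
qualitative phenotype of lobe-initiation mutants — fewer and shorter lobes,
wider necks, strongly reduced cellulose-stain signal — at effect sizes a
confocal experiment of ~10 images per genotype resolves clearly.  Because
amplitude raises area slightly, the two regimes differ moderately in area;
only effect *directions*, not absolute feature values, are treated as
comparable to real data.

### What the generator does not emulate

True interdigitation (a lobe of one cell filling the neck of its
neighbour), curved shared walls between touching cells, uneven illumination,
out-of-focus light, and Poisson photon statistics.  Passing tests therefore
demonstrate correctness of the measurement pipeline on images with the
right *statistical* structure (thin bright walls, controlled lobe geometry,
programmed intensity contrasts), not robustness to every artifact of real
microscopy.

## Segmentation

Walls are enhanced with a Sato tubeness filter at `smoothing_sigma` (1 µm
default, ≈ the wall half-width), binarized by hysteresis thresholding
(high = Otsu of the ridge response, low = half of it), thinned to a one-pixel
skeleton, and cell interiors taken as connected components of the skeleton's
complement (4-connectivity for the complement, since an 8-connected
one-pixel curve does not separate an 8-connected background).  Regions
touching the image border are dropped as incomplete cells, regions below
`min_cell_area` (default 240 µm², reducible to 75 µm² for very young
tissue) are removed, and survivors are renumbered 1..N in raster order of
their centroids, which makes relabeling order-stable.

Contours are traced as the 0.5-level of the region mask (marching squares)
and lightly smoothed along their arc length (σ = 1 px) — raw marching-squares
contours carry a staircase bias that inflates perimeters by ~6% and would
depress circularity of a perfect disk to ≈ 0.90.  After smoothing a
rasterized disk measures circularity 0.991.

## Shape features

* **Area** (shoelace), **perimeter**, **circularity** `4πA/P²`.
* **Curvature** is computed on the arc-length-resampled contour (spacing
  ≈ 0.2 µm) after Gaussian smoothing with `curvature_sigma` (2 µm default),
  using central differences — the discrete derivative-of-Gaussian kernels in
  common filter libraries carry a gain bias of several percent at these
  sigmas.  Smoothing shrinks closed curves, so the smoothed contour is
  rescaled to its original enclosed area before differentiation; a circle of
  any radius then measures curvature 1/R without bias.
* **Lobe detection**: tips are positive-curvature maxima with prominence
  ≥ `min_prominence` (0.05 µm⁻¹) whose curvature also exceeds 1.3× the
  curvature of the cell's equal-area circle — a tip must be more sharply
  convex than the cell outline as a whole, which rejects the gently convex
  stretches between necks.  Each lobe's bases are the nearest local
  curvature minima on either side of the tip.  Detection is invariant to
  rotation and starting vertex; tip/base *coordinates* come from the
  unsmoothed resampled contour so lobe lengths are not shrunk by smoothing.
* **Lobe length** is the distance from the tip to the segment joining the
  two bases; **basal lobe length** the distance from the tip to the base
  midpoint.  Both constructions are deliberately documented here because
  the field uses the terms loosely; with this geometry, mean lobe length
  scales close to linearly with the generator's programmed amplitude
  (amplitude ratio 0.7 is recovered as a length ratio of ≈ 0.7).
* **Margin roughness** is the mean absolute smoothed curvature normalized
  by the equal-area-circle curvature: exactly 1 for a circle, increasing
  with lobing.  Only cross-group *ordering* of this quantity should be
  compared across implementations, as the absolute value depends on the
  smoothing scale.
* **Core widths**: the core polygon is the contour with each lobe arc
  excised and replaced by its base segment.  Widths are maximal
  inscribed-circle diameters along the medial axis of the rasterized core
  (400 px across, seeded tie-breaking for determinism).  The axis is pruned
  by iterative endpoint removal up to the maximal inscribed radius, and only
  the component carrying the global distance maximum is kept — discrete
  medial axes of near-circular cores otherwise leave boundary spurs and loop
  artifacts that corrupt the minimum.  A disk of radius r yields
  max = min = 2r within 3%.
* **Size classes**: lower-inclusive intervals tiny [75, 240), small
  [240, 1400), medium [1400, 4042), large [4042, ∞) µm²; below 75 µm² a
  cell is flagged `excluded`.  4042 is used for the medium/large threshold
  where sources disagree between 4040 and 4042.

## Wall-signal quantification

A **boundary pixel** is a background pixel 8-adjacent to at least one
labeled region — i.e. the wall network itself, since the wall is the
stained object.  For each boundary pixel, every label present in the
centered 15×15 px window (clipped at image edges, not wrapped) receives the
pixel's intensity in its running sum and a +1 on its counter; a cell's mean
boundary intensity is sum/counter.  The implementation is vectorized per
label but verified to machine precision against an explicit window-scan
oracle.

**Flank intensities**: each lobe's flank band starts `wall_clearance`
(1.2 µm ≈ wall half-thickness + ~1.5 px of tracing slack) from the lobe arc
and extends `band_width` (1.5 µm) outward, minus a clearance zone around
the *entire* outline (the buffer's end caps would otherwise pick up wall
pixels of the contour past the lobe bases).  The part inside the cell
polygon is the convex ROI, the part outside the concave ROI; both are
sampled at pixel centers.

## Statistics

Shape features: Kruskal–Wallis (tie-corrected) omnibus, Dunn's post-hoc z
on pooled ranks with tie correction, Benjamini–Hochberg adjustment applied
within each feature across its pairwise comparisons (configurable to one
global family).  Flank intensities: Welch's t-test with
Welch–Satterthwaite df.  Summaries report median, mean, sample SD (n−1) and
a normal-approximation 95% CI of the mean (mean ± 1.96·SD/√n); with n = 1,
SD and CI are reported as missing.  Cells are pooled across images by
default, with `image_id` retained in every row for sensitivity analyses
that treat images as replicates.

Under the null (both groups drawn from the same shape distribution,
20 cells per group, 20 replicates) the fraction of features reaching
BH-adjusted p ≤ 0.05 stays at the nominal level (≤ 10% is asserted in the
test suite).

## Problem sizes

The simulated experiments use 10 images per genotype with 2×2 interior
cells at 0.4 µm/px (~330×330 px per image) — a desk-scale stand-in chosen
to keep a full two-genotype run (~80 cells) clearly powered for the
programmed effects while the whole validation suite runs in minutes.  The
null calibration runs on generator polygons directly (no rasterization),
since it exercises the statistics layer, not the imaging chain.

## Known limitations

* Segmentation assumes walls brighter than interiors; dark-wall images must
  be inverted upstream.
* Lobe detection on strongly under-resolved lobes (arc width ≲ the 2 µm
  curvature sigma) undercounts; the generator's κ floor keeps synthetic
  lobes above this scale.
* The boundary-intensity readout does not subtract background; programmed
  intensity ratios are recovered exactly only after background correction,
  which is left to the caller (the analysis scripts subtract the known
  rendered background).
* Core widths depend mildly on the rasterization resolution (`raster_n`);
  the default (400) keeps the discretization error under ~2% for cells in
  the 10–50 µm range.
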