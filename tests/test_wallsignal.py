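"""Boundary-intensity attribution and lobe-flank measurement.

The brute-force oracle below re-implements the window-attribution rule as a
plain double loop with no shared code, and is the reference for the
vectorized implementation.
"""

import numpy as np
import pytest

from pcmorph.images import IntensityImage, LabelImage
from pcmorph.morphometry import detect_lobes
from pcmorph.segment import SegmentationConfig, extract_contour, segment_cells
from pcmorph.synthcell import CellShapeSpec, MosaicSpec, generate_mosaic
from pcmorph.wallsignal import boundary_mean_intensity, lobe_flank_intensity


def brute_force_boundary_means(lab: np.ndarray, sig: np.ndarray, k: int) -> dict:
    """Independent oracle: explicit window scan over all boundary pixels."""
    h = k // 2
    nrow, ncol = lab.shape
    sums: dict = {}
    counts: dict = {}
    for r in range(nrow):
        for c in range(ncol):
            if lab[r, c] != 0:
                continue
            adjacent = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrow and 0 <= cc < ncol and lab[rr, cc] > 0:
                        adjacent = True
            if not adjacent:
                continue
            labels_in_window = set()
            for rr in range(max(0, r - h), min(nrow, r + h + 1)):
                for cc in range(max(0, c - h), min(ncol, c + h + 1)):
                    if lab[rr, cc] > 0:
                        labels_in_window.add(int(lab[rr, cc]))
            for label in labels_in_window:
                sums[label] = sums.get(label, 0.0) + sig[r, c]
                counts[label] = counts.get(label, 0) + 1
    return {
        label: (sums[label], counts[label], sums[label] / counts[label])
        for label in sums
    }


def test_constant_signal_gives_constant_means(ramp_wall_toy):
    labels, _ = ramp_wall_toy
    sig = IntensityImage(np.full(labels.shape, 4.5), labels.pixel_size)
    for rec in boundary_mean_intensity(labels, sig):
        assert rec.mean_boundary_intensity == pytest.approx(4.5)


def test_toy_ramp_matches_brute_force(ramp_wall_toy):
    labels, sig = ramp_wall_toy
    oracle = brute_force_boundary_means(labels.labels, sig.pixels, 15)
    for rec in boundary_mean_intensity(labels, sig, neighborhood=15):
        s, n, m = oracle[rec.cell_id]
        assert rec.intensity_sum == pytest.approx(s, abs=1e-12)
        assert rec.contributing_pixels == n
        assert rec.mean_boundary_intensity == pytest.approx(m, rel=1e-14)


@pytest.mark.parametrize("trial", range(6))
def test_random_toy_images_match_brute_force(trial):
    rng = np.random.default_rng(trial)
    nrow, ncol = rng.integers(24, 64, size=2)
    lab = np.zeros((nrow, ncol), dtype=np.int32)
    lab[2 : nrow // 2 - 2, 2 : ncol // 2 - 1] = 1
    lab[nrow // 2 + 1 : nrow - 2, 3 : ncol - 4] = 2
    lab[4 : nrow // 2 - 3, ncol // 2 + 2 : ncol - 2] = 3
    sig = rng.uniform(0.0, 255.0, size=(nrow, ncol))
    k = int(rng.choice([3, 7, 15]))
    oracle = brute_force_boundary_means(lab, sig, k)
    recs = boundary_mean_intensity(LabelImage(lab, 1.0), IntensityImage(sig, 1.0), k)
    assert {r.cell_id for r in recs} == set(oracle)
    for rec in recs:
        s, n, _ = oracle[rec.cell_id]
        assert rec.intensity_sum == pytest.approx(s, abs=1e-9)
        assert rec.contributing_pixels == n


def test_linearity_in_signal(ramp_wall_toy):
    labels, sig = ramp_wall_toy
    base = boundary_mean_intensity(labels, sig)
    scaled = boundary_mean_intensity(
        labels, IntensityImage(sig.pixels * 3.0, sig.pixel_size)
    )
    for a, b in zip(base, scaled):
        assert b.mean_boundary_intensity == pytest.approx(3.0 * a.mean_boundary_intensity)


def test_locality_of_attribution(ramp_wall_toy):
    labels, sig = ramp_wall_toy
    before = {r.cell_id: r for r in boundary_mean_intensity(labels, sig, 7)}
    # pixels in the far corner are beyond the window of cell 1's boundary
    perturbed = sig.pixels.copy()
    perturbed[0, 0] += 1000.0  # interior of region 1, not a boundary pixel
    after = {
        r.cell_id: r
        for r in boundary_mean_intensity(
            labels, IntensityImage(perturbed, sig.pixel_size), 7
        )
    }
    for cid in before:
        assert after[cid].intensity_sum == pytest.approx(before[cid].intensity_sum)


def test_shape_mismatch_and_bad_window_rejected(ramp_wall_toy):
    labels, sig = ramp_wall_toy
    with pytest.raises(ValueError):
        boundary_mean_intensity(labels, IntensityImage(np.zeros((5, 5)), 1.0))
    with pytest.raises(ValueError):
        boundary_mean_intensity(labels, sig, neighborhood=4)


def test_wall_multiplier_recovered_through_segmentation():
    """A programmed 0.55 wall-intensity ratio is recovered within 0.05."""
    means = {0.55: [], 1.0: []}
    spec = MosaicSpec(
        cells=tuple(CellShapeSpec(seed=i, lobe_amplitude=0.35) for i in range(4)),
        grid_shape=(2, 2),
        wall_intensity_per_cell={1: 100.0, 2: 55.0, 3: 55.0, 4: 100.0},
        background_intensity=0.0,
        noise_sd=2.0,
        seed=21,
    )
    wall, outline, truth_labels, truth = generate_mosaic(spec)
    seg = segment_cells(outline, SegmentationConfig())
    recs = {r.cell_id: r for r in boundary_mean_intensity(seg, wall)}
    from scipy import ndimage

    cents = ndimage.center_of_mass(seg.labels > 0, seg.labels, seg.cell_ids)
    for cid, (crow, ccol) in zip(seg.cell_ids, cents):
        pos = np.array([ccol, crow]) * seg.pixel_size
        nearest = min(
            truth.cells.values(), key=lambda ct: np.hypot(*(ct.center_um - pos))
        )
        means[nearest.wall_multiplier].append(recs[cid].mean_boundary_intensity)
    ratio = np.mean(means[0.55]) / np.mean(means[1.0])
    assert ratio == pytest.approx(0.55, abs=0.05)


def test_uniform_signal_gives_equal_flanks(noiseless_mosaic):
    seg = segment_cells(noiseless_mosaic["outline"], SegmentationConfig())
    contour = extract_contour(seg, 1)
    lobes = detect_lobes(contour)
    uniform = IntensityImage(
        np.full(seg.shape, 11.0), noiseless_mosaic["outline"].pixel_size
    )
    recs = lobe_flank_intensity(contour, lobes, uniform)
    assert recs
    for rec in recs:
        assert rec.convex_mean == pytest.approx(rec.concave_mean)
        assert rec.convex_mean == pytest.approx(11.0)


def test_zero_signal_gives_zero_flanks(noiseless_mosaic):
    seg = segment_cells(noiseless_mosaic["outline"], SegmentationConfig())
    contour = extract_contour(seg, 1)
    lobes = detect_lobes(contour)
    zero = IntensityImage(np.zeros(seg.shape), noiseless_mosaic["outline"].pixel_size)
    for rec in lobe_flank_intensity(contour, lobes, zero):
        assert rec.convex_mean == 0.0
        assert rec.concave_mean == 0.0


def test_programmed_flank_asymmetry_recovered():
    """A programmed 1.6 convex/concave ratio is recovered within 0.1 over >= 25 lobes."""
    conv, conc = [], []
    for im in range(2):
        spec = MosaicSpec(
            cells=tuple(
                CellShapeSpec(seed=10 * im + i, lobe_amplitude=0.35) for i in range(4)
            ),
            grid_shape=(2, 2),
            flank_asymmetry=1.6,
            noise_sd=2.0,
            seed=im,
        )
        _, outline, _, _ = generate_mosaic(spec)
        seg = segment_cells(outline, SegmentationConfig())
        for cid in seg.cell_ids:
            contour = extract_contour(seg, cid)
            for rec in lobe_flank_intensity(contour, detect_lobes(contour), outline):
                conv.append(rec.convex_mean)
                conc.append(rec.concave_mean)
    assert len(conv) >= 25
    assert np.mean(conv) / np.mean(conc) == pytest.approx(1.6, abs=0.1)
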