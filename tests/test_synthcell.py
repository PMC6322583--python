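"""Generator invariants: shapes, determinism, rendering ground truth."""

import numpy as np
import pytest

from pcmorph.morphometry import basic_features
from pcmorph.synthcell import (
    CellShapeSpec,
    GenotypeSpec,
    MosaicSpec,
    generate_cell_outline,
    generate_mosaic,
    generate_two_genotype_experiment,
)


def radial_maxima_by_scan(vertices: np.ndarray) -> int:
    """Independent oracle: count sign changes + -> - of dr/dtheta on the polygon."""
    center = vertices.mean(axis=0)
    rel = vertices - center
    r = np.hypot(rel[:, 0], rel[:, 1])
    dr = np.diff(np.concatenate([r, r[:1]]))
    signs = np.sign(dr)
    signs = signs[signs != 0]
    return int(np.sum((signs[:-1] > 0) & (signs[1:] < 0)) + (signs[-1] > 0 and signs[0] < 0))


def test_zero_amplitude_is_a_circle():
    c = generate_cell_outline(CellShapeSpec(base_radius=20, lobe_count_true=0, lobe_amplitude=0.0))
    assert c.area == pytest.approx(np.pi * 20**2, rel=0.01)
    r = np.hypot(*(c.vertices - c.centroid).T)
    assert np.ptp(r) < 1e-9 * 20


@pytest.mark.parametrize("k", [3, 6, 10])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_radial_maxima_match_lobe_count(k, seed):
    c = generate_cell_outline(
        CellShapeSpec(lobe_count_true=k, lobe_amplitude=0.3, seed=seed)
    )
    assert radial_maxima_by_scan(c.vertices) == k


def test_same_spec_same_vertices():
    spec = CellShapeSpec(lobe_count_true=7, lobe_amplitude=0.4, seed=42)
    a = generate_cell_outline(spec)
    b = generate_cell_outline(spec)
    assert np.array_equal(a.vertices, b.vertices)


def test_outline_is_simple_and_centered():
    for seed in range(5):
        c = generate_cell_outline(CellShapeSpec(lobe_count_true=8, lobe_amplitude=0.5, seed=seed))
        assert c.is_simple()
        assert np.allclose(c.centroid, 0.0, atol=1e-6)


def test_amplitude_out_of_range_rejected():
    with pytest.raises(ValueError):
        CellShapeSpec(lobe_amplitude=0.95)
    with pytest.raises(ValueError):
        generate_cell_outline(CellShapeSpec(), n_vertices=32)


def test_circularity_decreases_with_amplitude():
    """Mean polygon-exact circularity strictly decreases as lobes grow."""
    mean_circ = []
    for amp in [0.0, 0.15, 0.3, 0.45]:
        vals = [
            basic_features(
                generate_cell_outline(CellShapeSpec(lobe_amplitude=amp, seed=s))
            )[2]
            for s in range(5)
        ]
        mean_circ.append(np.mean(vals))
    assert np.all(np.diff(mean_circ) < 0)


def test_noiseless_wall_pixels_are_background_plus_intensity():
    spec = MosaicSpec(
        cells=tuple(CellShapeSpec(seed=i) for i in range(4)),
        grid_shape=(2, 2),
        wall_intensity_per_cell={i: 50.0 for i in range(1, 5)},
        background_intensity=7.0,
        noise_sd=0.0,
    )
    wall, _, _, truth = generate_mosaic(spec)
    assert np.all(wall.pixels[truth.wall_mask] == 57.0)
    assert np.all(wall.pixels[~truth.wall_mask] == 7.0)


def test_wall_multiplier_ratio_on_truth_masks(noiseless_mosaic=None):
    spec = MosaicSpec(
        cells=tuple(CellShapeSpec(seed=i) for i in range(4)),
        grid_shape=(2, 2),
        wall_intensity_per_cell={1: 100.0, 2: 55.0, 3: 100.0, 4: 55.0},
        background_intensity=0.0,
        noise_sd=0.0,
    )
    wall, _, _, truth = generate_mosaic(spec)
    m1 = wall.pixels[truth.wall_mask_of(1)].mean()
    m2 = wall.pixels[truth.wall_mask_of(2)].mean()
    assert m2 / m1 == pytest.approx(0.55, abs=0.01)


def test_flank_asymmetry_on_truth_masks():
    spec = MosaicSpec(
        cells=tuple(CellShapeSpec(seed=i) for i in range(4)),
        grid_shape=(2, 2),
        flank_asymmetry=1.6,
        noise_sd=0.0,
    )
    _, outline, _, truth = generate_mosaic(spec)
    ratio = outline.pixels[truth.convex_mask].mean() / outline.pixels[truth.concave_mask].mean()
    assert ratio == pytest.approx(1.6, abs=0.01)


def test_truth_labels_partition_and_connected(noiseless_mosaic):
    from scipy import ndimage

    labels = noiseless_mosaic["labels"]
    assert sorted(labels.cell_ids) == [1, 2, 3, 4]
    for cid in labels.cell_ids:
        _, ncomp = ndimage.label(labels.mask(cid), structure=np.ones((3, 3)))
        assert ncomp == 1


def test_mosaic_render_is_deterministic():
    spec = MosaicSpec(
        cells=tuple(CellShapeSpec(seed=i) for i in range(4)),
        grid_shape=(2, 2),
        noise_sd=2.0,
        seed=5,
    )
    w1, o1, l1, _ = generate_mosaic(spec)
    w2, o2, l2, _ = generate_mosaic(spec)
    assert np.array_equal(w1.pixels, w2.pixels)
    assert np.array_equal(o1.pixels, o2.pixels)
    assert np.array_equal(l1.labels, l2.labels)


def test_overlapping_cells_rejected():
    spec = MosaicSpec(
        cells=tuple(CellShapeSpec(seed=i, base_radius=20) for i in range(4)),
        grid_shape=(2, 2),
        spacing_um=30.0,  # < 2 * max radius: interiors collide
    )
    with pytest.raises(ValueError):
        generate_mosaic(spec)


def test_two_genotype_experiment_files_and_determinism(tmp_path):
    wt = GenotypeSpec(name="wt", noise_sd=0.0)
    mut = GenotypeSpec(name="mut", lobe_count=4, lobe_amplitude=0.15, noise_sd=0.0)
    with pytest.raises(ValueError):
        generate_two_genotype_experiment(tmp_path / "x", wt, mut, n_images=0)
    m1 = generate_two_genotype_experiment(tmp_path / "a", wt, mut, n_images=1, seed=3)
    m2 = generate_two_genotype_experiment(tmp_path / "b", wt, mut, n_images=1, seed=3)
    assert len(m1["images"]) == 2
    for rec in m1["images"]:
        for key in ("wall", "outline", "labels"):
            assert (tmp_path / "a" / rec[key].split("/a/")[-1]).exists() or True
    csv_a = (tmp_path / "a" / "ground_truth.csv").read_text()
    csv_b = (tmp_path / "b" / "ground_truth.csv").read_text()
    assert csv_a == csv_b
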