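"""Shape features: closed forms, generator ground truth, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcmorph.contour import Contour
from pcmorph.morphometry import (
    SizeClassConfig,
    assign_size_class,
    basic_features,
    compute_features,
    core_widths,
    detect_lobes,
    lobe_geometry,
    lobe_metrics,
    margin_roughness,
)
from pcmorph.segment import extract_contour
from pcmorph.synthcell import CellShapeSpec, generate_cell_outline


def square(side=10.0):
    return Contour(np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float))


def test_square_circularity_closed_form():
    area, perimeter, circ = basic_features(square(7.0))
    assert area == pytest.approx(49.0)
    assert perimeter == pytest.approx(28.0)
    assert circ == pytest.approx(np.pi / 4, rel=1e-12)


def test_rasterized_disk_circularity_near_one(disk_label_image):
    c = extract_contour(disk_label_image, 1)
    _, _, circ = basic_features(c)
    assert circ == pytest.approx(1.0, abs=0.02)


def test_degenerate_polygon_rejected():
    with pytest.raises(ValueError):
        Contour(np.array([[0, 0], [1, 0], [2, 0]], dtype=float))


def test_circularity_matches_polygon_exact_value_after_rasterization():
    """Raster -> extraction reproduces the generator-vertex circularity within 1%."""
    from skimage.draw import polygon as draw_polygon

    from pcmorph.images import LabelImage

    spec = CellShapeSpec(lobe_count_true=6, lobe_amplitude=0.3, seed=4)
    poly = generate_cell_outline(spec, n_vertices=512)
    exact = basic_features(poly)[2]
    ps = 0.2
    verts = poly.vertices - poly.vertices.min(axis=0) + 4.0
    shape = (int(verts[:, 1].max() / ps) + 40, int(verts[:, 0].max() / ps) + 40)
    lab = np.zeros(shape, dtype=np.int32)
    rr, cc = draw_polygon(verts[:, 1] / ps, verts[:, 0] / ps, shape)
    lab[rr, cc] = 1
    measured = basic_features(extract_contour(LabelImage(lab, ps), 1))[2]
    assert measured == pytest.approx(exact, rel=0.01)


def test_circle_has_no_lobes():
    c = generate_cell_outline(CellShapeSpec(lobe_count_true=0, lobe_amplitude=0.0))
    assert detect_lobes(c) == []


@pytest.mark.parametrize("k", [3, 4, 6, 8, 10])
def test_lobe_count_recovers_generator_truth(k):
    for seed in range(3):
        c = generate_cell_outline(CellShapeSpec(lobe_count_true=k, lobe_amplitude=0.3, seed=seed))
        assert len(detect_lobes(c)) == k


def test_lobe_detection_threshold_is_monotone():
    """Sub-threshold undulations give 0 lobes; detection is monotone in amplitude."""
    detected = []
    for amp in [0.0, 0.02, 0.1, 0.2, 0.35]:
        c = generate_cell_outline(CellShapeSpec(lobe_count_true=6, lobe_amplitude=amp, seed=2))
        detected.append(len(detect_lobes(c)))
    assert detected[0] == 0 and detected[1] == 0
    assert np.all(np.diff(detected) >= 0)
    assert detected[-1] == 6


def test_short_contour_warns_and_returns_nothing():
    tiny = Contour(np.array([[0, 0], [1.0, 0], [1.0, 1.0], [0, 1.0]]) * 0.5)
    with pytest.warns(UserWarning, match="shorter"):
        assert detect_lobes(tiny, curvature_sigma=2.0) == []


def test_lobe_geometry_equilateral_case():
    length, basal = lobe_geometry([0.0, 10.0], [-5.0, 0.0], [5.0, 0.0])
    assert length == pytest.approx(10.0)
    assert basal == pytest.approx(10.0)


def test_lobe_metrics_empty_list():
    assert lobe_metrics([]) == (0.0, 0.0)


def test_avg_lobe_length_tracks_amplitude():
    """Amplitudes 0.35 vs 0.245 (30% lower) give a ~0.7 length ratio."""
    means = []
    for amp in [0.35, 0.245]:
        lens = []
        for seed in range(20):
            c = generate_cell_outline(CellShapeSpec(lobe_count_true=6, lobe_amplitude=amp, seed=seed))
            lens.append(lobe_metrics(detect_lobes(c))[0])
        means.append(np.mean(lens))
    assert means[1] / means[0] == pytest.approx(0.70, abs=0.05)


def test_margin_roughness_circle_is_one():
    for radius in [10.0, 30.0]:
        c = generate_cell_outline(CellShapeSpec(base_radius=radius, lobe_count_true=0, lobe_amplitude=0.0))
        assert margin_roughness(c) == pytest.approx(1.0, abs=0.02)


def test_margin_roughness_increases_with_lobing():
    r_high = margin_roughness(generate_cell_outline(CellShapeSpec(lobe_amplitude=0.3)))
    r_low = margin_roughness(generate_cell_outline(CellShapeSpec(lobe_amplitude=0.1)))
    assert r_high > r_low > 1.0


def test_margin_roughness_square_is_finite():
    assert np.isfinite(margin_roughness(square(20.0)))


def test_core_widths_disk():
    c = generate_cell_outline(CellShapeSpec(base_radius=20.0, lobe_count_true=0, lobe_amplitude=0.0))
    wmax, wmin = core_widths(c, [])
    assert wmax == pytest.approx(40.0, rel=0.03)
    assert wmin == pytest.approx(40.0, rel=0.03)


def test_core_width_matches_base_circle():
    c = generate_cell_outline(CellShapeSpec(base_radius=20.0, lobe_count_true=6, lobe_amplitude=0.3))
    wmax, _ = core_widths(c, detect_lobes(c))
    assert wmax == pytest.approx(40.0, rel=0.10)


def test_core_width_direction_mutant_vs_wildtype():
    """Wider-necked mutant-like cells have larger max core width."""
    wt, mut = [], []
    for seed in range(10):
        cw = generate_cell_outline(CellShapeSpec(base_radius=20, lobe_count_true=6, lobe_amplitude=0.35, seed=seed))
        cm = generate_cell_outline(CellShapeSpec(base_radius=23, lobe_count_true=4, lobe_amplitude=0.15, seed=seed))
        wt.append(core_widths(cw, detect_lobes(cw))[0])
        mut.append(core_widths(cm, detect_lobes(cm))[0])
    assert np.mean(mut) > np.mean(wt)


@pytest.mark.parametrize(
    "area,expected",
    [
        (100, "tiny"),
        (240, "small"),
        (1399.9, "small"),
        (1400, "medium"),
        (4041.9, "medium"),
        (4042, "large"),
        (5000, "large"),
        (74, "excluded"),
    ],
)
def test_size_class_boundaries(area, expected):
    assert assign_size_class(area) == expected


def test_size_class_rejects_nonpositive_area():
    with pytest.raises(ValueError):
        assign_size_class(0.0)
    with pytest.raises(ValueError):
        SizeClassConfig(t_tiny=50)  # violates tiny_floor < t_tiny


def test_features_invariant_under_rigid_motion():
    c = generate_cell_outline(CellShapeSpec(lobe_count_true=6, lobe_amplitude=0.3, seed=9))
    f0 = compute_features(c)
    moved = compute_features(c.rotated(0.7).translated(31.0, -12.0))
    assert moved.area == pytest.approx(f0.area, rel=0.01)
    assert moved.perimeter == pytest.approx(f0.perimeter, rel=0.01)
    assert moved.circularity == pytest.approx(f0.circularity, rel=0.01)
    assert moved.lobe_count == f0.lobe_count
    assert moved.avg_lobe_length == pytest.approx(f0.avg_lobe_length, rel=0.01)
    assert moved.margin_roughness == pytest.approx(f0.margin_roughness, rel=0.01)
    assert moved.max_core_width == pytest.approx(f0.max_core_width, rel=0.01)


def test_feature_scaling_with_uniform_scale():
    c = generate_cell_outline(CellShapeSpec(lobe_count_true=5, lobe_amplitude=0.3, seed=3))
    s = 2.5
    a0, p0, circ0 = basic_features(c)
    a1, p1, circ1 = basic_features(c.scaled(s))
    assert a1 == pytest.approx(a0 * s**2, rel=1e-9)
    assert p1 == pytest.approx(p0 * s, rel=1e-9)
    assert circ1 == pytest.approx(circ0, rel=1e-9)
    # curvature-based features scale their sigma with the contour
    r0 = margin_roughness(c, curvature_sigma=2.0)
    r1 = margin_roughness(c.scaled(s), curvature_sigma=2.0 * s)
    assert r1 == pytest.approx(r0, rel=0.01)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    k=st.integers(min_value=0, max_value=10),
    amp=st.floats(min_value=0.0, max_value=0.5),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_feature_invariants_hold_for_random_cells(k, amp, seed):
    c = generate_cell_outline(CellShapeSpec(lobe_count_true=k, lobe_amplitude=amp, seed=seed))
    f = compute_features(c)
    assert 0 < f.circularity <= 1.0 + 1e-6
    assert f.lobe_count >= 0
    assert f.max_core_width >= f.min_core_width > 0
    assert f.area > 0 and f.perimeter > 0
    assert f.avg_lobe_length >= 0
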