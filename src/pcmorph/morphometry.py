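"""Per-cell shape features of pavement-cell contours.

Features follow the standard pavement-cell morphometry vocabulary:

- **circularity** ``4πA/P²`` — 1 for a circle, decreasing with lobing;
- **lobe count** — convex protrusions, detected as prominence-thresholded
  maxima of the smoothed signed contour curvature, with the flanking
  curvature minima (necks) as lobe bases;
- **average lobe length** — tip to base-segment distance, averaged over lobes;
- **average basal lobe length** — tip to base-midpoint distance;
- **margin roughness** — mean absolute curvature along the smoothed contour,
  normalized by the curvature of the equal-area circle (circle → 1);
- **max/min core width** — maximal-inscribed-circle diameters along the
  medial axis of the cell *core*, i.e. the contour with each lobe excised and
  replaced by its base segment (a proxy for neck-region growth restriction);
- **size class** — area-based grouping (tiny/small/medium/large) used to
  compare cells at similar expansion stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.draw import polygon as draw_polygon
from skimage.morphology import medial_axis

from pcmorph.contour import Contour, resample_closed

__all__ = [
    "SizeClassConfig",
    "LobeRecord",
    "ShapeFeatures",
    "basic_features",
    "detect_lobes",
    "lobe_geometry",
    "lobe_metrics",
    "margin_roughness",
    "core_widths",
    "assign_size_class",
    "compute_features",
    "features_table",
]

DEFAULT_CURVATURE_SIGMA = 2.0  # µm
DEFAULT_MIN_PROMINENCE = 0.05  # µm^-1


@dataclass(frozen=True)
class SizeClassConfig:
    """Area thresholds (µm²) for the size classes.

    Intervals are lower-inclusive: tiny [tiny_floor, t_tiny), small
    [t_tiny, t_small), medium [t_small, t_medium), large [t_medium, ∞).
    Cells below ``tiny_floor`` are flagged ``excluded``.
    """

    tiny_floor: float = 75.0
    t_tiny: float = 240.0
    t_small: float = 1400.0
    t_medium: float = 4042.0

    def __post_init__(self) -> None:
        if not (self.tiny_floor < self.t_tiny < self.t_small < self.t_medium):
            raise ValueError("size thresholds must satisfy tiny_floor < t_tiny < t_small < t_medium")


@dataclass(frozen=True)
class LobeRecord:
    """One detected lobe: tip, flanking base (neck) points and lengths (µm)."""

    tip: np.ndarray
    flank_base_1: np.ndarray
    flank_base_2: np.ndarray
    length: float
    basal_length: float
    tip_idx: int = -1  # indices into the arc-length-resampled contour
    base1_idx: int = -1
    base2_idx: int = -1
    arc: np.ndarray | None = None  # polyline base1 -> tip -> base2 (µm)


@dataclass(frozen=True)
class ShapeFeatures:
    """Full morphometric record of one cell."""

    cell_id: int
    area: float
    perimeter: float
    circularity: float
    lobe_count: int
    avg_lobe_length: float
    avg_basal_lobe_length: float
    margin_roughness: float
    max_core_width: float
    min_core_width: float
    size_class: str


def basic_features(contour: Contour) -> tuple[float, float, float]:
    """Area (shoelace, µm²), perimeter (µm) and circularity ``4πA/P²``."""
    area = contour.area
    perimeter = contour.perimeter
    if area <= 0 or perimeter <= 0:
        raise ValueError("degenerate polygon: zero area or perimeter")
    circ = 4.0 * np.pi * area / perimeter**2
    return area, perimeter, circ


def _resample_count(contour: Contour, target_spacing: float = 0.2) -> int:
    n = int(np.ceil(contour.perimeter / target_spacing))
    return int(np.clip(n, 256, 4096))


def _smoothed_curvature(
    contour: Contour, curvature_sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Signed curvature (µm⁻¹) on the arc-length-resampled contour.

    Returns ``(points, kappa)`` where ``points`` are the *unsmoothed*
    resampled contour points (so tip/base coordinates are not shrunk by the
    smoothing) and ``kappa`` is the curvature of the Gaussian-smoothed
    contour at those arc positions; positive curvature is convex (outward)
    for the counter-clockwise contours this package produces.
    """
    n = _resample_count(contour)
    pts = resample_closed(contour.vertices, n)
    spacing = contour.perimeter / n
    sig = max(curvature_sigma / spacing, 0.5)
    # smooth coordinates, then central differences: the discrete
    # derivative-of-Gaussian kernels carry a substantial gain bias
    xs = gaussian_filter1d(pts[:, 0], sig, mode="wrap")
    ys = gaussian_filter1d(pts[:, 1], sig, mode="wrap")
    # Gaussian smoothing shrinks closed curves (a circle of radius R becomes
    # one of radius R·exp(−σ²/2R²)); rescale to the original enclosed area so
    # curvatures stay unbiased at any cell size
    area0 = abs(_shoelace_xy(pts[:, 0], pts[:, 1]))
    area1 = abs(_shoelace_xy(xs, ys))
    if area1 > 0:
        s = np.sqrt(area0 / area1)
        xs = xs.mean() + (xs - xs.mean()) * s
        ys = ys.mean() + (ys - ys.mean()) * s
    x1 = _cdiff(xs) / spacing
    y1 = _cdiff(ys) / spacing
    x2 = _cdiff(x1) / spacing
    y2 = _cdiff(y1) / spacing
    denom = np.power(x1**2 + y1**2, 1.5)
    denom = np.where(denom > 0, denom, np.inf)
    kappa = (x1 * y2 - y1 * x2) / denom
    return pts, kappa


def _cdiff(v: np.ndarray) -> np.ndarray:
    return (np.roll(v, -1) - np.roll(v, 1)) / 2.0


def _shoelace_xy(x: np.ndarray, y: np.ndarray) -> float:
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _circular_peaks(values: np.ndarray, prominence: float) -> np.ndarray:
    """Indices of peaks of a circular signal with the given prominence."""
    n = len(values)
    tiled = np.concatenate([values, values, values])
    idx, _ = find_peaks(tiled, prominence=prominence)
    idx = idx[(idx >= n) & (idx < 2 * n)] - n
    return np.sort(idx)


def detect_lobes(
    contour: Contour,
    curvature_sigma: float = DEFAULT_CURVATURE_SIGMA,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    tip_min_rel_curvature: float = 1.3,
) -> list[LobeRecord]:
    """Detect lobes as prominent convex curvature maxima along the contour.

    Tips are positive-curvature maxima with prominence ≥ ``min_prominence``
    (µm⁻¹) whose curvature also exceeds ``tip_min_rel_curvature`` times the
    curvature of the cell's equal-area circle — a tip must be more sharply
    convex than the cell outline as a whole, which rejects gently convex
    stretches between necks.  The bases of each lobe are its flanking
    curvature minima: the nearest local curvature minimum on either side of
    the tip (the neck shoulder where the protrusion meets the cell body).
    Detection is invariant to rotation and to the contour's starting vertex.
    """
    if contour.perimeter < 3.0 * curvature_sigma:
        warnings.warn("contour shorter than 3x curvature_sigma; no lobes detected")
        return []
    pts, kappa = _smoothed_curvature(contour, curvature_sigma)
    tips = _circular_peaks(kappa, min_prominence)
    kappa_eq = np.sqrt(np.pi / contour.area)  # 1 / equal-area-circle radius
    tips = tips[kappa[tips] > tip_min_rel_curvature * kappa_eq]
    k = len(tips)
    if k == 0:
        return []
    n = len(pts)

    # all local curvature minima; the flanking pair of each tip are its bases
    prev, nxt = np.roll(kappa, 1), np.roll(kappa, -1)
    minima = np.where((kappa < prev) & (kappa <= nxt))[0]
    if len(minima) == 0:
        return []

    records = []
    for j in range(k):
        t = tips[j]
        d_fwd = (minima - t) % n
        d_bwd = (t - minima) % n
        b2 = int(minima[np.argmin(np.where(d_fwd == 0, n, d_fwd))])
        b1 = int(minima[np.argmin(np.where(d_bwd == 0, n, d_bwd))])
        tip = pts[t]
        p1, p2 = pts[b1], pts[b2]
        length, basal = lobe_geometry(tip, p1, p2)
        arc = pts[np.arange(b1, b2 if b2 > b1 else b2 + n) % n]
        records.append(
            LobeRecord(
                tip=tip,
                flank_base_1=p1,
                flank_base_2=p2,
                length=length,
                basal_length=basal,
                tip_idx=int(t),
                base1_idx=b1,
                base2_idx=b2,
                arc=arc,
            )
        )
    return records


def lobe_geometry(
    tip: np.ndarray, base1: np.ndarray, base2: np.ndarray
) -> tuple[float, float]:
    """Lobe length (tip to base segment) and basal length (tip to base midpoint)."""
    tip = np.asarray(tip, dtype=float)
    base1 = np.asarray(base1, dtype=float)
    base2 = np.asarray(base2, dtype=float)
    length = _point_segment_distance(tip, base1, base2)
    basal = float(np.hypot(*(tip - 0.5 * (base1 + base2))))
    return length, basal


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.hypot(*(p - a)))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.hypot(*(p - (a + t * ab))))


def lobe_metrics(lobes: list[LobeRecord]) -> tuple[float, float]:
    """Average lobe length and average basal lobe length (µm); empty → (0, 0)."""
    if not lobes:
        return 0.0, 0.0
    return (
        float(np.mean([l.length for l in lobes])),
        float(np.mean([l.basal_length for l in lobes])),
    )


def margin_roughness(
    contour: Contour, curvature_sigma: float = DEFAULT_CURVATURE_SIGMA
) -> float:
    """Circle-normalized mean absolute curvature; 1 for a circle, > 1 for lobed cells."""
    _, kappa = _smoothed_curvature(contour, curvature_sigma)
    r_eq = np.sqrt(contour.area / np.pi)
    return float(np.mean(np.abs(kappa)) * r_eq)


def core_widths(
    contour: Contour,
    lobes: list[LobeRecord],
    curvature_sigma: float = DEFAULT_CURVATURE_SIGMA,
    raster_n: int = 400,
) -> tuple[float, float]:
    """Maximum and minimum core width (µm).

    The core polygon is the contour with each lobe arc (between its two base
    points, through the tip) excised and replaced by the straight base
    segment.  Widths are diameters of the maximal inscribed circles along the
    pruned medial axis of the rasterized core.
    """
    pts, _ = _smoothed_curvature(contour, curvature_sigma)
    n = len(pts)
    keep = np.ones(n, dtype=bool)
    merged_warning = False
    for lobe in lobes:
        a, b = lobe.base1_idx, lobe.base2_idx
        if a < 0 or b < 0:
            continue
        idx = np.arange(a + 1, b if b > a else b + n) % n
        if not keep[idx].all():
            merged_warning = True
        keep[idx] = False
    if merged_warning:
        warnings.warn("adjacent lobes share neck points; merged their base arcs")
    core = pts[keep]
    if len(core) < 3:
        core = pts
    return _medial_axis_widths(core, raster_n)


def _medial_axis_widths(polygon_xy: np.ndarray, raster_n: int) -> tuple[float, float]:
    """Max/min inscribed-circle diameters along the pruned medial axis."""
    lo = polygon_xy.min(axis=0)
    hi = polygon_xy.max(axis=0)
    extent = float(max(hi - lo))
    if extent <= 0:
        raise ValueError("degenerate core polygon")
    ps = extent / raster_n
    pad = 2
    cols = (polygon_xy[:, 0] - lo[0]) / ps + pad
    rows = (polygon_xy[:, 1] - lo[1]) / ps + pad
    shape = (
        int(np.ceil((hi[1] - lo[1]) / ps)) + 2 * pad + 1,
        int(np.ceil((hi[0] - lo[0]) / ps)) + 2 * pad + 1,
    )
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("core polygon rasterized to an empty mask")
    # rng fixed: medial_axis breaks pixel-order ties randomly otherwise
    skel, dist = medial_axis(mask, return_distance=True, rng=0)
    skel = _prune_endpoints(skel, iterations=int(np.ceil(dist.max())))
    if skel.any():
        # keep only the axis component carrying the maximal inscribed circle;
        # pruning can leave disconnected loop artifacts near the boundary
        lab, _ = ndimage.label(skel, structure=np.ones((3, 3)))
        masked = np.where(skel, dist, -1.0)
        keep_label = lab[np.unravel_index(np.argmax(masked), masked.shape)]
        skel = lab == keep_label
    if not skel.any():
        # core so compact that the whole axis pruned away: use the incenter
        widths = np.array([dist.max()])
    else:
        widths = dist[skel]
    widths = 2.0 * widths * ps
    return float(widths.max()), float(widths.min())


def _prune_endpoints(skel: np.ndarray, iterations: int) -> np.ndarray:
    """Iteratively strip endpoint pixels to remove medial-axis spurs."""
    kernel = np.ones((3, 3))
    out = skel.copy()
    for _ in range(iterations):
        if not out.any():
            break
        neighbors = ndimage.convolve(out.astype(int), kernel, mode="constant") - out
        endpoints = out & (neighbors <= 1)
        if not endpoints.any():
            break
        out = out & ~endpoints
    return out


def assign_size_class(area: float, cfg: SizeClassConfig = SizeClassConfig()) -> str:
    """Size class of a cell area (µm²): excluded/tiny/small/medium/large.

    Boundaries are lower-inclusive: 240 µm² → small, 1400 → medium,
    4042 → large; areas below the 75 µm² floor are ``excluded``.
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    if area < cfg.tiny_floor:
        return "excluded"
    if area < cfg.t_tiny:
        return "tiny"
    if area < cfg.t_small:
        return "small"
    if area < cfg.t_medium:
        return "medium"
    return "large"


def compute_features(
    contour: Contour,
    size_cfg: SizeClassConfig = SizeClassConfig(),
    curvature_sigma: float = DEFAULT_CURVATURE_SIGMA,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> ShapeFeatures:
    """All shape features of one cell contour."""
    area, perimeter, circ = basic_features(contour)
    lobes = detect_lobes(contour, curvature_sigma, min_prominence)
    avg_len, avg_basal = lobe_metrics(lobes)
    rough = margin_roughness(contour, curvature_sigma)
    wmax, wmin = core_widths(contour, lobes, curvature_sigma)
    return ShapeFeatures(
        cell_id=contour.cell_id,
        area=area,
        perimeter=perimeter,
        circularity=circ,
        lobe_count=len(lobes),
        avg_lobe_length=avg_len,
        avg_basal_lobe_length=avg_basal,
        margin_roughness=rough,
        max_core_width=wmax,
        min_core_width=wmin,
        size_class=assign_size_class(area, size_cfg),
    )


FEATURE_COLUMNS = [
    "area_um2",
    "perimeter_um",
    "circularity",
    "lobe_count",
    "avg_lobe_length_um",
    "avg_basal_lobe_length_um",
    "margin_roughness",
    "max_core_width_um",
    "min_core_width_um",
]


def features_table(
    contours: list[Contour],
    image_id: str = "",
    genotype: str = "",
    size_cfg: SizeClassConfig = SizeClassConfig(),
    curvature_sigma: float = DEFAULT_CURVATURE_SIGMA,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> pd.DataFrame:
    """Feature table (one row per cell) with the documented column contract."""
    rows = []
    for c in contours:
        f = compute_features(c, size_cfg, curvature_sigma, min_prominence)
        rows.append(
            {
                "image_id": image_id,
                "cell_id": f.cell_id,
                "genotype": genotype,
                "area_um2": f.area,
                "perimeter_um": f.perimeter,
                "circularity": f.circularity,
                "lobe_count": f.lobe_count,
                "avg_lobe_length_um": f.avg_lobe_length,
                "avg_basal_lobe_length_um": f.avg_basal_lobe_length,
                "margin_roughness": f.margin_roughness,
                "max_core_width_um": f.max_core_width,
                "min_core_width_um": f.min_core_width,
                "size_class": f.size_class,
            }
        )
    cols = ["image_id", "cell_id", "genotype", *FEATURE_COLUMNS, "size_class"]
    return pd.DataFrame(rows, columns=cols)
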