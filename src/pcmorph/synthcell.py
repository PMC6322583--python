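"""Synthetic jigsaw-puzzle pavement-cell mosaics with known ground truth.

The generator produces interdigitated-looking lobed cell outlines from a radial
shape model, arranges them in a grid mosaic, and renders two stain channels:

``wall_stain``
    Calcofluor-like channel — bright anticlinal walls on a dark background,
    with a per-cell wall-intensity multiplier (to emulate genotypes with
    reduced cell-wall deposition).
``outline_stain``
    PI/GFP-like channel — bright walls for segmentation plus a band of signal
    adjacent to the wall whose brightness differs between the cell-interior
    (convex) and exterior (concave) side of the wall, controlled by
    ``flank_asymmetry``.

Every render carries full ground truth (label masks, lobe tips, wall and flank
pixel masks), so each downstream stage can be validated without microscopy
data.

Shape model
-----------
A cell outline is the polar curve ``r(θ) = R · (1 + a · b(θ))`` where ``b`` is
a min-max-normalized (to [0, 1]) sum of ``k`` periodic von-Mises-like bumps
``exp(κ·(cos(θ−θ_j) − 1))`` centered at jittered equally spaced angles.
Lobes protrude *outward* from the base circle: necks sit on radius ``R`` (so
the cell core stays a near-circle of diameter ``2R``) and lobe tips reach
``R·(1+a)``.  The bump concentration ``κ`` scales with ``k²`` so that lobe
width tracks the lobe spacing; because ``r > 0`` everywhere the outline is
star-shaped and hence always a simple polygon.  ``a = 0`` (or ``k = 0``)
gives an exact circle of radius ``R``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import polygon as draw_polygon

from pcmorph.contour import Contour
from pcmorph.images import IntensityImage, LabelImage

__all__ = [
    "CellShapeSpec",
    "MosaicSpec",
    "GroundTruth",
    "CellTruth",
    "GenotypeSpec",
    "WT_LIKE",
    "MUTANT_LIKE",
    "generate_cell_outline",
    "generate_mosaic",
    "generate_two_genotype_experiment",
    "count_radial_maxima",
]


@dataclass(frozen=True)
class CellShapeSpec:
    """Parameters of one synthetic pavement-cell outline.

    base_radius : µm; radius of the lobe-free core circle (neck radius).
    lobe_count_true : number of lobes (0 = circle).
    lobe_amplitude : lobe height as a fraction of base_radius, in [0, 0.9];
        0 = circle.
    lobe_sharpness : dimensionless bump concentration scale; larger values
        give narrower, more finger-like lobes and wider neck arcs (sensible
        range ~0.8-3; below ~1 lobes become broad undulations whose bases are
        hard to place consistently).
    rotation : radians; global rotation of the lobe pattern.
    seed : controls per-lobe angular and amplitude jitter.
    """

    base_radius: float = 20.0
    lobe_count_true: int = 6
    lobe_amplitude: float = 0.3
    lobe_sharpness: float = 1.5
    rotation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be > 0")
        if self.lobe_count_true < 0:
            raise ValueError("lobe_count_true must be >= 0")
        if not (0.0 <= self.lobe_amplitude <= 0.9):
            raise ValueError("lobe_amplitude must lie in [0, 0.9]")
        if self.lobe_sharpness <= 0:
            raise ValueError("lobe_sharpness must be > 0")

    @property
    def max_radius(self) -> float:
        return self.base_radius * (1.0 + self.lobe_amplitude)


def _bump_profile(
    theta: np.ndarray, spec: CellShapeSpec, rng: np.random.Generator, jitter: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lobe profile b(θ), min-max-normalized to [0, 1], and bump-center angles."""
    k = spec.lobe_count_true
    spacing = 2.0 * np.pi / k
    centers = spec.rotation + spacing * np.arange(k)
    centers = centers + rng.uniform(-0.25, 0.25, size=k) * spacing * jitter
    heights = 1.0 + rng.uniform(-0.15, 0.15, size=k) * jitter
    # lobe width tracks lobe spacing (kappa ~ k^2) but saturates for
    # few-lobed cells so their lobes stay distinct protrusions
    kappa = max(2.0, spec.lobe_sharpness * max(k**2, 14.0))
    b = np.zeros_like(theta)
    for c, h in zip(centers, heights):
        b = b + h * np.exp(kappa * (np.cos(theta - c) - 1.0))
    b = b - b.min()
    peak = b.max()
    if peak > 0:
        b = b / peak
    return b, centers


def count_radial_maxima(radii: np.ndarray) -> int:
    """Count strict local maxima of a circularly sampled radius profile."""
    prev = np.roll(radii, 1)
    nxt = np.roll(radii, -1)
    return int(np.count_nonzero((radii > prev) & (radii > nxt)))


def generate_cell_outline(
    spec: CellShapeSpec, n_vertices: int = 256
) -> Contour:
    """Generate one closed lobed outline centred at the origin.

    The returned polygon has exactly ``spec.lobe_count_true`` radial maxima
    (verified; jitter is reduced and the pattern regenerated if the bumps
    merge).  Determinism: the same spec always yields the same vertices.
    """
    contour, _ = generate_cell_outline_with_tips(spec, n_vertices)
    return contour


def generate_cell_outline_with_tips(
    spec: CellShapeSpec, n_vertices: int = 256
) -> tuple[Contour, np.ndarray]:
    """As :func:`generate_cell_outline`, also returning lobe-tip angles (rad)."""
    if n_vertices < 64:
        raise ValueError("n_vertices must be >= 64")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    k = spec.lobe_count_true
    if k == 0 or spec.lobe_amplitude == 0.0:
        r = np.full_like(theta, spec.base_radius)
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        return Contour(xy), np.empty(0)

    for attempt, jitter in enumerate([1.0, 0.6, 0.3, 0.0]):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        b, centers = _bump_profile(theta, spec, rng, jitter)
        r = spec.base_radius * (1.0 + spec.lobe_amplitude * b)
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        contour = Contour(xy)
        # recentre so the polygon centroid sits exactly at the origin; the
        # radial-maxima invariant is checked about the *centroid*
        contour = Contour(contour.vertices - contour.centroid)
        r_c = np.hypot(contour.vertices[:, 0], contour.vertices[:, 1])
        if spec.lobe_amplitude <= 0.05 or count_radial_maxima(r_c) == k:
            break
    else:  # pragma: no cover - zero jitter always yields k maxima
        warnings.warn("lobe bumps merged; amplitude pattern degenerate")
    tip_thetas = np.mod(centers, 2.0 * np.pi)
    return contour, np.sort(tip_thetas)


@dataclass(frozen=True)
class MosaicSpec:
    """Grid mosaic of synthetic cells plus rendering parameters.

    Cells are placed on a ``grid_shape = (rows, cols)`` lattice with
    center-to-center distance ``spacing_um`` (auto-derived when omitted so
    that neighboring outlines stay at least ``wall_thickness_um`` plus both
    flank bands apart).  Labels run 1..N in raster order.
    """

    cells: tuple[CellShapeSpec, ...]
    grid_shape: tuple[int, int]
    pixel_size: float = 0.4
    wall_thickness_um: float = 1.2
    wall_intensity_per_cell: dict[int, float] | None = None
    background_intensity: float = 5.0
    noise_sd: float = 2.0
    flank_asymmetry: float = 1.0
    flank_band_um: float = 3.0
    flank_base_intensity: float = 60.0
    outline_wall_intensity: float = 200.0
    spacing_um: float | None = None
    margin_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        nr, nc = self.grid_shape
        if nr * nc != len(self.cells):
            raise ValueError("grid_shape does not match number of cell specs")
        if self.wall_thickness_um <= 0:
            raise ValueError("wall_thickness_um must be > 0")
        if self.flank_asymmetry <= 0:
            raise ValueError("flank_asymmetry must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def resolved_spacing(self) -> float:
        if self.spacing_um is not None:
            return self.spacing_um
        rmax = max(c.max_radius for c in self.cells)
        return 2.0 * rmax + self.wall_thickness_um + 2.0 * self.flank_band_um + 1.0

    @property
    def image_shape(self) -> tuple[int, int]:
        nr, nc = self.grid_shape
        s = self.resolved_spacing
        h = 2 * self.margin_um + nr * s
        w = 2 * self.margin_um + nc * s
        return (int(np.ceil(h / self.pixel_size)), int(np.ceil(w / self.pixel_size)))

    def cell_center(self, index: int) -> np.ndarray:
        nr, nc = self.grid_shape
        i, j = divmod(index, nc)
        s = self.resolved_spacing
        return np.array(
            [self.margin_um + (j + 0.5) * s, self.margin_um + (i + 0.5) * s]
        )


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one rendered cell."""

    cell_id: int
    lobe_count_true: int
    lobe_tips: np.ndarray  # (k, 2) absolute µm
    base_radius_um: float
    wall_multiplier: float
    center_um: np.ndarray
    contour: Contour  # absolute µm coordinates


@dataclass(frozen=True)
class GroundTruth:
    """Full per-pixel and per-cell ground truth of one rendered mosaic."""

    labels: LabelImage
    cells: dict[int, CellTruth]
    wall_owner: np.ndarray  # nearest-cell id per pixel (0 = none in range)
    wall_mask: np.ndarray  # bool, anticlinal-wall band
    convex_mask: np.ndarray  # bool, flank band on the cell-interior side
    concave_mask: np.ndarray  # bool, flank band on the exterior side

    def wall_mask_of(self, cell_id: int) -> np.ndarray:
        return self.wall_mask & (self.wall_owner == cell_id)

    def convex_mask_of(self, cell_id: int) -> np.ndarray:
        return self.convex_mask & (self.wall_owner == cell_id)

    def concave_mask_of(self, cell_id: int) -> np.ndarray:
        return self.concave_mask & (self.wall_owner == cell_id)


def generate_mosaic(
    mspec: MosaicSpec,
) -> tuple[IntensityImage, IntensityImage, LabelImage, GroundTruth]:
    """Render a cell mosaic into (wall_stain, outline_stain, truth, ground_truth).

    Raises ``ValueError`` if cell interiors overlap or leave the image.
    Rendering is a pure function of the spec (bit-identical per seed).
    """
    ps = mspec.pixel_size
    shape = mspec.image_shape
    n = len(mspec.cells)

    filled = np.zeros(shape, dtype=np.int32)
    claim = np.zeros(shape, dtype=np.int16)
    outline_owner = np.zeros(shape, dtype=np.int32)
    cells: dict[int, CellTruth] = {}

    for idx, cspec in enumerate(mspec.cells):
        cid = idx + 1
        center = mspec.cell_center(idx)
        contour, tip_thetas = generate_cell_outline_with_tips(cspec)
        verts = contour.vertices + center
        rows = verts[:, 1] / ps
        cols = verts[:, 0] / ps
        rr, cc = draw_polygon(rows, cols, shape=shape)
        if rr.size == 0:
            raise ValueError(f"cell {cid} rasterizes to an empty region")
        filled[rr, cc] = cid
        claim[rr, cc] += 1

        # dense boundary raster carrying the owning cell id
        dense = Contour(verts).resampled(
            max(512, int(np.ceil(contour.perimeter / (0.25 * ps))))
        ).vertices
        br = np.clip(np.round(dense[:, 1] / ps).astype(int), 0, shape[0] - 1)
        bc = np.clip(np.round(dense[:, 0] / ps).astype(int), 0, shape[1] - 1)
        outline_owner[br, bc] = cid

        # lobe tip coordinates from the radial maxima nearest each bump center
        tips = []
        rel = contour.vertices
        ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
        rad = np.hypot(rel[:, 0], rel[:, 1])
        for t in tip_thetas:
            d = np.abs(np.angle(np.exp(1j * (ang - t))))
            near = np.where(d < np.pi / max(cspec.lobe_count_true, 1))[0]
            if near.size == 0:
                near = np.array([int(np.argmin(d))])
            tips.append(rel[near[np.argmax(rad[near])]] + center)
        cells[cid] = CellTruth(
            cell_id=cid,
            lobe_count_true=cspec.lobe_count_true if cspec.lobe_amplitude > 0 else 0,
            lobe_tips=np.array(tips) if tips else np.empty((0, 2)),
            base_radius_um=cspec.base_radius,
            # relative to the reference wall intensity of 100
            wall_multiplier=(mspec.wall_intensity_per_cell or {}).get(cid, 100.0)
            / 100.0,
            center_um=center,
            contour=Contour(verts, cell_id=cid),
        )

    if claim.max() > 1:
        raise ValueError("cell interiors overlap; increase spacing_um")
    edge_touch = (
        filled[0, :].any() or filled[-1, :].any()
        or filled[:, 0].any() or filled[:, -1].any()
    )
    if edge_touch:
        raise ValueError("cells touch the image border; increase margin_um")

    outline_mask = outline_owner > 0
    dist_px, (ir, ic) = distance_transform_edt(~outline_mask, return_indices=True)
    owner = outline_owner[ir, ic]
    dist_um = dist_px * ps

    half_wall = mspec.wall_thickness_um / 2.0
    wall_mask = dist_um <= half_wall
    band_mask = (dist_um > half_wall) & (dist_um <= half_wall + mspec.flank_band_um)
    inside_any = filled > 0
    convex_mask = band_mask & inside_any
    concave_mask = band_mask & ~inside_any

    truth_labels = np.where(wall_mask, 0, filled).astype(np.int32)

    # wall-stain channel: background + per-cell wall intensity on the wall band
    wall_int = np.full(n + 1, 100.0)
    wall_int[0] = 0.0
    if mspec.wall_intensity_per_cell:
        for cid, v in mspec.wall_intensity_per_cell.items():
            if not (1 <= cid <= n):
                raise ValueError(f"wall_intensity_per_cell has unknown cell id {cid}")
            wall_int[cid] = v
    wall_stain = np.full(shape, mspec.background_intensity, dtype=float)
    wall_stain[wall_mask] += wall_int[owner[wall_mask]]

    # outline-stain channel: bright wall core + asymmetric flank bands
    outline_stain = np.full(shape, mspec.background_intensity, dtype=float)
    outline_stain[wall_mask] = mspec.outline_wall_intensity
    outline_stain[convex_mask] = mspec.flank_base_intensity * mspec.flank_asymmetry
    outline_stain[concave_mask] = mspec.flank_base_intensity

    if mspec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([mspec.seed, 7]))
        wall_stain = np.clip(
            wall_stain + rng.normal(0.0, mspec.noise_sd, shape), 0.0, None
        )
        outline_stain = np.clip(
            outline_stain + rng.normal(0.0, mspec.noise_sd, shape), 0.0, None
        )

    labels = LabelImage(truth_labels, ps)
    truth = GroundTruth(
        labels=labels,
        cells=cells,
        wall_owner=np.where(dist_um <= half_wall + mspec.flank_band_um, owner, 0),
        wall_mask=wall_mask,
        convex_mask=convex_mask,
        concave_mask=concave_mask,
    )
    return (
        IntensityImage(wall_stain, ps),
        IntensityImage(outline_stain, ps),
        labels,
        truth,
    )


@dataclass(frozen=True)
class GenotypeSpec:
    """Shape and wall-signal regime of one synthetic genotype.

    Defaults for the wild-type-like regime: 6 well-developed lobes of relative
    amplitude 0.35 on a 20 µm base radius.  A mutant-like regime is obtained
    by lowering ``lobe_count`` / ``lobe_amplitude`` (fewer, shallower lobes and
    hence wider necks) and/or ``wall_intensity`` (reduced wall stain).
    """

    name: str
    lobe_count: int = 6
    lobe_amplitude: float = 0.35
    lobe_sharpness: float = 1.5
    base_radius_um: float = 20.0
    radius_jitter: float = 0.08
    wall_intensity: float = 100.0
    flank_asymmetry: float = 1.0
    noise_sd: float = 2.0


# canonical study conditions for the two-genotype experiments: the wild-type-
# like regime has many well-grown lobes; the mutant-like regime has fewer,
# shorter lobes, wider necks (larger lobe-free core) and ~45% reduced wall
# stain, the qualitative phenotype of lobe-initiation mutants
WT_LIKE = GenotypeSpec(
    name="wt", lobe_count=6, lobe_amplitude=0.35, base_radius_um=20.0,
    wall_intensity=100.0,
)
MUTANT_LIKE = GenotypeSpec(
    name="mut", lobe_count=4, lobe_amplitude=0.15, base_radius_um=23.0,
    wall_intensity=55.0,
)


def generate_two_genotype_experiment(
    out_dir: str | Path,
    wt_spec: GenotypeSpec,
    mut_spec: GenotypeSpec,
    n_images: int,
    seed: int = 0,
    grid_shape: tuple[int, int] = (2, 2),
    pixel_size: float = 0.4,
) -> dict:
    """Write a two-genotype image dataset with ground truth to ``out_dir``.

    Per genotype and image, writes ``<name>/img###_wall.tif``,
    ``..._outline.tif`` and ``..._labels.tif`` plus a pooled
    ``ground_truth.csv``.  Fully reproducible from ``seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    manifest: dict = {"images": [], "ground_truth_csv": str(out / "ground_truth.csv")}
    rows: list[dict] = []
    n_cells = grid_shape[0] * grid_shape[1]

    for g_idx, gspec in enumerate([wt_spec, mut_spec]):
        gdir = out / gspec.name
        gdir.mkdir(exist_ok=True)
        for i in range(n_images):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, g_idx, i])
            )
            cells = tuple(
                CellShapeSpec(
                    base_radius=gspec.base_radius_um
                    * (1.0 + rng.uniform(-1, 1) * gspec.radius_jitter),
                    lobe_count_true=gspec.lobe_count,
                    lobe_amplitude=gspec.lobe_amplitude,
                    lobe_sharpness=gspec.lobe_sharpness,
                    rotation=rng.uniform(0, 2 * np.pi),
                    seed=int(rng.integers(2**31)),
                )
                for _ in range(n_cells)
            )
            mspec = MosaicSpec(
                cells=cells,
                grid_shape=grid_shape,
                pixel_size=pixel_size,
                wall_intensity_per_cell={
                    c + 1: gspec.wall_intensity for c in range(n_cells)
                },
                flank_asymmetry=gspec.flank_asymmetry,
                noise_sd=gspec.noise_sd,
                seed=int(rng.integers(2**31)),
            )
            wall, outline, labels, truth = generate_mosaic(mspec)
            image_id = f"{gspec.name}/img{i:03d}"
            paths = {
                "wall": gdir / f"img{i:03d}_wall.tif",
                "outline": gdir / f"img{i:03d}_outline.tif",
                "labels": gdir / f"img{i:03d}_labels.tif",
            }
            wall.save(paths["wall"])
            outline.save(paths["outline"])
            labels.save(paths["labels"])
            manifest["images"].append(
                {
                    "image_id": image_id,
                    "genotype": gspec.name,
                    **{k: str(v) for k, v in paths.items()},
                }
            )
            for cid, ct in truth.cells.items():
                rows.append(
                    {
                        "image_id": image_id,
                        "genotype": gspec.name,
                        "cell_id": cid,
                        "lobe_count_true": ct.lobe_count_true,
                        "base_radius_um": round(ct.base_radius_um, 4),
                        "wall_multiplier": ct.wall_multiplier,
                    }
                )

    with open(out / "ground_truth.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
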