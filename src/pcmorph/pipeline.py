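"""End-to-end pipeline runs with stable file contracts.

Two entry points:

:func:`run_shape_pipeline`
    simulate (optional) → segment → contour → shape features → group
    statistics.  Writes ``features.csv``, ``summaries.csv``,
    ``comparisons.csv``, per-image label TIFFs and a JSON manifest with the
    config hash and per-stage cell counts.

:func:`run_intensity_pipeline`
    segment the outline channel → per-cell boundary intensity of the paired
    signal channel (+ per-lobe convex/concave flank intensities of the
    outline channel) → group statistics.  Writes ``boundary_intensity.csv``,
    ``flank_intensity.csv``, ``intensity_comparisons.csv``,
    ``flank_ttest.csv`` and a manifest.

Both runs are deterministic given (config, seed): re-running produces
byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from pcmorph import groupstats, morphometry, segment, synthcell, wallsignal
from pcmorph.images import IntensityImage, LabelImage

logger = logging.getLogger("pcmorph")

__all__ = ["RunConfig", "run_shape_pipeline", "run_intensity_pipeline"]

_CSV_FLOAT = "%.6g"


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (YAML-serializable)."""

    output_dir: str = "pcmorph_run"
    seed: int = 0
    # either a two-genotype simulation...
    simulate: dict | None = None  # keys: n_images, grid_shape, pixel_size, wt, mut
    # ...or a list of existing images:
    # {image_id, genotype, outline, wall (optional), pixel_size (optional)}
    images: list[dict] = field(default_factory=list)
    segmentation: dict = field(default_factory=dict)  # SegmentationConfig kwargs
    size_classes: dict = field(default_factory=dict)  # SizeClassConfig kwargs
    curvature_sigma: float = morphometry.DEFAULT_CURVATURE_SIGMA
    min_prominence: float = morphometry.DEFAULT_MIN_PROMINENCE
    neighborhood: int = 15
    flank_band_um: float = 1.5
    wall_clearance_um: float = 1.2
    adjust_scope: str = "per_feature"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def segmentation_config(self) -> segment.SegmentationConfig:
        return segment.SegmentationConfig(**self.segmentation)

    def size_class_config(self) -> morphometry.SizeClassConfig:
        return morphometry.SizeClassConfig(**self.size_classes)


def _genotype_spec(name: str, params: dict) -> synthcell.GenotypeSpec:
    return synthcell.GenotypeSpec(name=name, **params)


def _resolve_images(cfg: RunConfig, out: Path) -> list[dict]:
    """Return image records {image_id, genotype, outline, wall, pixel_size}."""
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        wt = _genotype_spec(sim.get("wt_name", "wt"), sim.get("wt", {}))
        mut = _genotype_spec(sim.get("mut_name", "mut"), sim.get("mut", {}))
        manifest = synthcell.generate_two_genotype_experiment(
            out / "data",
            wt,
            mut,
            n_images=int(sim.get("n_images", 10)),
            seed=cfg.seed,
            grid_shape=tuple(sim.get("grid_shape", (2, 2))),
            pixel_size=float(sim.get("pixel_size", 0.4)),
        )
        return [
            {
                "image_id": rec["image_id"],
                "genotype": rec["genotype"],
                "outline": rec["outline"],
                "wall": rec["wall"],
                "pixel_size": None,
            }
            for rec in manifest["images"]
        ]
    if not cfg.images:
        raise ValueError("config must provide either 'simulate' or 'images'")
    return [dict(rec) for rec in cfg.images]


def _load_image(path: str, pixel_size: float | None) -> IntensityImage:
    return IntensityImage.load(path, pixel_size=pixel_size)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT, lineterminator="\n")


def _segment_stage(
    cfg: RunConfig, rec: dict, labels_dir: Path
) -> tuple[LabelImage, list]:
    """Segment one image and extract its contours; errors name the image."""
    image_id = rec["image_id"]
    try:
        outline = _load_image(rec["outline"], rec.get("pixel_size"))
        labels = segment.segment_cells(outline, cfg.segmentation_config())
        labels.save(labels_dir / (image_id.replace("/", "_") + "_labels.tif"))
        contours = [segment.extract_contour(labels, cid) for cid in labels.cell_ids]
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage 'segment' failed on image {image_id!r}: {exc}") from exc
    return labels, contours


def run_shape_pipeline(cfg: RunConfig) -> dict:
    """Run simulate → segment → measure → compare; return the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels_dir = out / "labels"
    labels_dir.mkdir(exist_ok=True)
    records = _resolve_images(cfg, out)

    tables = []
    counts = {}
    for rec in records:
        image_id = rec["image_id"]
        labels, contours = _segment_stage(cfg, rec, labels_dir)
        try:
            table = morphometry.features_table(
                contours,
                image_id=image_id,
                genotype=rec.get("genotype", ""),
                size_cfg=cfg.size_class_config(),
                curvature_sigma=cfg.curvature_sigma,
                min_prominence=cfg.min_prominence,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"stage 'measure' failed on image {image_id!r}: {exc}"
            ) from exc
        counts[image_id] = {"cells_segmented": len(contours), "feature_rows": len(table)}
        logger.info("measured %d cells in %s", len(table), image_id)
        tables.append(table)

    features = pd.concat(tables, ignore_index=True)
    _write_csv(features, out / "features.csv")

    feature_cols = morphometry.FEATURE_COLUMNS
    n_groups = features["genotype"].nunique() if len(features) else 0
    if len(features) and n_groups >= 2:
        summaries = groupstats.summaries_table(features, feature_cols)
        comparisons = groupstats.comparisons_table(
            groupstats.compare_feature_table(
                features, feature_cols, adjust_scope=cfg.adjust_scope
            )
        )
    else:  # nothing to compare: still honor the file contract
        logger.warning("fewer than two groups with cells; statistics skipped")
        summaries = groupstats.summaries_table(features, feature_cols) if len(features) else (
            pd.DataFrame(columns=["feature", "group", "n", "median", "mean", "sd",
                                  "ci95_low", "ci95_high"])
        )
        comparisons = groupstats.comparisons_table([])
    _write_csv(summaries, out / "summaries.csv")
    _write_csv(comparisons, out / "comparisons.csv")

    manifest = {
        "pipeline": "shape",
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_images": len(records),
        "per_image": counts,
        "total_cells": int(sum(c["cells_segmented"] for c in counts.values())),
        "total_feature_rows": int(len(features)),
        "outputs": {
            "features": str(out / "features.csv"),
            "summaries": str(out / "summaries.csv"),
            "comparisons": str(out / "comparisons.csv"),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_intensity_pipeline(cfg: RunConfig) -> dict:
    """Run segment → boundary/flank intensity → genotype comparison."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels_dir = out / "labels"
    labels_dir.mkdir(exist_ok=True)
    records = _resolve_images(cfg, out)
    missing = [r["image_id"] for r in records if not r.get("wall")]
    if missing:
        raise ValueError(
            "intensity pipeline needs a paired signal ('wall') image for every "
            f"outline image; missing for: {missing}"
        )

    boundary_rows, flank_rows, counts = [], [], {}
    for rec in records:
        image_id = rec["image_id"]
        labels, contours = _segment_stage(cfg, rec, labels_dir)
        try:
            signal = _load_image(rec["wall"], rec.get("pixel_size"))
            outline_img = _load_image(rec["outline"], rec.get("pixel_size"))
            brecs = wallsignal.boundary_mean_intensity(
                labels, signal, neighborhood=cfg.neighborhood
            )
            for b in brecs:
                boundary_rows.append(
                    {
                        "image_id": image_id,
                        "genotype": rec.get("genotype", ""),
                        "cell_id": b.cell_id,
                        "intensity_sum": b.intensity_sum,
                        "contributing_pixels": b.contributing_pixels,
                        "mean_boundary_intensity": b.mean_boundary_intensity,
                    }
                )
            for contour in contours:
                lobes = morphometry.detect_lobes(
                    contour, cfg.curvature_sigma, cfg.min_prominence
                )
                for f in wallsignal.lobe_flank_intensity(
                    contour,
                    lobes,
                    outline_img,
                    band_width=cfg.flank_band_um,
                    wall_clearance=cfg.wall_clearance_um,
                ):
                    flank_rows.append(
                        {
                            "image_id": image_id,
                            "genotype": rec.get("genotype", ""),
                            "cell_id": f.cell_id,
                            "lobe_index": f.lobe_index,
                            "convex_mean": f.convex_mean,
                            "concave_mean": f.concave_mean,
                        }
                    )
        except RuntimeError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"stage 'intensity' failed on image {image_id!r}: {exc}"
            ) from exc
        counts[image_id] = {"cells": len(labels.cell_ids)}

    boundary = pd.DataFrame(boundary_rows)
    flanks = pd.DataFrame(flank_rows)
    _write_csv(boundary, out / "boundary_intensity.csv")
    _write_csv(flanks, out / "flank_intensity.csv")

    comparisons = groupstats.comparisons_table(
        groupstats.compare_feature_table(
            boundary, ["mean_boundary_intensity"], adjust_scope=cfg.adjust_scope
        )
    )
    _write_csv(comparisons, out / "intensity_comparisons.csv")

    ttest_df = pd.DataFrame(
        columns=["n_lobes", "convex_mean", "concave_mean", "ratio", "t", "df", "p"]
    )
    if len(flanks) >= 2:
        t, dof, p = groupstats.welch_t_test(
            flanks["convex_mean"].to_numpy(), flanks["concave_mean"].to_numpy()
        )
        ttest_df = pd.DataFrame(
            [
                {
                    "n_lobes": len(flanks),
                    "convex_mean": flanks["convex_mean"].mean(),
                    "concave_mean": flanks["concave_mean"].mean(),
                    "ratio": flanks["convex_mean"].mean() / flanks["concave_mean"].mean(),
                    "t": t,
                    "df": dof,
                    "p": p,
                }
            ]
        )
    _write_csv(ttest_df, out / "flank_ttest.csv")

    manifest = {
        "pipeline": "intensity",
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_images": len(records),
        "per_image": counts,
        "total_boundary_rows": int(len(boundary)),
        "total_flank_rows": int(len(flanks)),
        "outputs": {
            "boundary_intensity": str(out / "boundary_intensity.csv"),
            "flank_intensity": str(out / "flank_intensity.csv"),
            "intensity_comparisons": str(out / "intensity_comparisons.csv"),
            "flank_ttest": str(out / "flank_ttest.csv"),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
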