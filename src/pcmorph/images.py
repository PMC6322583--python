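"""Image containers with physical pixel size, and TIFF round-tripping.

Conventions: images are indexed ``(row, col)`` with the origin at the top-left
pixel; the physical coordinate of pixel ``(r, c)`` is ``(x, y) = (c, r) *
pixel_size`` in micrometres.  All downstream features are reported in µm/µm².
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class IntensityImage:
    """Single-channel grayscale image with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite, non-negative intensities.
    pixel_size : float
        Edge length of one pixel in micrometres (µm/pixel), > 0.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("intensity image contains non-finite values")
        if np.any(px < 0):
            raise ValueError("intensity image contains negative values")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(
            str(path),
            self.pixels.astype(np.float32),
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={"unit": "um", "pixel_size_um": self.pixel_size},
        )

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None) -> "IntensityImage":
        px, ps = _read_tiff(path)
        ps = pixel_size if pixel_size is not None else ps
        if ps is None:
            raise ValueError(f"{path}: no pixel size in TIFF; pass pixel_size explicitly")
        return cls(px, ps)


@dataclass(frozen=True)
class LabelImage:
    """Integer-labeled cell regions; background is 0.

    After size filtering labels are consecutive ``1..N`` in raster order of
    region centroids.
    """

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"expected a 2-D label image, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def mask(self, cell_id: int) -> np.ndarray:
        return self.labels == cell_id

    def area_um2(self, cell_id: int) -> float:
        return float(np.count_nonzero(self.labels == cell_id)) * self.pixel_size**2

    def save(self, path: str | Path) -> None:
        if self.labels.max() > np.iinfo(np.uint16).max:
            raise ValueError("more than 65535 labels; cannot write 16-bit TIFF")
        tifffile.imwrite(
            str(path),
            self.labels.astype(np.uint16),
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={"unit": "um", "pixel_size_um": self.pixel_size},
        )

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None) -> "LabelImage":
        px, ps = _read_tiff(path)
        ps = pixel_size if pixel_size is not None else ps
        if ps is None:
            raise ValueError(f"{path}: no pixel size in TIFF; pass pixel_size explicitly")
        return cls(px.astype(np.int32), ps)


def _read_tiff(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a single-page TIFF; recover the pixel size written by `save` if present."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        ps = None
        meta = tf.shaped_metadata or tf.imagej_metadata
        if meta:
            m = meta[0] if isinstance(meta, (list, tuple)) else meta
            if isinstance(m, dict) and "pixel_size_um" in m:
                ps = float(m["pixel_size_um"])
        if ps is None:
            try:
                xres = page.tags["XResolution"].value
                if xres[0] > 0:
                    ps = xres[1] / xres[0]
            except KeyError:
                ps = None
    return arr, ps
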