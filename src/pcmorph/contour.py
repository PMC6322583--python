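"""Closed polygonal cell contours in physical (µm) coordinates.

A :class:`Contour` stores the ordered vertices of one cell's outline,
counter-clockwise (positive shoelace area) in the image coordinate frame
``x = col * pixel_size``, ``y = row * pixel_size``.  The closing edge from the
last vertex back to the first is implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon


@dataclass(frozen=True)
class Contour:
    """Simple closed polygon outline of one cell.

    Parameters
    ----------
    vertices : (n, 2) ndarray
        Ordered ``(x, y)`` vertices in µm, not repeating the first point.
    cell_id : int
        Label of the cell this contour belongs to.
    """

    vertices: np.ndarray
    cell_id: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"vertices must be (n, 2), got {v.shape}")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValueError("a contour needs at least 3 distinct vertices")
        area = _shoelace(v)
        if area == 0:
            raise ValueError("degenerate polygon: zero signed area")
        if area < 0:  # enforce counter-clockwise orientation
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        """Enclosed area by the shoelace formula (µm²)."""
        return _shoelace(self.vertices)

    @property
    def perimeter(self) -> float:
        """Length of the closed polyline (µm)."""
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the polygon (µm)."""
        v = self.vertices
        w = np.roll(v, -1, axis=0)
        cross = v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1]
        a = cross.sum() / 2.0
        cx = ((v[:, 0] + w[:, 0]) * cross).sum() / (6.0 * a)
        cy = ((v[:, 1] + w[:, 1]) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])

    def is_simple(self) -> bool:
        return Polygon(self.vertices).is_valid

    def to_polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + np.array([dx, dy]), self.cell_id)

    def rotated(self, angle: float) -> "Contour":
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        return Contour(self.vertices @ rot.T, self.cell_id)

    def scaled(self, s: float) -> "Contour":
        return Contour(self.vertices * s, self.cell_id)

    def resampled(self, n: int) -> "Contour":
        """Resample to ``n`` vertices equally spaced in arc length."""
        xy = resample_closed(self.vertices, n)
        return Contour(xy, self.cell_id)


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Equal-arc-length resampling of a closed polyline to ``n`` points."""
    v = np.vstack([vertices, vertices[:1]])
    seg = np.hypot(*np.diff(v, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, v[:, 0])
    y = np.interp(t, s, v[:, 1])
    return np.column_stack([x, y])
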