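"""Polygon rasterization and analytic areas.

The ventricle outline is a simple polygon in pixel coordinates (0-based,
x rightward, y downward, vertices at pixel centers).  A pixel belongs to the
ROI iff its center is inside the polygon under the even-odd rule; pixel
centers lying exactly on an edge are included.  Whole pixels are counted —
no partial-pixel weighting — because blood area is ultimately a count of
hemoglobin-classified pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundsError, DegeneratePolygonError

_EDGE_TOL = 1e-9


@dataclass
class RoiMask:
    """Boolean ROI raster for one frame."""

    mask: np.ndarray
    frame_index: int
    area_px: int

    def __post_init__(self) -> None:
        self.area_px = int(self.area_px)
        assert self.area_px == int(self.mask.sum())


def shoelace_area(polygon) -> float:
    """Continuous polygon area in px^2 via the shoelace formula.

    Orientation-independent; the polygon is implicitly closed.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise DegeneratePolygonError(
            f"polygon needs >= 3 (x, y) vertices; got shape {verts.shape}"
        )
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return abs(np.sum(x * yn - xn * y)) / 2.0


def _on_any_edge(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Pixel centers whose distance to some polygon edge is ~0."""
    on = np.zeros(px.shape, dtype=bool)
    v2 = np.roll(verts, -1, axis=0)
    scale = max(1.0, np.abs(verts).max())
    tol = _EDGE_TOL * scale
    for (x1, y1), (x2, y2) in zip(verts, v2):
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        if L2 == 0.0:
            d2 = (px - x1) ** 2 + (py - y1) ** 2
            on |= d2 <= tol * tol
            continue
        t = np.clip(((px - x1) * dx + (py - y1) * dy) / L2, 0.0, 1.0)
        d2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
        on |= d2 <= tol * tol
    return on


def rasterize_polygon(polygon, image_shape, frame_index: int = 0) -> RoiMask:
    """Even-odd rasterization of a simple polygon onto an image grid.

    A pixel is a member iff its center is strictly inside (even-odd crossing
    count) or exactly on an edge.  Deterministic; no anti-aliasing.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise DegeneratePolygonError(
            f"polygon needs >= 3 (x, y) vertices; got shape {verts.shape}"
        )
    h, w = int(image_shape[0]), int(image_shape[1])
    if verts[:, 0].min() < 0 or verts[:, 0].max() > w - 1:
        raise BoundsError("polygon x-range exceeds image width")
    if verts[:, 1].min() < 0 or verts[:, 1].max() > h - 1:
        raise BoundsError("polygon y-range exceeds image height")

    x0 = int(np.floor(verts[:, 0].min()))
    x1 = int(np.ceil(verts[:, 0].max()))
    y0 = int(np.floor(verts[:, 1].min()))
    y1 = int(np.ceil(verts[:, 1].max()))
    px, py = np.meshgrid(
        np.arange(x0, x1 + 1, dtype=float),
        np.arange(y0, y1 + 1, dtype=float),
    )

    inside = np.zeros(px.shape, dtype=bool)
    v2 = np.roll(verts, -1, axis=0)
    for (xa, ya), (xb, yb) in zip(verts, v2):
        crosses = (ya > py) != (yb > py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = xa + (py - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (px < xint)
    inside |= _on_any_edge(px, py, verts)

    mask = np.zeros((h, w), dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    return RoiMask(mask=mask, frame_index=int(frame_index), area_px=int(mask.sum()))
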