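"""Polygon-to-raster helpers shared by annotation and ROI handling.

Coordinate frame: 0-based, row-major; the center of pixel (r, c) sits at
(x=c, y=r). A pixel belongs to a polygon iff its center lies strictly
inside (even-odd rule; holes via interior rings).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon


def validate_polygon(poly: Polygon) -> None:
    if not isinstance(poly, Polygon) or poly.is_empty:
        raise ValueError("annotation geometry must be a non-empty Polygon")
    if not poly.is_valid:
        raise ValueError(f"polygon is not simple/valid: {shapely.is_valid_reason(poly)}")


def check_in_bounds(poly: Polygon, shape: tuple[int, int]) -> None:
    """Polygons must fall inside the image's pixel grid (half-pixel margin)."""
    rows, cols = shape
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > cols - 0.5 or maxy > rows - 0.5:
        raise ValueError(
            f"polygon bounds {poly.bounds} fall outside image of shape {shape}"
        )


def polygon_mask(polygons: Iterable[Polygon], shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of pixels whose centers lie inside any of ``polygons``."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.ceil(minx)))
        c1 = min(cols - 1, int(np.floor(maxx)))
        r0 = max(0, int(np.ceil(miny)))
        r1 = min(rows - 1, int(np.floor(maxy)))
        if c1 < c0 or r1 < r0:
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        inside = shapely.contains_xy(poly, cc.ravel(), rr.ravel())
        mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def polygons_overlap(a: Sequence[Polygon], b: Sequence[Polygon], tol: float = 1e-9) -> bool:
    """True when the unions of the two polygon sets overlap with positive area."""
    if not a or not b:
        return False
    ua = shapely.unary_union(list(a))
    ub = shapely.unary_union(list(b))
    return ua.intersection(ub).area > tol
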