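"""Carry planning-frame contours through a transform onto a guidance scan.

Every contour vertex is mapped individually through the fixed-to-moving
transform chain.  Mapped vertices generally leave their original slice
plane, so each mapped polygon is reassigned to the nearest target slice
plane (within half a slice spacing) and its vertices are orthogonally
projected onto that plane.  When two source polygons land on the same
target slice — routine when propagating 3 mm planning slices onto 6 mm
guidance slices — their union is taken.
"""

from __future__ import annotations

import logging

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .image_io import Contour, ImageVolume, StructureSet
from .registration import TransformChain

__all__ = ["propagate_contours", "map_contour_points", "regroup_to_slices"]

logger = logging.getLogger(__name__)

MIN_POLYGON_AREA_MM2 = 1.0


def map_contour_points(ss: StructureSet, chain: TransformChain) -> list[np.ndarray]:
    """Map every contour's vertices to 3D moving-frame points (no snapping)."""
    out = []
    for c in ss.contours:
        pts3 = np.column_stack([c.points, np.full(len(c.points), c.z)])
        out.append(chain.apply(pts3))
    return out


def regroup_to_slices(
    mapped_polygons: list[np.ndarray], target: ImageVolume
) -> list[Contour]:
    """Snap mapped 3D polygons onto target slice planes and merge overlaps.

    A polygon goes to the plane nearest its mean mapped z if that plane
    is within dz/2; otherwise it is outside the target stack and is
    dropped.  Polygons sharing a plane are unioned.  Degenerate results
    (< 3 distinct vertices or area below 1 mm^2) are dropped with a
    warning.
    """
    planes = target.z_planes
    dz = target.spacing[2]
    by_plane: dict[int, list[Polygon]] = {}
    for pts in mapped_polygons:
        zbar = float(pts[:, 2].mean())
        k = int(np.argmin(np.abs(planes - zbar)))
        if abs(planes[k] - zbar) > dz / 2 + 1e-9:
            logger.warning("mapped polygon at z=%.2f mm falls outside the target stack", zbar)
            continue
        poly = Polygon(pts[:, :2])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.area < MIN_POLYGON_AREA_MM2:
            logger.warning("degenerate mapped polygon dropped near z=%.2f mm", zbar)
            continue
        by_plane.setdefault(k, []).append(poly)

    contours: list[Contour] = []
    for k, polys in sorted(by_plane.items()):
        merged = unary_union(polys)
        parts = merged.geoms if isinstance(merged, MultiPolygon) else [merged]
        for part in parts:
            if part.area < MIN_POLYGON_AREA_MM2:
                logger.warning("degenerate merged polygon dropped at z=%.2f mm", planes[k])
                continue
            xy = np.asarray(part.exterior.coords)[:-1]  # closure implicit
            if len(xy) < 3:
                continue
            contours.append(Contour(float(planes[k]), xy))
    return contours


def propagate_contours(
    ss: StructureSet, chain: TransformChain, target: ImageVolume
) -> StructureSet:
    """Propagate a planning structure set onto the target guidance grid.

    Raises
    ------
    ValueError
        If every mapped polygon degenerates or leaves the target stack.
    """
    mapped = map_contour_points(ss, chain)
    contours = regroup_to_slices(mapped, target)
    if not contours:
        raise ValueError("propagation produced no valid contours on the target grid")
    return StructureSet(ss.name, contours, frame=target.frame)
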