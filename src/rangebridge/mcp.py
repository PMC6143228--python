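"""Percent minimum convex polygons.

The q% MCP retains the ceil(n*q/100) relocations closest to the arithmetic
mean center (ties broken by earlier timestamp retained first) and returns
their convex hull.  Areas are reported in hectares, perimeters in meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon, mapping

from .grids import M2_PER_HA
from .telemetry import ConfigurationError, Track


class DegenerateGeometryError(ValueError):
    """Fewer than 3 non-collinear points: no polygon exists."""


@dataclass(frozen=True)
class PolygonRegion:
    """A closed, convex planar region with precomputed metrics."""

    polygon: Polygon
    area_ha: float
    perimeter_m: float

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.polygon.exterior.coords)


def _region_from_polygon(poly: Polygon) -> PolygonRegion:
    return PolygonRegion(
        polygon=poly,
        area_ha=poly.area / M2_PER_HA,
        perimeter_m=poly.exterior.length,
    )


def percent_mcp(track: Track, percent: float = 95.0) -> PolygonRegion:
    """Convex hull of the ``percent``% of fixes closest to the mean center."""
    if not (0.0 < percent <= 100.0):
        raise ConfigurationError("percent must be in (0, 100]")
    xy = track.xy
    n = len(xy)
    keep = math.ceil(n * percent / 100.0)
    center = xy.mean(axis=0)
    dist = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    # stable sort on distance keeps earlier timestamps first among ties
    retained = xy[np.argsort(dist, kind="stable")[:keep]]
    hull = MultiPoint(retained).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0.0:
        raise DegenerateGeometryError(
            f"{keep} retained fixes are collinear or coincident; no MCP exists"
        )
    return _region_from_polygon(hull)


def polygon_metrics(region: PolygonRegion | Polygon) -> tuple[float, float]:
    """(area_ha, perimeter_m): shoelace area / Euclidean edge sum.

    Accepts either a PolygonRegion or a raw closed ring polygon.
    """
    poly = region.polygon if isinstance(region, PolygonRegion) else region
    if not poly.exterior.is_closed:
        raise ConfigurationError("polygon ring must be closed")
    return poly.area / M2_PER_HA, poly.exterior.length


def contains_point(region: PolygonRegion, x: float, y: float) -> bool:
    """Boundary-inclusive point-in-polygon test."""
    p = Point(x, y)
    return bool(region.polygon.covers(p))


def mcp_to_geojson_feature(
    region: PolygonRegion, properties: dict | None = None
) -> dict:
    props = {"area_ha": region.area_ha, "perimeter_m": region.perimeter_m}
    props.update(properties or {})
    return {"type": "Feature", "geometry": mapping(region.polygon), "properties": props}
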