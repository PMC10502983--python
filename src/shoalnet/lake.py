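"""Lake geometry: polygon handling, containment, distance from shore.

Coordinates are planar metric (metres); the polygon's exterior is the
shoreline.  A separate (lat, lon) pair carries the geographic location
used for solar geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, shape
from shapely import wkt as shapely_wkt


@dataclass(frozen=True)
class Lake:
    """A study lake: metric shoreline polygon plus geographic coordinates."""

    polygon: Polygon
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValueError("lake polygon must be simple and valid")
        if abs(self.lat) > 66.6:
            raise ValueError("polar latitudes unsupported (no diel cycle)")

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    @property
    def area_m2(self) -> float:
        return self.polygon.area

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised strict containment test."""
        return shapely.contains_xy(self.polygon, x, y)

    def distance_from_shore(self, x: float, y: float) -> float:
        """Minimum Euclidean distance from an interior point to the shoreline.

        Raises ValueError for points outside the polygon (covers-test, so
        boundary points are allowed and return 0).
        """
        p = Point(x, y)
        if not self.polygon.covers(p):
            raise ValueError(f"point ({x}, {y}) lies outside the lake polygon")
        return self.polygon.exterior.distance(p)

    def distances_from_shore(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised distance-to-shoreline for interior points."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.distance(shapely.get_exterior_ring(self.polygon), pts)


def ellipse_polygon(
    a: float, b: float, n_vertices: int = 64, center: tuple[float, float] = (0.0, 0.0)
) -> Polygon:
    """Elliptical shoreline with semi-axes ``a`` and ``b`` metres."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    xs = center[0] + a * np.cos(t)
    ys = center[1] + b * np.sin(t)
    return Polygon(zip(xs, ys))


def default_lake() -> Lake:
    """A 25 ha ellipse at the latitude of a north German lowland lake.

    Semi-axes 320 m x 250 m give pi*a*b ~ 25.1 ha, matching the scale of
    the study system; geographic position 52.995 N, 13.582 E.
    """
    return Lake(polygon=ellipse_polygon(320.0, 250.0), lat=52.995, lon=13.582)


def lake_from_file(path: str, lat: float, lon: float) -> Lake:
    """Read a shoreline polygon from GeoJSON (``.geojson``/``.json``) or WKT."""
    text = open(path).read()
    if path.endswith((".geojson", ".json")):
        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            geom = shape(obj["features"][0]["geometry"])
        elif obj.get("type") == "Feature":
            geom = shape(obj["geometry"])
        else:
            geom = shape(obj)
    else:
        geom = shapely_wkt.loads(text)
    if not isinstance(geom, Polygon):
        raise ValueError(f"expected a Polygon shoreline, got {geom.geom_type}")
    return Lake(polygon=geom, lat=lat, lon=lon)


def lake_to_geojson(lake: Lake, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(shapely.geometry.mapping(lake.polygon), fh)
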