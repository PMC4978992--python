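"""Species range sizes as minimum convex polygon (MCP) areas.

A species' range size in a time bin is the area (km²) of the smallest convex
polygon enclosing its occurrence points — its extent of occurrence. Points
given as paleocoordinates (degrees) are first mapped to a plane with an
equal-area projection chosen from the point set's extent:

* longitudinal extent < 180° → Lambert azimuthal equal-area, centred on the
  point set's centroid;
* extent ≥ 180° within ±60° latitude → Mollweide;
* extent ≥ 180° reaching beyond ±60° → Albers equal-area conic.

Synthetic planar inputs (already in km) bypass cartography via
``planar_passthrough``. Projections use spherical formulas on the authalic
Earth radius, which preserves areas on the sphere exactly.

Clade-level range is the area of the geometric union of species polygons,
computed on one shared (clade-wide) projection per bin so polygons are
co-registered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union

#: Authalic Earth radius, km (sphere with the ellipsoid's surface area).
EARTH_RADIUS_KM = 6371.0072

LAMBERT = "lambert_azimuthal"
MOLLWEIDE = "mollweide"
ALBERS = "albers"
PASSTHROUGH = "planar_passthrough"


class ProjectionError(ValueError):
    """Point set incompatible with the requested projection."""


class InsufficientPointsError(ValueError):
    """Fewer than three distinct points: no convex polygon exists."""


@dataclass(frozen=True)
class ProjectedPointSet:
    """Occurrence points of one species-bin on an equal-area plane (km)."""

    species_name: str
    bin_index: int
    points: np.ndarray  # (n, 2) in km
    projection_id: str

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 1 or not np.all(np.isfinite(pts)):
            raise ProjectionError("projected point set must be non-empty and finite")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class RangePolygon:
    """Convex-hull range polygon of one species-bin, vertices CCW, km."""

    species_name: str
    bin_index: int
    vertices: np.ndarray  # (m, 2), closed ring (first == last)
    area_km2: float
    degenerate: bool = False
    projection_id: str = PASSTHROUGH

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


def select_projection(lon_extent: float, lat_bounds: tuple[float, float]) -> str:
    """Projection choice from a point set's bounding box (degrees)."""
    if lon_extent < 180.0:
        return LAMBERT
    lo, hi = min(lat_bounds), max(lat_bounds)
    if -60.0 <= lo and hi <= 60.0:
        return MOLLWEIDE
    return ALBERS


def _lambert_azimuthal(lon, lat, lon0, lat0):
    lam, phi = np.radians(lon) - np.radians(lon0), np.radians(lat)
    phi0 = np.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    if np.any(denom < 1e-12):
        raise ProjectionError(
            "point antipodal to the projection centre; use the Albers projection instead"
        )
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return x, y


def _mollweide(lon, lat, lon0):
    lam, phi = np.radians(lon) - np.radians(lon0), np.radians(lat)
    # auxiliary angle: 2θ + sin 2θ = π sin φ  (Newton iteration)
    theta = np.arcsin(np.clip(np.sin(phi), -1, 1))
    for _ in range(50):
        f = 2 * theta + np.sin(2 * theta) - np.pi * np.sin(phi)
        fp = 2 + 2 * np.cos(2 * theta)
        step = np.where(np.abs(fp) > 1e-12, f / np.maximum(fp, 1e-12), 0.0)
        theta = theta - step
        if np.max(np.abs(step)) < 1e-13:
            break
    x = EARTH_RADIUS_KM * np.sqrt(8.0) / np.pi * lam * np.cos(theta)
    y = EARTH_RADIUS_KM * np.sqrt(2.0) * np.sin(theta)
    return x, y


def _albers(lon, lat, lon0, lat0, lat1, lat2):
    lam, phi = np.radians(lon) - np.radians(lon0), np.radians(lat)
    phi0, phi1, phi2 = np.radians(lat0), np.radians(lat1), np.radians(lat2)
    n = (np.sin(phi1) + np.sin(phi2)) / 2.0
    if abs(n) < 1e-9:
        n = 1e-9  # standard parallels symmetric about the equator
    c = np.cos(phi1) ** 2 + 2 * n * np.sin(phi1)
    rho = EARTH_RADIUS_KM * np.sqrt(np.maximum(c - 2 * n * np.sin(phi), 0.0)) / n
    rho0 = EARTH_RADIUS_KM * np.sqrt(max(c - 2 * n * np.sin(phi0), 0.0)) / n
    x = rho * np.sin(n * lam)
    y = rho0 - rho * np.cos(n * lam)
    return x, y


def project(
    points: np.ndarray,
    projection_id: str,
    species_name: str = "",
    bin_index: int = 0,
    center: tuple[float, float] | None = None,
) -> ProjectedPointSet:
    """Project lon/lat points (degrees) to an equal-area plane (km).

    The projection is centred on the point set's centroid unless ``center``
    (lon, lat) is given — passing the clade-wide centroid co-registers
    species polygons for union areas. ``planar_passthrough`` returns the
    coordinates unchanged (synthetic data already in km).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if projection_id == PASSTHROUGH:
        return ProjectedPointSet(species_name, bin_index, pts, projection_id)
    lon, lat = pts[:, 0], pts[:, 1]
    lon0, lat0 = center if center is not None else (_circular_mean_lon(lon), float(np.mean(lat)))
    if projection_id == LAMBERT:
        x, y = _lambert_azimuthal(lon, lat, lon0, lat0)
    elif projection_id == MOLLWEIDE:
        x, y = _mollweide(lon, lat, lon0)
    elif projection_id == ALBERS:
        lat_lo, lat_hi = float(np.min(lat)), float(np.max(lat))
        span = max(lat_hi - lat_lo, 1.0)
        x, y = _albers(lon, lat, lon0, lat0, lat_lo + span / 6.0, lat_hi - span / 6.0)
    else:
        raise ProjectionError(f"unknown projection: {projection_id!r}")
    return ProjectedPointSet(species_name, bin_index, np.column_stack([x, y]), projection_id)


def _circular_mean_lon(lon: np.ndarray) -> float:
    rad = np.radians(lon)
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def mcp_area(pts: ProjectedPointSet) -> RangePolygon:
    """Minimum convex polygon of a projected point set, area in km².

    Duplicate points are removed first; fewer than three distinct points
    raise :class:`InsufficientPointsError` (the caller decides whether to
    drop the species-bin). Collinear sets give area 0 with a degeneracy
    flag.
    """
    distinct = np.unique(pts.points, axis=0)
    if len(distinct) < 3:
        raise InsufficientPointsError(
            f"{pts.species_name or 'point set'}: {len(distinct)} distinct point(s), need >= 3"
        )
    hull = MultiPoint(distinct).convex_hull
    if hull.geom_type != "Polygon":  # collinear: hull degenerates to a segment
        ring = np.asarray(hull.coords if hull.geom_type == "LineString" else [hull.coords[0]] * 2)
        ring = np.vstack([ring, ring[0]])
        return RangePolygon(pts.species_name, pts.bin_index, ring, 0.0, True, pts.projection_id)
    hull = orient(hull, sign=1.0)
    verts = np.asarray(hull.exterior.coords)
    return RangePolygon(pts.species_name, pts.bin_index, verts, float(hull.area), False, pts.projection_id)


def union_area(polys: list[RangePolygon]) -> float:
    """Area (km²) of the geometric union of range polygons.

    Polygons must share a projection plane (one clade-wide projection per
    bin); at most the sum of individual areas, exactly the sum when
    pairwise disjoint.
    """
    polys = [p for p in polys if not p.degenerate]
    if not polys:
        return 0.0
    proj_ids = {p.projection_id for p in polys}
    if len(proj_ids) > 1:
        raise ProjectionError(f"polygons on mixed projections: {sorted(proj_ids)}")
    return float(unary_union([p.as_shapely() for p in polys]).area)


def species_range_km2(lon: np.ndarray, lat: np.ndarray) -> tuple[float, str]:
    """Range size of one species-bin from paleocoordinates (degrees).

    Selects the projection from the point set's extent. Point sets that
    wrap the antimeridian of their centroid with < 180° true extent are
    split at that antimeridian, each part projected with the Lambert
    azimuthal projection, and the part areas summed.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon_extent = float(np.ptp(lon))
    if lon_extent > 180.0 and _wrapped_extent(lon) < 180.0:
        # ranges straddling the dateline: split at the centroid's antimeridian
        anti = (_circular_mean_lon(lon) + 180.0) % 360.0 - 180.0
        west = lon < anti
        total = 0.0
        for mask in (west, ~west):
            if mask.sum() >= 3:
                ps = project(np.column_stack([lon[mask], lat[mask]]), LAMBERT)
                total += mcp_area(ps).area_km2
        return total, LAMBERT
    proj_id = select_projection(lon_extent, (float(lat.min()), float(lat.max())))
    ps = project(np.column_stack([lon, lat]), proj_id)
    return mcp_area(ps).area_km2, proj_id


def _wrapped_extent(lon: np.ndarray) -> float:
    shifted = np.sort(lon % 360.0)
    gaps = np.diff(np.concatenate([shifted, [shifted[0] + 360.0]]))
    return 360.0 - float(np.max(gaps))
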