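"""Spherical-Earth geodesy helpers.

All geographic computation in roadscape (cell areas, polyline lengths,
point-to-line distances, polygon areas) uses a single spherical Earth of
radius ``EARTH_RADIUS_KM`` so that densities (km/km^2) and proportional
range sizes are internally consistent.

Areas use the cylindrical equal-area measure
``A = R^2 * dlambda * d(sin phi)`` (exact on the sphere for
longitude/latitude-aligned quadrilaterals), which makes the area of a
lon/lat box exactly the sum of the areas of the grid cells tiling it.
"""

from __future__ import annotations

import numpy as np

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Kilometres per degree of latitude (and of longitude at the equator).
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def cell_band_area_km2(lat_south: np.ndarray, lat_north: np.ndarray,
                       dlon_deg: float) -> np.ndarray:
    """Area (km^2) of a lon/lat cell spanning ``dlon_deg`` of longitude
    between the two latitudes (degrees). Vectorised over latitudes."""
    phi_s = np.radians(np.asarray(lat_south, dtype=float))
    phi_n = np.radians(np.asarray(lat_north, dtype=float))
    dlam = np.radians(dlon_deg)
    return EARTH_RADIUS_KM ** 2 * dlam * (np.sin(phi_n) - np.sin(phi_s))


def polygon_ring_area_km2(lons: np.ndarray, lats: np.ndarray) -> float:
    """Unsigned area (km^2) of a closed lon/lat ring.

    Shoelace formula in (lambda, sin phi) coordinates times R^2 -- the same
    measure as :func:`cell_band_area_km2`, so a ring tracing the grid
    boundary has exactly the summed area of the cells inside it.
    """
    lam = np.radians(np.asarray(lons, dtype=float))
    s = np.sin(np.radians(np.asarray(lats, dtype=float)))
    # shoelace on the (lam, s) plane
    area = 0.5 * np.sum(lam * np.roll(s, -1) - np.roll(lam, -1) * s)
    return float(abs(area)) * EARTH_RADIUS_KM ** 2


def polygon_area_km2(geometry) -> float:
    """Spherical area (km^2) of a shapely Polygon or MultiPolygon."""
    from shapely.geometry import MultiPolygon, Polygon

    if isinstance(geometry, MultiPolygon):
        return sum(polygon_area_km2(g) for g in geometry.geoms)
    if not isinstance(geometry, Polygon):
        raise TypeError(f"expected Polygon/MultiPolygon, got {type(geometry)}")
    x, y = geometry.exterior.coords.xy
    area = polygon_ring_area_km2(np.asarray(x)[:-1], np.asarray(y)[:-1])
    for ring in geometry.interiors:
        x, y = ring.coords.xy
        area -= polygon_ring_area_km2(np.asarray(x)[:-1], np.asarray(y)[:-1])
    return area


def segment_length_km(lon0, lat0, lon1, lat1, max_step_deg: float = 0.02) -> float:
    """Length (km) of a straight lon/lat segment under the spherical metric
    ``ds = R * sqrt(dphi^2 + cos(phi)^2 dlambda^2)``.

    The segment is subdivided so each piece spans <= ``max_step_deg`` and the
    metric is evaluated at piece midpoints; because the measure is a path
    integral, lengths are additive under splitting the segment anywhere
    (to well below 1e-6 relative), which keeps per-cell clipped road lengths
    consistent with whole-network totals.
    """
    dlon = lon1 - lon0
    dlat = lat1 - lat0
    span = max(abs(dlon), abs(dlat))
    n = max(1, int(np.ceil(span / max_step_deg)))
    t_mid = (np.arange(n) + 0.5) / n
    lat_mid = lat0 + t_mid * dlat
    dphi = np.radians(dlat) / n
    dlam = np.radians(dlon) / n
    steps = EARTH_RADIUS_KM * np.sqrt(
        dphi ** 2 + (np.cos(np.radians(lat_mid)) * dlam) ** 2
    )
    return float(steps.sum())


def polyline_length_km(coords: np.ndarray) -> float:
    """Length (km) of a lon/lat polyline (array of (lon, lat) vertices)."""
    coords = np.asarray(coords, dtype=float)
    total = 0.0
    for i in range(len(coords) - 1):
        total += segment_length_km(coords[i, 0], coords[i, 1],
                                   coords[i + 1, 0], coords[i + 1, 1])
    return total


def shapely_line_length_km(geom) -> float:
    """Spherical length of a shapely LineString / MultiLineString /
    GeometryCollection (points contribute zero)."""
    gtype = geom.geom_type
    if gtype == "LineString":
        return polyline_length_km(np.asarray(geom.coords))
    if gtype in ("MultiLineString", "GeometryCollection"):
        return sum(shapely_line_length_km(g) for g in geom.geoms
                   if g.geom_type in ("LineString", "MultiLineString",
                                      "GeometryCollection"))
    return 0.0


def haversine_km(lon0, lat0, lon1, lat1):
    """Great-circle distance (km); vectorised."""
    phi0 = np.radians(np.asarray(lat0, dtype=float))
    phi1 = np.radians(np.asarray(lat1, dtype=float))
    dphi = phi1 - phi0
    dlam = np.radians(np.asarray(lon1, dtype=float) - np.asarray(lon0, dtype=float))
    a = np.sin(dphi / 2) ** 2 + np.cos(phi0) * np.cos(phi1) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def point_segment_distance_km(lon_p, lat_p, lon0, lat0, lon1, lat1):
    """Distance (km) from points to one lon/lat segment; vectorised over
    points.

    Uses a local equirectangular projection centred on each query point
    (accurate to <<1% at the <=tens-of-km distances buffers use).
    """
    lon_p = np.asarray(lon_p, dtype=float)
    lat_p = np.asarray(lat_p, dtype=float)
    cosphi = np.cos(np.radians(lat_p))
    x0 = (lon0 - lon_p) * cosphi * KM_PER_DEG
    y0 = (lat0 - lat_p) * KM_PER_DEG
    x1 = (lon1 - lon_p) * cosphi * KM_PER_DEG
    y1 = (lat1 - lat_p) * KM_PER_DEG
    dx = x1 - x0
    dy = y1 - y0
    seg2 = dx ** 2 + dy ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(seg2 > 0, -(x0 * dx + y0 * dy) / seg2, 0.0)
    t = np.clip(t, 0.0, 1.0)
    cx = x0 + t * dx
    cy = y0 + t * dy
    return np.hypot(cx, cy)
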