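"""Road-network density, per-proposal buffer summaries and route profiles.

Existing roads carry a 4-level classification (1 = highway down to
4 = track/footpath); Level 4 roads are excluded from density by default
because they are not easily accessible to vehicular traffic. Proposed
roads are assessed with zonal means of the benefit/cost aggregates (and
travel time, population, existing-road density) over all cells whose
centre lies within a buffer distance of the route -- 10 km by default,
matching the analysis resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box
from shapely.strtree import STRtree

from .errors import DegenerateInputError, ValidationError
from .geodesy import (point_segment_distance_km, polyline_length_km,
                      shapely_line_length_km)
from .grid import CellAreas, Grid, Surface, check_same_grid

PROPOSAL = "proposal"
DEFAULT_DENSITY_LEVELS = frozenset({1, 2, 3})


@dataclass
class RoadLine:
    """A classified road polyline in lon/lat coordinates.

    ``level`` is 1-4 for existing roads or the string ``"proposal"``.
    """

    road_id: str
    level: object
    coords: np.ndarray  # (k, 2) of (lon, lat)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2 \
                or len(self.coords) < 2:
            raise ValidationError(
                f"road {self.road_id}: polyline needs >= 2 (lon, lat) vertices")
        if self.level != PROPOSAL and self.level not in (1, 2, 3, 4):
            raise ValidationError(
                f"road {self.road_id}: level must be 1-4 or 'proposal'")

    @property
    def geometry(self) -> LineString:
        return LineString(self.coords)

    def length_km(self) -> float:
        return polyline_length_km(self.coords)

    def reversed(self) -> "RoadLine":
        return RoadLine(self.road_id, self.level, self.coords[::-1].copy())


@dataclass
class RoadSummary:
    """Zonal means over one proposal's buffer (the per-road report row).

    Fields that could not be computed (all-NoData buffer for that
    surface) are ``None``.
    """

    road_id: str
    n_buffer_cells: int
    mean_benefit: float | None = None
    mean_cost: float | None = None
    mean_travel_time: float | None = None
    mean_population: float | None = None
    mean_road_density: float | None = None


def road_density(network: list[RoadLine], grid: Grid, areas: CellAreas,
                 levels=DEFAULT_DENSITY_LEVELS) -> Surface:
    """Existing-road density surface, km of road per km^2.

    Per cell: total length of the (level-filtered) network clipped to the
    cell, divided by the cell's geodesic area. Cells with no road are 0.
    """
    if not network:
        raise ValidationError("road_density needs a non-empty network")
    import logging
    total_km = np.zeros(grid.shape)
    rows, cols = np.nonzero(grid.valid_mask)
    boxes = [box(*grid.cell_bounds(r, c)) for r, c in zip(rows, cols)]
    tree = STRtree(boxes)
    for road in network:
        if road.level not in levels:
            continue
        geom = road.geometry
        if geom.length == 0:
            logging.getLogger(__name__).warning(
                "road %s has zero-length geometry; skipped", road.road_id)
            continue
        for i in tree.query(geom, predicate="intersects"):
            piece = geom.intersection(boxes[i])
            total_km[rows[i], cols[i]] += shapely_line_length_km(piece)
    return Surface(grid, total_km / areas.area, "km/km^2")


def buffer_cells(road: RoadLine, grid: Grid, width_km: float = 10.0,
                 mode: str = "centre") -> list[tuple[int, int]]:
    """Valid cells within ``width_km`` of the road polyline.

    ``mode="centre"`` (default) includes a cell when its *centre* is
    within the buffer distance, matching the analysis resolution;
    ``mode="overlap"`` includes any cell whose square the buffered route
    overlaps.
    """
    if width_km <= 0:
        raise ValidationError("width_km must be > 0")
    lon, lat = grid.center_mesh()
    if mode == "centre":
        dmin = np.full(grid.shape, np.inf)
        c = road.coords
        for i in range(len(c) - 1):
            d = point_segment_distance_km(lon, lat, c[i, 0], c[i, 1],
                                          c[i + 1, 0], c[i + 1, 1])
            dmin = np.minimum(dmin, d)
        inside = (dmin <= width_km) & grid.valid_mask
    elif mode == "overlap":
        # buffer in degrees using the local metre of the route's mid-latitude
        from .geodesy import KM_PER_DEG
        mid_lat = float(np.mean(road.coords[:, 1]))
        width_deg = width_km / (KM_PER_DEG * min(1.0, np.cos(np.radians(mid_lat))))
        buf = road.geometry.buffer(width_deg)
        inside = np.zeros(grid.shape, dtype=bool)
        rows, cols = np.nonzero(grid.valid_mask)
        boxes = [box(*grid.cell_bounds(r, c)) for r, c in zip(rows, cols)]
        tree = STRtree(boxes)
        for i in tree.query(buf, predicate="intersects"):
            inside[rows[i], cols[i]] = True
    else:
        raise ValidationError(f"unknown buffer mode {mode!r}")
    cells = list(zip(*np.nonzero(inside)))
    if not cells:
        raise DegenerateInputError(
            f"road {road.road_id}: no valid cells within {width_km} km")
    return [(int(r), int(c)) for r, c in cells]


def road_summary(road: RoadLine, surfaces: dict[str, Surface], grid: Grid,
                 width_km: float = 10.0) -> RoadSummary:
    """Unweighted means of named surfaces over the road's buffer cells.

    NoData cells are excluded from each surface's mean independently;
    a surface with no data anywhere in the buffer reports ``None``.
    Recognised names: benefit, cost, travel_time, population,
    road_density (mapped onto the matching summary fields).
    """
    for s in surfaces.values():
        check_same_grid(Surface(grid, np.zeros(grid.shape), ""), s)
    cells = buffer_cells(road, grid, width_km)
    idx = tuple(np.array(cells).T)
    summary = RoadSummary(road_id=road.road_id, n_buffer_cells=len(cells))
    field_map = {"benefit": "mean_benefit", "cost": "mean_cost",
                 "travel_time": "mean_travel_time",
                 "population": "mean_population",
                 "road_density": "mean_road_density"}
    for name, surf in surfaces.items():
        vals = surf.values[idx]
        finite = np.isfinite(vals)
        mean = float(vals[finite].mean()) if finite.any() else None
        if name in field_map:
            setattr(summary, field_map[name], mean)
    return summary


def summarize_proposals(proposals: list[RoadLine],
                        surfaces: dict[str, Surface], grid: Grid,
                        width_km: float = 10.0) -> pd.DataFrame:
    """Buffer-summary table for a set of proposals (one row per road)."""
    rows = []
    for road in proposals:
        s = road_summary(road, surfaces, grid, width_km)
        rows.append({"road_id": s.road_id, "n_buffer_cells": s.n_buffer_cells,
                     "mean_benefit": s.mean_benefit, "mean_cost": s.mean_cost,
                     "mean_travel_time": s.mean_travel_time,
                     "mean_population": s.mean_population,
                     "mean_road_density": s.mean_road_density})
    return pd.DataFrame(rows)


def traverse_cells(road: RoadLine, grid: Grid) -> list[tuple[int, int]]:
    """Cells intersected by the polyline, in order of first entry along
    the route from its first vertex.

    Exact traversal: each segment's crossings with the grid's row/column
    lines are computed parametrically, and the cell occupied between
    consecutive crossings is read off at the interval midpoint.
    """
    lon0, lat0 = grid.origin
    cs = grid.cell_size
    seen: set[tuple[int, int]] = set()
    ordered: list[tuple[int, int]] = []
    c = road.coords
    for i in range(len(c) - 1):
        (x0, y0), (x1, y1) = c[i], c[i + 1]
        ts = {0.0, 1.0}
        if x1 != x0:
            j0 = int(np.floor((min(x0, x1) - lon0) / cs))
            j1 = int(np.ceil((max(x0, x1) - lon0) / cs))
            for j in range(j0, j1 + 1):
                t = (lon0 + j * cs - x0) / (x1 - x0)
                if 0 < t < 1:
                    ts.add(t)
        if y1 != y0:
            k0 = int(np.floor((lat0 - max(y0, y1)) / cs))
            k1 = int(np.ceil((lat0 - min(y0, y1)) / cs))
            for k in range(k0, k1 + 1):
                t = (lat0 - k * cs - y0) / (y1 - y0)
                if 0 < t < 1:
                    ts.add(t)
        for ta, tb in zip(*(lambda s: (s[:-1], s[1:]))(sorted(ts))):
            tm = (ta + tb) / 2
            cell = grid.cell_of(x0 + tm * (x1 - x0), y0 + tm * (y1 - y0))
            if cell is not None and cell not in seen:
                seen.add(cell)
                ordered.append(cell)
    if not ordered:
        raise DegenerateInputError(
            f"road {road.road_id} does not intersect the grid")
    return ordered


def road_profile(road: RoadLine, benefit: Surface, cost: Surface,
                 grid: Grid) -> pd.DataFrame:
    """Along-route benefit/cost profile: one row per traversed cell, in
    first-entry order (columns: row, col, benefit, cost)."""
    check_same_grid(benefit, cost)
    cells = traverse_cells(road, grid)
    return pd.DataFrame(
        [{"road_id": road.road_id, "order": k, "row": r, "col": c,
          "benefit": float(benefit.values[r, c]),
          "cost": float(cost.values[r, c])}
         for k, (r, c) in enumerate(cells)])
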