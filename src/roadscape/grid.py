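"""Raster data model: grids, surfaces, cell areas, and the equal-area
decile rescaling that normalises every layer before layers are combined.

Conventions
-----------
* Cell-centre registration, row-major from the upper-left origin;
  row 0 is the northernmost row, column 0 the westernmost column.
* ``origin`` is the (lon, lat) of the *upper-left corner* of cell (0, 0).
* NoData is ``NaN``; a cell is NoData if the grid's validity mask is false
  (permanent water / outside the study region) or its value is missing.
  NoData propagates -- it is never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateInputError, ShapeError, ValidationError
from .geodesy import cell_band_area_km2


@dataclass(eq=False)
class Grid:
    """A shared lon/lat raster lattice.

    Parameters
    ----------
    n_rows, n_cols:
        Lattice dimensions (>= 1 each).
    cell_size:
        Cell edge in degrees; 0.0833 deg (~10 km) is the analysis scale.
    origin:
        (lon, lat) of the upper-left corner of the grid.
    valid_mask:
        Boolean (n_rows, n_cols) array; False marks permanent water or
        cells outside the study region. Defaults to all-valid.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 0.0833
    origin: tuple[float, float] = (98.0, 29.0)
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and column")
        if self.valid_mask is None:
            self.valid_mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.n_rows, self.n_cols):
            raise ShapeError(
                f"valid_mask shape {self.valid_mask.shape} != "
                f"({self.n_rows}, {self.n_cols})")
        if not self.valid_mask.any():
            raise ValidationError("grid has no valid cells")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def lon_centers(self) -> np.ndarray:
        lon0 = self.origin[0]
        return lon0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        lat0 = self.origin[1]
        return lat0 - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) of cell centres."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of one cell."""
        lon0, lat0 = self.origin
        w = lon0 + col * self.cell_size
        n = lat0 - row * self.cell_size
        return (w, n - self.cell_size, w + self.cell_size, n)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell index containing a point, or None if outside the grid."""
        col = int(np.floor((lon - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - lat) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def same_lattice(self, other: "Grid") -> bool:
        return (self.shape == other.shape
                and abs(self.cell_size - other.cell_size) < 1e-12
                and abs(self.origin[0] - other.origin[0]) < 1e-9
                and abs(self.origin[1] - other.origin[1]) < 1e-9)

    def __eq__(self, other):
        return (isinstance(other, Grid) and self.same_lattice(other)
                and np.array_equal(self.valid_mask, other.valid_mask))


@dataclass(eq=False)
class Surface:
    """One value per valid grid cell, with a units tag.

    ``values`` is a float array shaped like the grid; NaN marks NoData.
    On construction, cells outside the grid's validity mask are forced to
    NaN so a surface can never carry data over water.
    """

    grid: Grid
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.array(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ShapeError(
                f"surface shape {self.values.shape} != grid {self.grid.shape}")
        self.values[~self.grid.valid_mask] = np.nan

    @property
    def defined_mask(self) -> np.ndarray:
        """Cells that are valid on the grid and carry a finite value."""
        return self.grid.valid_mask & np.isfinite(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined_mask]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Surface":
        return Surface(self.grid, values, self.units if units is None else units)

    def __eq__(self, other):
        return (isinstance(other, Surface) and self.grid == other.grid
                and self.units == other.units
                and np.array_equal(self.values, other.values, equal_nan=True))


@dataclass
class CellAreas:
    """Geodesic cell areas (km^2), constant along each row."""

    grid: Grid
    area: np.ndarray  # (n_rows, n_cols) km^2

    def area_ha(self) -> np.ndarray:
        return self.area * 100.0  # 1 km^2 = 100 ha


RESCALED_UNITS = "0-1 rescaled"


def equal_area_rescale(surface: Surface) -> Surface:
    """Rank-based equal-area rescaling of a surface onto [0, 1].

    Each cell receives ``(rank - 0.5) / n`` where ranks are midranks
    (ties averaged) over the n defined cells, so each tenth of the cells
    falls in one decile interval of the output -- the "equal-area decile"
    normalisation applied before any layers are added or averaged, which
    prevents outlying values from dominating a combination.

    An all-constant surface maps every cell to 0.5 (one giant midrank),
    not an error. Fewer than 10 defined cells raises
    :class:`DegenerateInputError`.
    """
    mask = surface.defined_mask
    n = int(mask.sum())
    if n < 10:
        raise DegenerateInputError(
            f"equal_area_rescale needs >= 10 defined cells, got {n}")
    out = np.full(surface.grid.shape, np.nan)
    ranks = rankdata(surface.values[mask], method="average")
    out[mask] = (ranks - 0.5) / n
    return Surface(surface.grid, out, RESCALED_UNITS)


def apply_mask(surface: Surface, grid: Grid) -> Surface:
    """Re-impose a grid's validity mask on a surface (water exclusion).

    Valid cells keep their values; invalid cells become NoData. The
    returned surface lives on ``grid``.
    """
    if surface.values.shape != grid.shape:
        raise ShapeError(
            f"surface shape {surface.values.shape} != grid {grid.shape}")
    return Surface(grid, surface.values.copy(), surface.units)


def cell_areas(grid: Grid) -> CellAreas:
    """Per-cell areas in km^2 from the spherical-Earth band formula.

    ``A = R^2 * dlambda * (sin(lat_north) - sin(lat_south))`` per cell,
    so area is the same across a row and shrinks with |latitude|.
    """
    lat_c = grid.lat_centers()
    if np.any(np.abs(lat_c) + grid.cell_size / 2 > 90):
        raise ValidationError("grid rows extend beyond +/-90 deg latitude")
    half = grid.cell_size / 2
    row_areas = cell_band_area_km2(lat_c - half, lat_c + half, grid.cell_size)
    area = np.repeat(row_areas[:, None], grid.n_cols, axis=1)
    return CellAreas(grid, area)


def check_same_grid(*surfaces: Surface) -> Grid:
    """Assert all surfaces share one lattice; returns the common grid."""
    g = surfaces[0].grid
    for s in surfaces[1:]:
        if not g.same_lattice(s.grid):
            raise ShapeError("surfaces are on different grids")
    return g


def check_rescaled(surface: Surface, name: str = "surface") -> None:
    vals = surface.defined_values()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValidationError(f"{name} is not 0-1 rescaled "
                              f"(range {vals.min():.3g}..{vals.max():.3g})")
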