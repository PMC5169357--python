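"""Potential food-production benefit of road development.

The benefit of improving transport links is proxied by how much extra food
energy a cell could produce on its *existing* cropland (its production
gap) times how isolated it currently is (travel time to the nearest city
of >50,000 people). Both factors are equal-area rescaled before being
multiplied, and the product is rescaled once more to give the aggregate
benefit surface on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grid import (Grid, Surface, check_same_grid, equal_area_rescale)


@dataclass
class CropLayer:
    """One crop's yield gap, harvested area and food-energy content.

    yield_gap:
        Gap between attainable and current yield, t/ha/y, per cell.
    harvested_area:
        Area currently harvested for this crop, ha per cell.
    energy_content:
        Food energy per tonne of product, GJ/t.
    current_yield:
        Optional current yield surface (t/ha/y), used for relative
        production-increase accounting; not required by the core pipeline.
    """

    name: str
    yield_gap: Surface
    harvested_area: Surface
    energy_content: float
    current_yield: Surface | None = None

    def __post_init__(self):
        if self.energy_content <= 0:
            raise ValidationError(
                f"crop {self.name}: energy content must be > 0 GJ/t")
        for s, label in ((self.yield_gap, "yield gap"),
                         (self.harvested_area, "harvested area")):
            vals = s.defined_values()
            if vals.size and vals.min() < 0:
                raise ValidationError(
                    f"crop {self.name}: negative {label} values")


def production_gap(crops: list[CropLayer], grid: Grid) -> Surface:
    """Extra food energy attainable on existing cropland, GJ/cell/y.

    Per cell: sum over crops of yield_gap (t/ha/y) x harvested area (ha)
    x energy content (GJ/t). Cells with no cropland score 0 (they offer no
    yield-closing potential, but they are still part of the landscape),
    not NoData.
    """
    if not crops:
        raise ValidationError("production_gap needs at least one crop")
    total = np.zeros(grid.shape)
    for crop in crops:
        check_same_grid(Surface(grid, total, ""), crop.yield_gap,
                        crop.harvested_area)
        gap = np.nan_to_num(crop.yield_gap.values, nan=0.0)
        area = np.nan_to_num(crop.harvested_area.values, nan=0.0)
        total += gap * area * crop.energy_content
    return Surface(grid, total, "GJ/cell/y")


def current_production(crops: list[CropLayer], grid: Grid) -> Surface:
    """Current food-energy output, GJ/cell/y, where crops carry a
    current-yield surface (crops without one contribute nothing)."""
    total = np.zeros(grid.shape)
    for crop in crops:
        if crop.current_yield is None:
            continue
        cur = np.nan_to_num(crop.current_yield.values, nan=0.0)
        area = np.nan_to_num(crop.harvested_area.values, nan=0.0)
        total += cur * area * crop.energy_content
    return Surface(grid, total, "GJ/cell/y")


def _isolation_weighted(quantity: Surface, travel_time: Surface,
                        final_rescale: bool) -> Surface:
    check_same_grid(quantity, travel_time)
    q = equal_area_rescale(quantity)
    t = equal_area_rescale(travel_time)
    product = Surface(quantity.grid, q.values * t.values, "0-1 product")
    return equal_area_rescale(product) if final_rescale else product


def benefit_surface(prod_gap: Surface, travel_time: Surface,
                    final_rescale: bool = True) -> Surface:
    """Aggregate potential food-production benefit on [0, 1].

    Rescales the production gap and travel time each to 0-1 equal-area
    deciles, multiplies them, and (by default) rescales the product so
    the aggregate itself sits on the equal-area decile scale used by the
    benefit-cost overlay. ``final_rescale=False`` returns the raw product
    of the two rescaled factors instead.
    """
    return _isolation_weighted(prod_gap, travel_time, final_rescale)


def population_benefit(population: Surface, travel_time: Surface,
                       final_rescale: bool = True) -> Surface:
    """Population-based alternative benefit surface: people x isolation.

    Substitutes population density for the production gap in the same
    pipeline -- a measure of how many people might gain from better
    access rather than of agricultural potential. Used as the third
    sensitivity test.
    """
    return _isolation_weighted(population, travel_time, final_rescale)
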