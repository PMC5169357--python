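"""Potential environmental cost of road development.

Three component layers, each ending on the 0-1 equal-area decile scale:

* **Terrestrial vertebrates** -- per cell, the proportion of each species'
  global range inside the cell (cell area / global range area), summed
  over the species of a class whose range touches the cell, weighted by
  the proportion of the cell still under natural forest/grassland/shrub;
  class totals are rescaled and the three class layers averaged.
* **Carbon storage** -- the carbon lost if remaining habitat were
  converted to agriculture (regionally, mostly rice paddy): all biomass
  carbon is lost while carbon in the top 30 cm of soil *gains* 10%
  under paddy management, so net per-ha loss = biomass - 0.10 x soil30,
  floored at zero, times natural cover and cell area.
* **Local climate regulation** -- per-ecoregion Heat (deg C) and Moisture
  (mm/d) Regulation Indices describing how completely removing natural
  vegetation would change heat and moisture loading of the atmosphere;
  each index is assigned to cells by ecoregion, rescaled, weighted by
  intact proportion, and the two are averaged.

The aggregate cost is the per-cell mean of the three layers (max as a
sensitivity variant), rescaled once more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box
from shapely.strtree import STRtree

from .errors import ValidationError
from .grid import (CellAreas, Surface, check_rescaled, check_same_grid,
                   equal_area_rescale)

logger = logging.getLogger(__name__)

VERTEBRATE_CLASSES = ("mammal", "bird", "amphibian")


@dataclass
class SpeciesRange:
    """A species' range polygon and the size of its global range.

    ``geometry`` is a shapely Polygon/MultiPolygon in lon/lat;
    ``global_range_area`` is the species' *total* (not in-region) range
    area in km^2, the denominator of proportional range size.
    """

    species_id: str
    v_class: str
    geometry: object
    global_range_area: float

    def __post_init__(self):
        if self.v_class not in VERTEBRATE_CLASSES:
            raise ValidationError(
                f"unknown vertebrate class {self.v_class!r}")
        if self.global_range_area <= 0:
            raise ValidationError(
                f"species {self.species_id}: global range area must be > 0")
        if self.geometry is None or self.geometry.is_empty:
            raise ValidationError(
                f"species {self.species_id}: empty range geometry")


@dataclass
class EcoregionIndices:
    """Per-ecoregion climate-regulation indices (HRI deg C, MRI mm/d)."""

    ecoregion_id: int
    hri: float
    mri: float


def _cell_boxes(grid):
    """Shapely boxes for all valid cells + their (row, col) indices."""
    rows, cols = np.nonzero(grid.valid_mask)
    boxes = [box(*grid.cell_bounds(r, c)) for r, c in zip(rows, cols)]
    return boxes, rows, cols


def vertebrate_class_scores(ranges: list[SpeciesRange],
                            natural_cover: Surface,
                            areas: CellAreas) -> dict[str, Surface]:
    """Raw (un-rescaled) per-class importance scores.

    Per cell: sum over class species present (range polygon intersects
    the cell square -- any overlap counts) of cell_area/global_range_area,
    times the cell's natural-cover proportion.
    """
    grid = natural_cover.grid
    check_same_grid(natural_cover, Surface(grid, areas.area, ""))
    boxes, rows, cols = _cell_boxes(grid)
    tree = STRtree(boxes)
    cover = np.nan_to_num(natural_cover.values, nan=0.0)

    out: dict[str, Surface] = {}
    for v_class in VERTEBRATE_CLASSES:
        members = [r for r in ranges if r.v_class == v_class]
        if not members:
            continue
        raw = np.zeros(grid.shape)
        for sp in members:
            idx = tree.query(sp.geometry, predicate="intersects")
            for i in idx:
                r, c = rows[i], cols[i]
                raw[r, c] += areas.area[r, c] / sp.global_range_area
        raw *= cover
        raw[~grid.valid_mask] = np.nan
        out[v_class] = Surface(grid, raw, "proportional range x cover")
    return out


def vertebrate_importance(ranges: list[SpeciesRange],
                          natural_cover: Surface,
                          areas: CellAreas,
                          rescale_output: bool = True) -> Surface:
    """Vertebrate-importance cost layer on [0, 1].

    Rescales each class's raw score, averages the (up to three) class
    layers, and rescales the mean so the layer enters the cost aggregate
    on the common decile scale. Classes with no species are skipped with
    a warning.
    """
    if not ranges:
        raise ValidationError("vertebrate_importance needs >= 1 species range")
    scores = vertebrate_class_scores(ranges, natural_cover, areas)
    for v_class in VERTEBRATE_CLASSES:
        if v_class not in scores:
            logger.warning("no %s ranges supplied; class skipped", v_class)
    rescaled = [equal_area_rescale(s).values for s in scores.values()]
    mean = Surface(natural_cover.grid, np.mean(rescaled, axis=0),
                   "mean class importance")
    return equal_area_rescale(mean) if rescale_output else mean


def carbon_cost(biomass: Surface, soil30: Surface, natural_cover: Surface,
                areas: CellAreas, rescale_output: bool = True) -> Surface:
    """Carbon-loss cost layer on [0, 1].

    Net per-ha loss on conversion = biomass - 0.10 x soil30 (all biomass
    carbon lost; top-30cm soil carbon gains 10% under paddy management),
    floored at 0, x natural cover x cell area (ha) -> tonnes C per cell,
    then rescaled.
    """
    grid = check_same_grid(biomass, soil30, natural_cover)
    for s, label in ((biomass, "biomass"), (soil30, "soil")):
        vals = s.defined_values()
        if vals.size and vals.min() < 0:
            raise ValidationError(f"negative {label} carbon stocks")
    net_per_ha = biomass.values - 0.10 * soil30.values
    net_per_ha = np.maximum(net_per_ha, 0.0)
    raw = net_per_ha * np.nan_to_num(natural_cover.values, nan=0.0) \
        * areas.area_ha()
    surf = Surface(grid, raw, "t C/cell")
    return equal_area_rescale(surf) if rescale_output else surf


def climate_cost(ecoregion_id: Surface, indices: list[EcoregionIndices],
                 natural_cover: Surface,
                 rescale_output: bool = True) -> Surface:
    """Local climate-regulation cost layer on [0, 1].

    For each index (HRI, MRI): assign the ecoregion value to its cells,
    rescale across cells, multiply by intact (natural-cover) proportion.
    The layer is the mean of the two, rescaled.
    """
    grid = check_same_grid(ecoregion_id, natural_cover)
    table = {e.ecoregion_id: e for e in indices}
    ids = ecoregion_id.values
    defined = ecoregion_id.defined_mask
    present = np.unique(ids[defined]).astype(int)
    unknown = [i for i in present if i not in table]
    if unknown:
        raise ValidationError(f"cells reference unknown ecoregion ids {unknown}")

    cover = np.nan_to_num(natural_cover.values, nan=0.0)
    parts = []
    for attr in ("hri", "mri"):
        vals = np.full(grid.shape, np.nan)
        for eid in present:
            vals[defined & (ids == eid)] = getattr(table[eid], attr)
        scaled = equal_area_rescale(Surface(grid, vals, attr))
        parts.append(scaled.values * cover)
    mean = Surface(grid, np.mean(parts, axis=0), "mean regulation x cover")
    return equal_area_rescale(mean) if rescale_output else mean


def aggregate_cost(layers: list[Surface], rule: str = "mean",
                   rescale_output: bool = True) -> Surface:
    """Combine 0-1 cost layers into the aggregate cost surface.

    ``rule="mean"`` (default) averages the layers; ``rule="max"`` takes
    each cell's worst value across layers (the combining-rule sensitivity
    variant). The combined surface is rescaled onto equal-area deciles.
    """
    if not layers:
        raise ValidationError("aggregate_cost needs >= 1 layer")
    grid = check_same_grid(*layers)
    for i, layer in enumerate(layers):
        check_rescaled(layer, f"cost layer {i}")
    stack = np.stack([s.values for s in layers])
    if rule == "mean":
        combined = np.mean(stack, axis=0)
    elif rule == "max":
        combined = np.max(stack, axis=0)
    else:
        raise ValidationError(f"unknown aggregation rule {rule!r}")
    surf = Surface(grid, combined, "0-1 combined")
    return equal_area_rescale(surf) if rescale_output else surf
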