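# roadscape

Raster benefit–cost assessment of road development for spatial
conservation planning.

New and improved roads can raise rural incomes and food production, but
they also open remaining natural habitats to conversion, with losses of
biodiversity, carbon and the climate-regulating services of intact
vegetation. `roadscape` implements a transparent framework for comparing
these two sides on a common grid (~10 km cells, 0.0833°), so planners can
see where road investment could close crop yield gaps at relatively low
environmental cost — and where it would do the most harm. It is aimed at
conservation scientists and infrastructure-planning analysts working with
gridded agricultural, biodiversity and carbon layers.

## The method

Every layer is normalised before layers are combined with an
**equal-area decile rescaling**: cell values are replaced by
`(rank − ½)/n` (ties take their average rank), so each tenth of the cells
occupies one decile of the 0–1 scale and outliers cannot dominate a sum
or product.

**Potential benefit.** The *production gap* of a cell is

```
G_i = Σ_c  gap_{ic} · area_{ic} · e_c        [GJ/cell/y]
```

summed over crops *c*, with `gap` the yield gap (t/ha/y) between current
and climatically attainable yields, `area` the harvested area (ha) and
`e_c` the crop's food-energy content (GJ/t). Using current harvested area
means the benefit reflects intensification, not cropland expansion
(land sparing). The aggregate benefit is
`rescale( rescale(G) × rescale(T) )` where `T` is travel time (min) to
the nearest city of >50,000 people — road improvements matter most where
gaps are large *and* access is poor.

**Potential cost** is the rescaled mean (or, in a sensitivity variant,
the cell-wise max) of three 0–1 layers:

* *vertebrates* — per class (mammals, birds, amphibians), the sum over
  species present of `cell_area / global_range_area`, weighted by the
  proportion of the cell still under natural cover; class layers are
  rescaled and averaged;
* *carbon* — net loss on conversion `= biomass − 0.10 · soil30` t C/ha
  (all biomass carbon lost, top-30 cm soil carbon gains 10% under paddy
  management), floored at 0, × natural cover × cell area;
* *climate regulation* — per-ecoregion Heat (°C) and Moisture (mm/d)
  Regulation Indices assigned to cells, rescaled, × intact proportion,
  averaged.

Benefit and cost are intersected in a **bivariate (dual-colour)
classification**; sensitivity tests swap one ingredient at a time and
report the fraction of cells whose score changes by more than |0.2|.
Individual road proposals are scored by mean benefit, cost, travel time,
population and existing-road density (Levels 1–3, km/km²) in a 10 km
buffer, plus an along-route cell profile.

A built-in synthetic landscape generator produces complete input bundles
(accessibility-graded conversion, isolation-dependent yield gaps,
cover-correlated carbon, Voronoi ecoregions, species ranges spanning two
orders of magnitude in size, city-anchored road networks), so the whole
pipeline is testable end to end without external GIS data.

## Worked example

```python
import numpy as np
import roadscape as rs

bundle = rs.generate_landscape(rs.LandscapeParams(seed=1))
gap = rs.production_gap(bundle.crops, bundle.grid)
benefit = rs.benefit_surface(gap, bundle.travel_time)
cost, _ = rs.build_cost(bundle, rule="mean")

m = benefit.defined_mask & cost.defined_mask
print(np.corrcoef(benefit.values[m], cost.values[m])[0, 1])
```

Running `python examples/02_benefit_cost_overlay.py` prints:

```
production gap: 0.75 billion GJ/y attainable without cropland expansion
benefit-cost Pearson r = -0.33 -> broadly negative association: converted, gap-rich cells hold little habitat value
  high-benefit/low-cost         3106 cells (32.0%)
  low-benefit/low-cost          1744 cells (18.0%)
  low-benefit/high-cost         3106 cells (32.0%)
  high-benefit/high-cost        1744 cells (18.0%)
```

0.75 billion GJ/y is the extra food energy attainable by closing yield
gaps on existing cropland; the negative correlation means the places
where roads would help production most are broadly the places where they
would harm habitats least; the 32% high-benefit/low-cost cells are the
candidates for targeted road investment, while high/high cells (18%)
flag potential conflict. The other scripts in `examples/` walk through
landscape generation, the three sensitivity tests and per-road buffer
assessment.

A thin CLI mirrors the library: `roadscape simulate | benefit | cost |
intersect | sensitivity | roads | run` (see `roadscape --help`); `run`
executes the whole pipeline from a YAML config and writes every surface
(ASCII-grid rasters), the quadrant counts, changed fractions, road
summary and profile CSVs, and a run log.

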