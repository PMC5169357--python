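# Methods

This note records the model, the numerical choices and the reasoning
behind the design decisions in `roadscape`, and what the synthetic
landscapes do and do not demonstrate.

## Grid model and rescaling

Analysis happens on a lon/lat lattice of 0.0833° (~10 km) cells,
cell-centre registered, row-major from the upper-left origin. Permanent
water and out-of-region cells are masked; NoData (NaN) propagates
through every operation and is never imputed.

All areas, lengths and distances use one spherical Earth
(R = 6371.0088 km). Cell areas use the band formula
`R² Δλ (sin φ_N − sin φ_S)` — exact on the sphere for lon/lat-aligned
quadrilaterals, constant along a row, and consistent with the polygon
area measure (shoelace in (λ, sin φ) space), so a species covering the
whole study region has per-cell proportional ranges that sum to exactly 1.
Polyline lengths integrate `ds = R √(dφ² + cos²φ dλ²)` with midpoint
evaluation on ≤0.02° pieces; because this is a path integral it is
additive under splitting, keeping per-cell clipped road lengths
consistent with whole-network totals to ≪10⁻⁶ relative.

**Equal-area decile rescaling** is an equal-cell-count rank transform:
`(rank − ½)/n` over defined cells, ties sharing their average rank
(midrank). Consequences, all tested: each decile interval holds n/10
cells up to tie groups; the transform is invariant under any strictly
increasing re-expression of the input (so benefit is identical whether
travel time is in minutes or hours); an all-constant layer maps to 0.5
everywhere (one giant tie), which is the documented degenerate
behaviour, not an error. Midrank keeps boundary tie groups together —
the simplest deterministic choice; whether source analyses split them is
unknowable from the outside, and no downstream statistic here depends on
it. Cells are treated as the unit of "area": true cell areas vary only
~2% per degree of latitude at tropical latitudes, and decile plots of
this kind conventionally count cells.

## Benefit surface

`production_gap` multiplies, per crop, yield gap (t/ha/y) × harvested
area (ha/cell) × energy content (GJ/t) and sums across crops. Cells with
no cropland score 0 rather than NoData: they genuinely offer no
intensification potential and belong at the bottom of the ranking, not
outside it. The aggregate benefit rescales the production gap and travel
time separately, multiplies them, and rescales the product once more.
Rescaling before multiplying stops either factor's heavy tail from
dominating; rescaling the product puts the aggregate on the same decile
scale as the cost surface for the overlay. `final_rescale=False` exposes
the un-rescaled product for anyone preferring the two-step variant; the
difference is a monotone relabeling, so rankings and quadrant
classifications are unaffected.

The population-based alternative (`population_benefit`) runs population
density through the identical pipeline — a deliberate substitution of
"people who might gain access" for "food energy attainable", used as the
third sensitivity test.

## Cost layers

*Vertebrates.* Presence is any intersection between the range polygon
and the cell square — presence/absence, not fractional overlap
(fractional weighting is available via `vertebrate_class_scores` for
experimentation, but the headline layer uses intersects, which is
robust to the coarse and error-prone edges of range maps). Each present
species contributes `cell_area / global_range_area`; narrow endemics
therefore dominate wide-ranging species. The class sum is weighted by
the natural-cover proportion, each class layer is rescaled, the class
layers are averaged, and the mean is rescaled once more before entering
the aggregate — consistent with the global rule that layers are rescaled
whenever they are combined.

*Carbon.* Net committed loss per hectare on conversion is
`biomass − 0.10 × soil30`: complete biomass carbon loss and a 10% *gain*
in the top-30 cm soil stock, reflecting post-conversion paddy
management. The net loss is floored at zero before weighting by cover
and cell area: in this framework a conversion "cost" cannot be negative,
and without the floor soil-rich/biomass-poor cells would be rewarded for
conversion; the choice only affects cells already near the bottom of the
ranking.

*Climate regulation.* Heat and Moisture Regulation Indices are
per-ecoregion constants describing how complete vegetation removal
would change sensible- and latent-heat loading; each index surface is
rescaled, weighted by intact cover, and the two are averaged and
rescaled. With a single ecoregion the layer degenerates to a monotone
map of cover — the expected limiting behaviour.

`aggregate_cost` averages the three 0–1 layers (or takes the cell-wise
max as the pessimistic sensitivity variant) and rescales. A validation
pass rejects inputs outside [0, 1] so un-rescaled layers cannot slip in.

## Intersection and sensitivity

Bivariate classification bins both surfaces with
`floor(value × n_bins)`, clamping 1.0 into the top bin. Quadrants split
both axes at 0.5 — a median split on the decile scale, exposed as a
summary convenience; the underlying two-axis bins are the primary
product, and no claim is made that the 0.5 split reproduces any
particular published verbal category.

Difference maps are plain per-cell `new − original` (bounded in [−1, 1]
because both surfaces are 0–1); the changed-cell statistic counts
`|Δ| > threshold` with *strict* inequality, reading ">|0.2|" literally —
for continuous surfaces the boundary is measure-zero, so the choice is
cosmetic but fixed.

## Road assessment

Road density clips Levels 1–3 polylines (Level 4 tracks/footpaths are
excluded by default: not vehicular) to each cell square and divides the
spherical length by cell area. Buffer membership uses the cell-centre
rule — a cell belongs to a road's buffer when its centre lies within the
buffer width (default 10 km, matching the cell size); an any-overlap
mode exists but centre membership is the default because it is
deterministic at the analysis resolution and makes buffer area
approximately proportional to route length. Buffer means are unweighted
cell means (cell areas vary by <1% across a 20 km band), with NoData
excluded per surface independently. Route profiles traverse the exact
sequence of cells a polyline crosses, computed from parametric
crossings of the grid's row/column lines, deduplicated at first entry;
reversing a route exactly reverses its profile.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes:

* **travel time** = 1.2 min/km × distance to the nearest of 5 cities
  (≈50 km/h average), with smoothed multiplicative noise;
* **natural cover** = logistic (gain `conversion_steepness`, default 6)
  of a *conversion pressure* combining normalised travel time (weight
  0.4) with a large-scale suitability field (smoothed Gaussian,
  σ = 6 cells, unit sd). The suitability term matters: if conversion
  were a function of accessibility alone, the isolation factor of the
  benefit product would mirror the cost surface and cancel the
  production-gap signal. Real agricultural frontiers follow fertile
  plains and deltas as much as market proximity, which is exactly what
  decouples the two;
* **cropland** occupies 90% of the converted fraction, shared across 17
  crops by Dirichlet weights with cell-level share noise, so cropland +
  natural cover can never exceed cell capacity (a tested invariant);
* **yield gaps** rise linearly with travel time
  (`yieldgap_isolation_slope`, default 0.004 t/ha/y per minute — ≈1 t/ha
  over a 4-hour isolation gradient) plus Gaussian noise (`noise_sd`,
  default 0.15 t/ha): isolated farms face higher input costs and weaker
  market pull. The slope is recoverable by regression within 20%;
* the **alternative crop database** (16 crops) differs from the primary
  one by a shared smoothed regional bias field (log-sd 1.2), per-crop
  scale factors (log-sd 0.4) and small cell noise — independently
  derived attainable-yield maps disagree regionally and systematically,
  not cell-by-cell (i.i.d. cell noise would simply average out across
  crops);
* **carbon stocks** increase with cover (biomass ≈ 10 + 180·cover^1.3
  t/ha; soil ≈ 30 + 40·cover t/ha) plus smoothed noise;
* **ecoregions** are a nearest-seed (Voronoi) partition — contiguous by
  construction — with indices drawn per region (HRI 0.5–2.5 °C, MRI
  0.3–2.5 mm/d);
* **population** sums exponential kernels around cities (peak ≈ 1,500
  persons/km², decay 10–30 km) over a rural background;
* **roads** connect cities by a minimum spanning tree (Level 1) with
  redundant links (2), spurs (3) and short tracks (4); **proposals** run
  from low-cover to high-cover cells, so each crosses contrasting
  landscape;
* **species ranges** are rotated ellipses with log-uniform areas over
  10²–10^4.5 km² (≥ two orders of magnitude within a class), centres
  weighted by natural cover; the generating ellipse's analytic area
  (πab) is the species' global range area.

One master seed feeds independent named substreams (mask, cities,
cover, crops, carbon, ecoregions, population, roads, proposals, ranges),
so adding a stage never perturbs another — every generated object is
bit-reproducible from the seed.

Because converted, low-cover cells are the ones carrying cropland and
hence production gaps, while intact cells carry the species, carbon and
regulation value, the benefit and cost aggregates come out negatively
correlated (mean r ≈ −0.4 over 20 default seeds; negative in all 20).
This is the qualitative structure the framework is designed to reveal,
built in by construction — passing tests show the *pipeline* recovers
the structure faithfully, not that any real region has it.

What the generator does **not** emulate: real crop phenology or
calibrated yields, actual range-map shapes, empirical travel-time
frictions, or the specific geography of any region. Quantities that
depend on those — total production-gap tonnage, the exact changed-cell
percentages of the sensitivity tests — are therefore illustrative. In
particular, the synthetic alternative-database and max-rule tests move
fewer cells (≈4–9% and ≈2–4% at >|0.2|) than analyses on real regional
data report, largely because half the synthetic landscape has near-zero
cropland under *both* crop databases and strongly cover-correlated cost
layers; the population-substitution test (≈45–49%) is comparable.

## Numerical details and edge cases

* Rescaling requires ≥ 10 defined cells (a decile needs at least one
  cell); fewer raises `DegenerateInputError`.
* `bivariate_classify` validates both inputs lie in [0, 1].
* Zero-length road geometries are skipped with a warning; a road whose
  buffer contains no valid cell, or that never enters the grid, raises
  `DegenerateInputError`.
* Rasters are ESRI ASCII grids written at 17 significant digits, so
  write→read round trips are bit-exact and two pipeline runs with one
  config + seed produce byte-identical files (tested).
* The pipeline validates its config (unknown keys, conflicting input
  modes, bad rule names) before any computation.

## Problem sizes

Tests and the acceptance script run the full pipeline at the default
100×100-cell landscape (the analysis scale of interest for a subregional
assessment) and exercise oracle comparisons at 20×20–50×50; these sizes
give stable statistics (9,700 valid cells; Monte-Carlo checks over 20
seeds) while keeping the whole suite near half a minute.
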