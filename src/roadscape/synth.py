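"""Synthetic landscape generator.

Produces complete, internally consistent input bundles with the
statistical structure the benefit-cost analysis assumes, so the whole
pipeline is testable without external GIS data:

* travel time grows with distance from a handful of cities;
* habitat conversion follows a logistic of conversion pressure --
  accessibility (travel time) combined with a regional suitability
  field -- so cover is low near cities and on fertile plains;
* cropland sits only on the converted fraction of each cell, and yield
  gaps widen with isolation (farms far from markets under-perform);
* carbon stocks rise with natural cover; ecoregions are a contiguous
  nearest-seed partition carrying heat/moisture regulation indices;
* population decays away from cities; roads connect city pairs.

Because converted, low-cover cells are exactly the ones with cropland
(hence production gaps) while intact cells hold the biodiversity, carbon
and regulation value, the generated landscapes embed a broadly negative
spatial association between the final benefit and cost surfaces -- the
structure the framework is designed to reveal.

Randomness: one master seed feeds independent named substreams, so
adding a generator stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import minimum_spanning_tree
from shapely.affinity import rotate, scale, translate
from shapely.geometry import Point

from .benefit import CropLayer
from .cost import EcoregionIndices, SpeciesRange, VERTEBRATE_CLASSES
from .errors import ParameterError
from .geodesy import KM_PER_DEG, haversine_km
from .grid import CellAreas, Grid, Surface, cell_areas
from .roads import RoadLine

#: Food-energy content of the 17 mapped crops, GJ per tonne of product
#: (fresh weight). Synthetic stand-in table mirroring the role of a crop
#: energy-content reference; values are editable via LandscapeParams.
DEFAULT_CROP_ENERGY_GJ_PER_T = {
    "rice": 15.2, "maize": 16.3, "wheat": 15.8, "barley": 13.7,
    "sorghum": 14.6, "millet": 15.1, "rye": 14.0, "cassava": 6.7,
    "potato": 3.2, "sweet_potato": 4.0, "sugarcane": 1.8, "sugar_beet": 2.9,
    "soybean": 18.5, "groundnut": 24.0, "rapeseed": 24.8, "sunflower": 24.2,
    "cotton_seed": 16.1,
}


@dataclass
class LandscapeParams:
    """Knobs of the synthetic landscape.

    Defaults describe a ~830 x 830 km tropical study region at the
    analysis scale (0.0833 deg cells), 17 crops, three vertebrate classes
    of 50 species each, and moderate observation noise.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 0.0833
    origin: tuple[float, float] = (98.0, 29.0)
    n_cities: int = 5
    n_crops: int = 17
    n_ecoregions: int = 8
    n_species: int = 50            # per vertebrate class
    n_proposals: int = 8
    conversion_steepness: float = 6.0
    yieldgap_isolation_slope: float = 0.004   # t/ha/y per minute
    noise_sd: float = 0.15
    water_fraction: float = 0.03
    travel_min_per_km: float = 1.2
    cropland_share: float = 0.9    # of converted land that is cropped
    crop_energy: dict = field(default_factory=lambda: dict(DEFAULT_CROP_ENERGY_GJ_PER_T))
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_rows=self.n_rows, n_cols=self.n_cols,
                      n_cities=self.n_cities, n_crops=self.n_crops,
                      n_ecoregions=self.n_ecoregions, n_species=self.n_species,
                      n_proposals=self.n_proposals)
        for name, v in counts.items():
            if v < 1:
                raise ParameterError(f"{name} must be >= 1, got {v}")
        if self.n_rows * self.n_cols < 100:
            raise ParameterError("grid must have >= 100 cells")
        if self.conversion_steepness <= 0:
            raise ParameterError("conversion_steepness must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.water_fraction < 0.5:
            raise ParameterError("water_fraction must be in [0, 0.5)")
        if not 0 < self.cropland_share <= 1:
            raise ParameterError("cropland_share must be in (0, 1]")
        if self.n_crops > len(self.crop_energy):
            raise ParameterError(
                f"n_crops={self.n_crops} exceeds energy table size "
                f"{len(self.crop_energy)}")


@dataclass
class LandscapeBundle:
    """Everything the pipeline consumes, on one shared grid."""

    params: LandscapeParams
    grid: Grid
    areas: CellAreas
    travel_time: Surface            # min
    natural_cover: Surface          # proportion 0-1
    crops: list[CropLayer]
    crops_alt: list[CropLayer]      # alternative yield-gap database variant
    carbon_biomass: Surface         # t/ha
    carbon_soil30: Surface          # t/ha (upper 30 cm)
    ecoregion_id: Surface           # integer codes
    ecoregion_indices: list[EcoregionIndices]
    population: Surface             # persons/km^2
    roads_existing: list[RoadLine]
    road_proposals: list[RoadLine]
    species_ranges: list[SpeciesRange]
    cities: np.ndarray              # (k, 2) lon/lat


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent substream keyed by (seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31), zlib.crc32(name.encode())]))


def _smooth_noise(rng, shape, sigma: float, sd: float) -> np.ndarray:
    """Spatially smoothed Gaussian field rescaled to a target sd."""
    if sd == 0:
        return np.zeros(shape)
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = f.std()
    return f * (sd / s) if s > 0 else f


def generate_landscape(params: LandscapeParams) -> LandscapeBundle:
    """Generate a full synthetic input bundle (deterministic in the seed)."""
    params.validate()
    p = params

    # -- grid & water mask --------------------------------------------------
    rng = _rng(p.seed, "mask")
    shape = (p.n_rows, p.n_cols)
    water_field = gaussian_filter(rng.standard_normal(shape), 3.0, mode="reflect")
    if p.water_fraction > 0:
        thresh = np.quantile(water_field, p.water_fraction)
        mask = water_field > thresh
    else:
        mask = np.ones(shape, dtype=bool)
    grid = Grid(p.n_rows, p.n_cols, p.cell_size, tuple(p.origin), mask)
    areas = cell_areas(grid)
    lon, lat = grid.center_mesh()

    # -- cities & travel time ----------------------------------------------
    rng = _rng(p.seed, "cities")
    vr, vc = np.nonzero(grid.valid_mask)
    pick = rng.choice(len(vr), size=min(p.n_cities, len(vr)), replace=False)
    cities = np.column_stack([lon[vr[pick], vc[pick]], lat[vr[pick], vc[pick]]])

    d_city = np.full(shape + (len(cities),), np.nan)
    for k, (clon, clat) in enumerate(cities):
        d_city[..., k] = haversine_km(clon, clat, lon, lat)
    d_nearest = d_city.min(axis=-1)

    rng = _rng(p.seed, "travel")
    tt = p.travel_min_per_km * d_nearest
    tt = np.maximum(tt * (1 + _smooth_noise(rng, shape, 1.5, p.noise_sd)), 0.0)
    travel_time = Surface(grid, tt, "min")

    # -- natural cover ------------------------------------------------------
    # Conversion pressure combines accessibility (normalised travel time,
    # low cover near cities) with a large-scale suitability field standing
    # in for terrain/soils -- historically, farmland follows fertile plains
    # as much as city proximity, so the two are only loosely coupled.
    rng = _rng(p.seed, "cover")
    tt_def = tt[grid.valid_mask]
    t_scale = max(float(np.median(tt_def)), 1e-9)
    suitability = _smooth_noise(rng, shape, 6.0, 1.0)
    pressure = 0.4 * (tt / t_scale - 1.0) + suitability
    cover = 1.0 / (1.0 + np.exp(-p.conversion_steepness * pressure))
    cover = np.clip(cover + _smooth_noise(rng, shape, 2.0, p.noise_sd), 0, 1)
    natural_cover = Surface(grid, cover, "proportion")

    # -- crops ---------------------------------------------------------------
    crop_names = list(p.crop_energy)[:p.n_crops]
    crops = _generate_crops(p, grid, areas, travel_time, natural_cover,
                            crop_names, _rng(p.seed, "crops"))
    # alternative database: drop the last crop, perturb gaps & areas
    crops_alt = _perturb_crops(crops[:-1] if len(crops) > 1 else crops,
                               grid, _rng(p.seed, "crops_alt"))

    # -- carbon --------------------------------------------------------------
    rng = _rng(p.seed, "carbon")
    biomass = np.clip(10 + 180 * cover ** 1.3
                      + 15 * _smooth_noise(rng, shape, 1.5, 1.0), 0, None)
    soil = np.clip(30 + 40 * cover
                   + 8 * _smooth_noise(rng, shape, 1.5, 1.0), 0, None)
    carbon_biomass = Surface(grid, biomass, "t/ha")
    carbon_soil30 = Surface(grid, soil, "t/ha")

    # -- ecoregions (nearest-seed / Voronoi partition) -----------------------
    rng = _rng(p.seed, "ecoregions")
    seeds = rng.choice(len(vr), size=min(p.n_ecoregions, len(vr)), replace=False)
    sr, sc = vr[seeds], vc[seeds]
    rr, cc = np.meshgrid(np.arange(p.n_rows), np.arange(p.n_cols), indexing="ij")
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    eco = d2.argmin(axis=-1) + 1
    ecoregion_id = Surface(grid, eco.astype(float), "ecoregion id")
    indices = [EcoregionIndices(int(i + 1),
                                hri=float(rng.uniform(0.5, 2.5)),
                                mri=float(rng.uniform(0.3, 2.5)))
               for i in range(len(seeds))]

    # -- population -----------------------------------------------------------
    rng = _rng(p.seed, "population")
    pop = np.full(shape, 5.0)
    for k in range(len(cities)):
        peak = rng.lognormal(np.log(1500), 0.4)
        scale_km = rng.uniform(10, 30)
        pop += peak * np.exp(-d_city[..., k] / scale_km)
    pop *= np.exp(_smooth_noise(rng, shape, 2.0, 0.3))
    population = Surface(grid, pop, "persons/km^2")

    # -- roads ----------------------------------------------------------------
    roads_existing = _generate_roads(p, grid, cities, _rng(p.seed, "roads"))
    road_proposals = _generate_proposals(p, grid, natural_cover,
                                         _rng(p.seed, "proposals"))

    # -- species ranges -------------------------------------------------------
    species_ranges = generate_species_ranges(p, natural_cover,
                                             _rng(p.seed, "ranges"))

    return LandscapeBundle(
        params=p, grid=grid, areas=areas, travel_time=travel_time,
        natural_cover=natural_cover, crops=crops, crops_alt=crops_alt,
        carbon_biomass=carbon_biomass, carbon_soil30=carbon_soil30,
        ecoregion_id=ecoregion_id, ecoregion_indices=indices,
        population=population, roads_existing=roads_existing,
        road_proposals=road_proposals, species_ranges=species_ranges,
        cities=cities)


def _generate_crops(p, grid, areas, travel_time, natural_cover, names, rng):
    """Cropland only on the converted fraction; yield gaps grow with
    isolation at the stated slope."""
    shape = grid.shape
    converted_ha = (1.0 - natural_cover.values) * areas.area_ha()
    crop_ha_total = p.cropland_share * converted_ha
    base_share = rng.dirichlet(np.ones(len(names)) * 2.0)
    noise = rng.standard_normal((len(names),) + shape) * 0.3
    w = base_share[:, None, None] * np.exp(noise)
    w /= w.sum(axis=0, keepdims=True)

    tt = travel_time.values
    crops = []
    for i, name in enumerate(names):
        area_ha = w[i] * crop_ha_total
        base = rng.uniform(0.3, 1.0)
        gap = np.clip(base + p.yieldgap_isolation_slope * tt
                      + rng.standard_normal(shape) * p.noise_sd, 0, None)
        cur = np.clip(rng.uniform(1.5, 4.0)
                      + rng.standard_normal(shape) * p.noise_sd, 0.1, None)
        crops.append(CropLayer(
            name=name,
            yield_gap=Surface(grid, gap, "t/ha/y"),
            harvested_area=Surface(grid, area_ha, "ha/cell"),
            energy_content=float(p.crop_energy[name]),
            current_yield=Surface(grid, cur, "t/ha/y")))
    return crops


def _perturb_crops(crops, grid, rng):
    """An independently 'measured' variant of the crop database.

    Two methodologies disagree systematically, not cell-by-cell: the
    variant applies a smoothed regional bias field shared by all crops
    (attainable-yield models err regionally), a per-crop scale factor,
    and small residual cell noise.
    """
    regional = np.exp(_smooth_noise(rng, grid.shape, 4.0, 1.2))
    out = []
    for crop in crops:
        crop_factor = rng.lognormal(0.0, 0.4)
        cell_noise = rng.lognormal(0.0, 0.15, grid.shape)
        gap = crop.yield_gap.values * regional * crop_factor * cell_noise
        area = crop.harvested_area.values * rng.lognormal(0.0, 0.1, grid.shape)
        out.append(CropLayer(
            name=crop.name + "_alt",
            yield_gap=Surface(grid, np.clip(gap, 0, None), "t/ha/y"),
            harvested_area=Surface(grid, np.clip(area, 0, None), "ha/cell"),
            energy_content=crop.energy_content,
            current_yield=crop.current_yield))
    return out


def _jittered_line(a, b, rng, n_mid=3, jitter_deg=0.15):
    """Polyline from a to b with jittered intermediate vertices."""
    t = np.linspace(0, 1, n_mid + 2)[:, None]
    pts = a + t * (b - a)
    pts[1:-1] += rng.normal(0, jitter_deg, (n_mid, 2))
    return pts


def _generate_roads(p, grid, cities, rng):
    """Existing network: MST of cities (level 1), extra links (2),
    city spurs (3) and short tracks (4)."""
    k = len(cities)
    roads = []
    rid = 0
    if k >= 2:
        d = np.zeros((k, k))
        for i in range(k):
            d[i] = haversine_km(cities[i, 0], cities[i, 1],
                                cities[:, 0], cities[:, 1])
        mst = minimum_spanning_tree(d).toarray()
        for i, j in zip(*np.nonzero(mst)):
            roads.append(RoadLine(f"E{rid:03d}", 1,
                                  _jittered_line(cities[i], cities[j], rng)))
            rid += 1
        # a couple of redundant level-2 links
        extra = min(2, k * (k - 1) // 2 - (k - 1))
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)
                 if mst[i, j] == 0 and mst[j, i] == 0]
        if pairs and extra > 0:
            for idx in rng.choice(len(pairs), size=min(extra, len(pairs)),
                                  replace=False):
                i, j = pairs[idx]
                roads.append(RoadLine(f"E{rid:03d}", 2,
                                      _jittered_line(cities[i], cities[j], rng)))
                rid += 1
    lon0, lat0 = grid.origin
    ext = (lon0, lon0 + grid.n_cols * grid.cell_size,
           lat0 - grid.n_rows * grid.cell_size, lat0)
    for level, count, reach in ((3, 2 * k, 1.5), (4, k, 0.6)):
        for _ in range(count):
            c = cities[rng.integers(len(cities))]
            end = c + rng.normal(0, reach, 2)
            end[0] = np.clip(end[0], ext[0], ext[1])
            end[1] = np.clip(end[1], ext[2], ext[3])
            roads.append(RoadLine(f"E{rid:03d}", level,
                                  _jittered_line(c, end, rng, n_mid=2,
                                                 jitter_deg=0.08)))
            rid += 1
    return roads


def _generate_proposals(p, grid, natural_cover, rng):
    """Proposals span contrasting regions: from a converted (low-cover)
    cell to an intact (high-cover) cell."""
    lon, lat = grid.center_mesh()
    cov = natural_cover.values[grid.valid_mask]
    lon_v, lat_v = lon[grid.valid_mask], lat[grid.valid_mask]
    lo, hi = np.quantile(cov, [0.3, 0.7])
    low_idx = np.nonzero(cov <= lo)[0]
    high_idx = np.nonzero(cov >= hi)[0]
    if len(low_idx) == 0 or len(high_idx) == 0:   # flat cover: anywhere
        low_idx = high_idx = np.arange(len(cov))
    proposals = []
    for i in range(p.n_proposals):
        a_i = int(rng.choice(low_idx))
        b_i = int(rng.choice(high_idx))
        a = np.array([lon_v[a_i], lat_v[a_i]])
        b = np.array([lon_v[b_i], lat_v[b_i]])
        proposals.append(RoadLine(f"P{i + 1:02d}", "proposal",
                                  _jittered_line(a, b, rng, n_mid=3,
                                                 jitter_deg=0.1)))
    return proposals


def generate_species_ranges(params: LandscapeParams, natural_cover: Surface,
                            rng: np.random.Generator) -> list[SpeciesRange]:
    """Per class, ``n_species`` elliptical ranges.

    Range areas are log-uniform over ~2.5 orders of magnitude (1e2 to
    10^4.5 km^2); centres are placed on valid cells with probability
    proportional to natural cover (+ a floor, so zero cover degrades to
    uniform placement). The generating ellipse's analytic area (pi*a*b)
    is recorded as the species' global range area.
    """
    grid = natural_cover.grid
    lon, lat = grid.center_mesh()
    lon_v = lon[grid.valid_mask]
    lat_v = lat[grid.valid_mask]
    weights = np.nan_to_num(natural_cover.values[grid.valid_mask], nan=0.0) + 0.05
    weights = weights / weights.sum()

    ranges = []
    for v_class in VERTEBRATE_CLASSES:
        for s in range(params.n_species):
            area_km2 = 10 ** rng.uniform(2.0, 4.5)
            q = rng.uniform(0.4, 1.0)             # axis ratio b/a
            a_km = np.sqrt(area_km2 / (np.pi * q))
            b_km = q * a_km
            i = rng.choice(len(lon_v), p=weights)
            clon, clat = float(lon_v[i]), float(lat_v[i])
            a_deg = a_km / (KM_PER_DEG * max(np.cos(np.radians(clat)), 1e-6))
            b_deg = b_km / KM_PER_DEG
            ellipse = scale(Point(0, 0).buffer(1.0, quad_segs=16),
                            a_deg, b_deg)
            ellipse = rotate(ellipse, rng.uniform(0, 180), origin=(0, 0))
            ellipse = translate(ellipse, clon, clat)
            ranges.append(SpeciesRange(
                species_id=f"{v_class[0]}{s + 1:03d}", v_class=v_class,
                geometry=ellipse,
                global_range_area=float(np.pi * a_km * b_km)))
    return ranges
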