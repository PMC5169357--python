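"""File formats: ASCII-grid rasters, GeoJSON vectors, CSV tables and the
bundle manifest.

Rasters use the ESRI ASCII grid format (``.asc``) -- a plain-text,
widely supported single-band raster with cell-size/corner georeferencing
and a NODATA tag. Values are written with 17 significant digits so a
write/read round trip is exact. Vector layers (roads, species ranges)
are GeoJSON; tables are CSV; the bundle manifest is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .benefit import CropLayer
from .cost import EcoregionIndices, SpeciesRange
from .errors import FormatError
from .grid import Grid, Surface, cell_areas
from .roads import PROPOSAL, RoadLine
from .synth import LandscapeBundle, LandscapeParams

NODATA = -9999.0
_FMT = "%.17g"


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_surface(surface: Surface, path) -> None:
    """Write a surface as an ESRI ASCII grid (NoData cells -> NODATA)."""
    g = surface.grid
    lon0, lat0 = g.origin
    yll = lat0 - g.n_rows * g.cell_size
    vals = np.where(np.isfinite(surface.values), surface.values, NODATA)
    header = (f"ncols {g.n_cols}\nnrows {g.n_rows}\n"
              f"xllcorner {lon0:.17g}\nyllcorner {yll:.17g}\n"
              f"cellsize {g.cell_size:.17g}\nNODATA_value {NODATA:g}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=_FMT)


def read_surface(path, units: str = "", grid: Grid | None = None) -> Surface:
    """Read an ESRI ASCII grid back into a Surface.

    If ``grid`` is given its lattice must match and its validity mask is
    applied; otherwise the mask is taken from the file's NODATA cells.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        n_rows, n_cols = int(hdr["nrows"]), int(hdr["ncols"])
        vals = vals.reshape(n_rows, n_cols)
        cs = hdr["cellsize"]
        origin = (hdr["xllcorner"], hdr["yllcorner"] + n_rows * cs)
        nodata = hdr.get("nodata_value", NODATA)
    except Exception as exc:  # noqa: BLE001 - surface any parse failure
        raise FormatError(f"cannot parse ASCII grid {path}: {exc}") from exc
    vals = np.where(vals == nodata, np.nan, vals)
    if grid is None:
        grid = Grid(n_rows, n_cols, cs, origin, np.isfinite(vals))
    return Surface(grid, vals, units)


# ---------------------------------------------------------------------------
# vectors
# ---------------------------------------------------------------------------

def write_roads(roads: list[RoadLine], path) -> None:
    features = [{"type": "Feature",
                 "properties": {"road_id": r.road_id, "level": r.level},
                 "geometry": mapping(r.geometry)} for r in roads]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_roads(path) -> list[RoadLine]:
    with open(path) as fh:
        fc = json.load(fh)
    roads = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if geom.geom_type != "LineString":
            raise FormatError(f"{path}: roads must be LineStrings, "
                              f"got {geom.geom_type}")
        level = props.get("level", PROPOSAL)
        roads.append(RoadLine(str(props.get("road_id", "road")),
                              level if level == PROPOSAL else int(level),
                              np.asarray(geom.coords)))
    return roads


def write_species_ranges(ranges: list[SpeciesRange], path) -> None:
    features = [{"type": "Feature",
                 "properties": {"species_id": r.species_id,
                                "v_class": r.v_class,
                                "global_range_area": r.global_range_area},
                 "geometry": mapping(r.geometry)} for r in ranges]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_species_ranges(path) -> list[SpeciesRange]:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc.get("features", []):
        props = feat["properties"]
        out.append(SpeciesRange(props["species_id"], props["v_class"],
                                shape(feat["geometry"]),
                                float(props["global_range_area"])))
    return out


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

_BUNDLE_RASTERS = {           # attribute -> (filename, units)
    "travel_time": ("travel_time.asc", "min"),
    "natural_cover": ("natural_cover.asc", "proportion"),
    "carbon_biomass": ("carbon_biomass.asc", "t/ha"),
    "carbon_soil30": ("carbon_soil30.asc", "t/ha"),
    "ecoregion_id": ("ecoregion_id.asc", "ecoregion id"),
    "population": ("population.asc", "persons/km^2"),
}


def _write_crops(crops: list[CropLayer], directory: Path, prefix: str):
    rows, files = [], []
    for crop in crops:
        gap_f = f"{prefix}_gap_{crop.name}.asc"
        area_f = f"{prefix}_area_{crop.name}.asc"
        write_surface(crop.yield_gap, directory / gap_f)
        write_surface(crop.harvested_area, directory / area_f)
        row = {"name": crop.name, "energy_GJ_per_t": crop.energy_content,
               "yield_gap_path": gap_f, "area_path": area_f}
        if crop.current_yield is not None:
            cur_f = f"{prefix}_current_{crop.name}.asc"
            write_surface(crop.current_yield, directory / cur_f)
            row["current_yield_path"] = cur_f
            files.append(cur_f)
        rows.append(row)
        files += [gap_f, area_f]
    manifest = f"{prefix}_crops.csv"
    pd.DataFrame(rows).to_csv(directory / manifest, index=False)
    return manifest, files


def read_crops(manifest_path, grid: Grid | None = None) -> list[CropLayer]:
    """Load a crop set from its manifest CSV (paths relative to it)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    crops = []
    for _, row in df.iterrows():
        cur = None
        if "current_yield_path" in row and isinstance(row.get("current_yield_path"), str):
            cur = read_surface(base / row["current_yield_path"], "t/ha/y", grid)
        crops.append(CropLayer(
            name=str(row["name"]),
            yield_gap=read_surface(base / row["yield_gap_path"], "t/ha/y", grid),
            harvested_area=read_surface(base / row["area_path"], "ha/cell", grid),
            energy_content=float(row["energy_GJ_per_t"]),
            current_yield=cur))
    return crops


def write_bundle(bundle: LandscapeBundle, directory) -> dict:
    """Write a bundle to a directory; returns (and writes) the manifest.

    Everything needed to reload -- or regenerate -- the bundle is
    recorded: file names with units, and the generating parameters
    including the seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    mask = Surface(bundle.grid, bundle.grid.valid_mask.astype(float), "0/1")
    write_surface(mask, directory / "valid_mask.asc")
    files["valid_mask"] = {"path": "valid_mask.asc", "units": "boolean 0/1"}
    for attr, (fname, units) in _BUNDLE_RASTERS.items():
        write_surface(getattr(bundle, attr), directory / fname)
        files[attr] = {"path": fname, "units": units}

    crops_csv, _ = _write_crops(bundle.crops, directory, "crop")
    alt_csv, _ = _write_crops(bundle.crops_alt, directory, "cropalt")
    files["crops"] = {"path": crops_csv, "units": "see columns"}
    files["crops_alt"] = {"path": alt_csv, "units": "see columns"}

    pd.DataFrame([{"ecoregion_id": e.ecoregion_id, "hri_degC": e.hri,
                   "mri_mm_per_day": e.mri}
                  for e in bundle.ecoregion_indices]).to_csv(
        directory / "ecoregion_indices.csv", index=False)
    files["ecoregion_indices"] = {"path": "ecoregion_indices.csv",
                                  "units": "HRI degC, MRI mm/d"}

    write_roads(bundle.roads_existing, directory / "roads_existing.geojson")
    write_roads(bundle.road_proposals, directory / "road_proposals.geojson")
    write_species_ranges(bundle.species_ranges,
                         directory / "species_ranges.geojson")
    files["roads_existing"] = {"path": "roads_existing.geojson", "units": "level 1-4"}
    files["road_proposals"] = {"path": "road_proposals.geojson", "units": "proposal"}
    files["species_ranges"] = {"path": "species_ranges.geojson",
                               "units": "range area km^2"}
    np.savetxt(directory / "cities.csv", bundle.cities, delimiter=",",
               header="lon,lat", comments="", fmt=_FMT)
    files["cities"] = {"path": "cities.csv", "units": "lon,lat deg"}

    from dataclasses import asdict
    params = asdict(bundle.params)
    params["origin"] = list(params["origin"])
    manifest = {"format": "roadscape-bundle-v1", "params": params,
                "seed": bundle.params.seed, "files": files}
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_bundle(directory) -> LandscapeBundle:
    """Reload a bundle written by :func:`write_bundle` (exact values)."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format") != "roadscape-bundle-v1":
        raise FormatError(f"{directory}: not a roadscape bundle manifest")
    pdict = dict(manifest["params"])
    pdict["origin"] = tuple(pdict["origin"])
    params = LandscapeParams(**pdict)

    mask_surf = read_surface(directory / "valid_mask.asc")
    mask = np.nan_to_num(mask_surf.values, nan=0.0) > 0.5
    grid = Grid(mask_surf.grid.n_rows, mask_surf.grid.n_cols,
                mask_surf.grid.cell_size, mask_surf.grid.origin, mask)

    surfaces = {attr: read_surface(directory / spec["path"], spec["units"], grid)
                for attr, spec in _BUNDLE_RASTERS.items()
                for spec in [manifest["files"][attr]]}

    idx_df = pd.read_csv(directory / manifest["files"]["ecoregion_indices"]["path"])
    indices = [EcoregionIndices(int(r.ecoregion_id), float(r.hri_degC),
                                float(r.mri_mm_per_day))
               for r in idx_df.itertuples()]
    cities = np.loadtxt(directory / "cities.csv", delimiter=",", skiprows=1,
                        ndmin=2)
    return LandscapeBundle(
        params=params, grid=grid, areas=cell_areas(grid),
        crops=read_crops(directory / manifest["files"]["crops"]["path"], grid),
        crops_alt=read_crops(directory / manifest["files"]["crops_alt"]["path"], grid),
        ecoregion_indices=indices,
        roads_existing=read_roads(directory / "roads_existing.geojson"),
        road_proposals=read_roads(directory / "road_proposals.geojson"),
        species_ranges=read_species_ranges(directory / "species_ranges.geojson"),
        cities=cities, **surfaces)
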