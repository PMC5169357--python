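"""One-command pipeline: inputs -> benefit & cost -> intersection ->
sensitivity -> road assessment, with every artifact written to disk.

Configuration is a plain dict (typically loaded from YAML) validated
up front so a bad config fails before any computation. Exactly one input
mode is used: ``generate`` (synthetic landscape parameters) or
``bundle_dir`` (a directory written by :func:`roadscape.io.write_bundle`).
Identical config + seed produces byte-identical rasters.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benefit import benefit_surface, population_benefit, production_gap
from .cost import (aggregate_cost, carbon_cost, climate_cost,
                   vertebrate_importance)
from .errors import ParameterError
from .grid import Surface
from .intersect import bivariate_classify, changed_fraction, difference_map
from .io import read_bundle, write_bundle, write_surface
from .roads import road_density, road_profile, summarize_proposals
from .synth import LandscapeParams, generate_landscape

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "generate": None,          # dict of LandscapeParams overrides
    "bundle_dir": None,        # or: path to an existing bundle
    "seed": 0,
    "benefit_mode": "production",   # production | population
    "cost_rule": "mean",            # mean | max
    "n_bins": 10,
    "buffer_width_km": 10.0,
    "sensitivity": True,
    "write_bundle": False,
    "changed_threshold": 0.2,
}


def validate_config(config: dict) -> dict:
    """Fill defaults and fail fast on inconsistent settings."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    if (cfg["generate"] is None) == (cfg["bundle_dir"] is None):
        raise ParameterError(
            "config needs exactly one of 'generate' or 'bundle_dir'")
    if cfg["benefit_mode"] not in ("production", "population"):
        raise ParameterError("benefit_mode must be production|population")
    if cfg["cost_rule"] not in ("mean", "max"):
        raise ParameterError("cost_rule must be mean|max")
    if cfg["bundle_dir"] is not None and not Path(cfg["bundle_dir"]).exists():
        raise ParameterError(f"bundle_dir {cfg['bundle_dir']} does not exist")
    return cfg


def _surface_stats(surface: Surface) -> dict:
    vals = surface.defined_values()
    return {"n_defined": int(vals.size),
            "min": float(vals.min()), "max": float(vals.max()),
            "mean": float(vals.mean()), "units": surface.units}


def build_cost(bundle, rule: str = "mean") -> tuple[Surface, dict[str, Surface]]:
    """The three component layers and their aggregate."""
    vert = vertebrate_importance(bundle.species_ranges, bundle.natural_cover,
                                 bundle.areas)
    carbon = carbon_cost(bundle.carbon_biomass, bundle.carbon_soil30,
                         bundle.natural_cover, bundle.areas)
    climate = climate_cost(bundle.ecoregion_id, bundle.ecoregion_indices,
                           bundle.natural_cover)
    layers = {"vertebrates": vert, "carbon": carbon, "climate": climate}
    return aggregate_cost(list(layers.values()), rule=rule), layers


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full assessment; returns the artifact manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stats: dict[str, dict] = {}

    def emit(name: str, surface: Surface) -> None:
        fname = f"{name}.asc"
        write_surface(surface, out / fname)
        artifacts[name] = fname
        stats[name] = _surface_stats(surface)
        logger.info("stage %s: %s", name, stats[name])

    # -- stage: inputs ------------------------------------------------------
    if cfg["generate"] is not None:
        params = LandscapeParams(**{**cfg["generate"], "seed": cfg["seed"]})
        bundle = generate_landscape(params)
        if cfg["write_bundle"]:
            write_bundle(bundle, out / "bundle")
            artifacts["bundle"] = "bundle/manifest.yaml"
    else:
        bundle = read_bundle(cfg["bundle_dir"])
    grid = bundle.grid

    # -- stage: benefit -----------------------------------------------------
    prod_gap = production_gap(bundle.crops, grid)
    emit("production_gap", prod_gap)
    if cfg["benefit_mode"] == "production":
        benefit = benefit_surface(prod_gap, bundle.travel_time)
    else:
        benefit = population_benefit(bundle.population, bundle.travel_time)
    emit("benefit", benefit)

    # -- stage: cost --------------------------------------------------------
    cost, layers = build_cost(bundle, rule=cfg["cost_rule"])
    for name, layer in layers.items():
        emit(f"cost_{name}", layer)
    emit("cost", cost)

    # -- stage: intersection ------------------------------------------------
    classified = bivariate_classify(benefit, cost, cfg["n_bins"])
    emit("benefit_bin", Surface(grid, np.where(classified.benefit_bin >= 0,
                                               classified.benefit_bin, np.nan),
                                "bin 0..n-1"))
    emit("cost_bin", Surface(grid, np.where(classified.cost_bin >= 0,
                                            classified.cost_bin, np.nan),
                             "bin 0..n-1"))
    counts = pd.DataFrame(
        [{"quadrant": q, "n_cells": n}
         for q, n in classified.quadrant_counts().items()])
    counts.to_csv(out / "quadrant_counts.csv", index=False)
    artifacts["quadrant_counts"] = "quadrant_counts.csv"

    # -- stage: sensitivity -------------------------------------------------
    changed: dict[str, float] = {}
    if cfg["sensitivity"]:
        alt_gap = production_gap(bundle.crops_alt, grid)
        alt_benefit = benefit_surface(alt_gap, bundle.travel_time)
        cost_max, _ = build_cost(bundle, rule="max")
        pop_benefit = population_benefit(bundle.population, bundle.travel_time)
        tests = {
            "alt_yieldgap_benefit": (alt_benefit, benefit),
            "max_rule_cost": (cost_max, cost),
            "population_benefit": (pop_benefit, benefit),
        }
        for label, (new, orig) in tests.items():
            diff = difference_map(new, orig, label)
            emit(f"diff_{label}", Surface(grid, diff.delta, "delta -1..1"))
            changed[label] = changed_fraction(diff, cfg["changed_threshold"])
        pd.DataFrame([{"test": k, "changed_fraction": v}
                      for k, v in changed.items()]).to_csv(
            out / "changed_fractions.csv", index=False)
        artifacts["changed_fractions"] = "changed_fractions.csv"

    # -- stage: roads -------------------------------------------------------
    density = road_density(bundle.roads_existing, grid, bundle.areas)
    emit("road_density", density)
    surfaces = {"benefit": benefit, "cost": cost,
                "travel_time": bundle.travel_time,
                "population": bundle.population, "road_density": density}
    summary = summarize_proposals(bundle.road_proposals, surfaces, grid,
                                  cfg["buffer_width_km"])
    summary.to_csv(out / "road_summaries.csv", index=False)
    artifacts["road_summaries"] = "road_summaries.csv"
    profiles = pd.concat([road_profile(r, benefit, cost, grid)
                          for r in bundle.road_proposals[:2]],
                         ignore_index=True)
    profiles.to_csv(out / "road_profiles.csv", index=False)
    artifacts["road_profiles"] = "road_profiles.csv"

    # -- run log ------------------------------------------------------------
    manifest = {"roadscape_version": __version__, "config": _plain(cfg),
                "seed": cfg["seed"], "artifacts": artifacts,
                "surface_stats": stats, "changed_fractions": changed}
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def _plain(obj):
    """YAML-safe copy of a config (tuples -> lists etc.)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
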