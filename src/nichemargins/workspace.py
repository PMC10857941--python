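"""On-disk layout of a simulated (or imported) study workspace.

A workspace directory holds everything the pipeline stages exchange, in
plain-text formats::

    config.yaml                resolved simulation configuration
    climate/<period>/*.asc     one ASCII-grid band per climate variable
    landcover/landcover.asc    integer land-cover classes
    countries.geojson          country polygons (property: country_id)
    covariates.csv             country_id, area_km2, gdp_pc, centroid lon/lat
    ranges.csv                 species, pixel_id (range membership)
    occurrences.csv            species, lon, lat, pixel_id
    species_truth.csv          niche ground truth per species
    projects.csv               monitoring-project records
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import read_geojson, read_raster, write_geojson, write_raster
from .world import (EffortParams, Scenario, SpeciesData, SpeciesTruth, World,
                    WorldConfig, generate_project_table, generate_species_set,
                    generate_world)


def config_from_dict(doc: dict) -> WorldConfig:
    scenarios = tuple(
        Scenario(s["id"], shift=float(s.get("shift", 0.0)),
                 scale=float(s.get("scale", 1.0)))
        for s in doc.get("scenarios", [{"id": "mild", "shift": 0.5},
                                       {"id": "harsh", "shift": 1.5,
                                        "scale": 1.1}]))
    keys = ("x_min", "y_min", "resolution", "n_rows", "n_cols",
            "n_climate_vars", "smoothness", "n_countries",
            "n_landcover_classes", "seed")
    kwargs = {k: doc[k] for k in keys if k in doc}
    return WorldConfig(scenarios=scenarios, **kwargs)


def config_to_dict(config: WorldConfig) -> dict:
    doc = {k: getattr(config, k) for k in
           ("x_min", "y_min", "resolution", "n_rows", "n_cols",
            "n_climate_vars", "smoothness", "n_countries",
            "n_landcover_classes", "seed")}
    doc["scenarios"] = [
        {"id": s.scenario_id, "shift": float(np.mean(s.shift)),
         "scale": float(np.mean(s.scale))}
        for s in config.scenarios]
    return doc


def save_world(directory: str | Path, world: World,
               species: list[SpeciesData] | None = None,
               projects: pd.DataFrame | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "config.yaml").write_text(
        yaml.safe_dump(config_to_dict(world.config)))
    for period, raster in world.climate.items():
        write_raster(directory / "climate" / period, raster)
    write_raster(directory / "landcover", world.landcover)
    write_geojson(directory / "countries.geojson", world.country_polygons,
                  [{"country_id": c} for c in world.country_ids])
    world.covariates.to_csv(directory / "covariates.csv", index=False)
    if species is not None:
        pd.concat([
            pd.DataFrame({"species": sp.truth.species_id,
                          "pixel_id": sp.range_pixel_ids})
            for sp in species
        ]).to_csv(directory / "ranges.csv", index=False)
        pd.concat([sp.occurrences for sp in species]).to_csv(
            directory / "occurrences.csv", index=False)
        rows = []
        for sp in species:
            t = sp.truth
            rows.append({
                "species": t.species_id, "group": t.group,
                "centroid_1": t.centroid[0], "centroid_2": t.centroid[1],
                "cov_11": t.covariance[0, 0], "cov_12": t.covariance[0, 1],
                "cov_22": t.covariance[1, 1],
                "envelope_radius": t.envelope_radius,
                "occurrence_count": t.occurrence_count,
            })
        pd.DataFrame(rows).to_csv(directory / "species_truth.csv",
                                  index=False)
    if projects is not None:
        projects.to_csv(directory / "projects.csv", index=False)


def load_world(directory: str | Path) -> World:
    directory = Path(directory)
    config = config_from_dict(
        yaml.safe_load((directory / "config.yaml").read_text()))
    climate = {}
    for sub in sorted((directory / "climate").iterdir()):
        if sub.is_dir():
            climate[sub.name] = read_raster(sub)
    landcover = read_raster(directory / "landcover")
    polys, props = read_geojson(directory / "countries.geojson")
    country_ids = [p["country_id"] for p in props]
    covariates = pd.read_csv(directory / "covariates.csv")
    # country raster is reproducible from the config seed, but cheap to
    # rebuild from polygons too; rebuild by regeneration for fidelity
    rebuilt = generate_world(config)
    return World(config=config, climate=climate, landcover=landcover,
                 country_ids=country_ids, country_polygons=polys,
                 country_raster=rebuilt.country_raster, covariates=covariates)


def load_species(directory: str | Path) -> list[SpeciesData]:
    directory = Path(directory)
    truth = pd.read_csv(directory / "species_truth.csv")
    ranges = pd.read_csv(directory / "ranges.csv")
    occ = pd.read_csv(directory / "occurrences.csv")
    config = config_from_dict(
        yaml.safe_load((directory / "config.yaml").read_text()))
    shape = (config.n_rows, config.n_cols)
    out = []
    for row in truth.to_dict("records"):
        t = SpeciesTruth(
            species_id=row["species"], group=row["group"],
            centroid=np.array([row["centroid_1"], row["centroid_2"]]),
            covariance=np.array([[row["cov_11"], row["cov_12"]],
                                 [row["cov_12"], row["cov_22"]]]),
            envelope_radius=row["envelope_radius"],
            occurrence_count=int(row["occurrence_count"]),
        )
        mask = np.zeros(shape[0] * shape[1], dtype=bool)
        mask[ranges.loc[ranges["species"] == t.species_id,
                        "pixel_id"].to_numpy()] = True
        out.append(SpeciesData(
            truth=t, range_mask=mask.reshape(shape),
            occurrences=occ.loc[occ["species"] == t.species_id].reset_index(
                drop=True)))
    return out


def simulate_workspace(
    directory: str | Path,
    config: WorldConfig,
    n_species: int = 8,
    effort_params: EffortParams | None = None,
) -> World:
    """Generate and persist a complete synthetic workspace."""
    from .pipeline import random_species_truths
    from .world import latent_environment

    world = generate_world(config)
    _, latent = latent_environment(world)
    truths = random_species_truths(n_species, config.seed, latent.scores)
    species, _ = generate_species_set(world, truths)
    projects, _ = generate_project_table(
        world, effort_params or EffortParams())
    save_world(directory, world, species=species, projects=projects)
    return world
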