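"""End-to-end orchestration of the marginality analysis.

Glue between the synthetic world (or externally supplied rasters) and
the per-species niche/NMI/transition stages, plus random species-truth
helpers used by the simulator CLI and tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .climate import Calibration, ScoreSet, project_scores
from .grids import Raster
from .nmi import NicheModel, NMIMap, RangePixels, compute_nmi, estimate_niche, \
    filter_range_by_landcover
from .transitions import ThresholdRule, TransitionMap, classify_transitions
from .world import GROUPS, SpeciesData, SpeciesTruth, World, _substream, \
    latent_environment

logger = logging.getLogger(__name__)


def random_species_truths(
    n_species: int,
    seed: int,
    latent_scores: np.ndarray,
    groups: Sequence[str] = GROUPS,
    radius_range: tuple[float, float] = (1.5, 3.0),
    occurrence_count: int = 80,
) -> list[SpeciesTruth]:
    """Draw plausible niche truths inside the occupied latent cloud."""
    rng = _substream(seed, "species-truths")
    pts = latent_scores[np.all(np.isfinite(latent_scores), axis=1)]
    lo, hi = np.quantile(pts, [0.2, 0.8], axis=0)
    sds = pts.std(axis=0)
    truths = []
    for i in range(n_species):
        centroid = rng.uniform(lo, hi)
        # random SPD covariance scaled to a fraction of the cloud spread
        angle = rng.uniform(0, np.pi)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        var = (rng.uniform(0.15, 0.45, size=2) * sds) ** 2
        cov = rot @ np.diag(var) @ rot.T
        truths.append(SpeciesTruth(
            species_id=f"sp{i:03d}",
            group=groups[i % len(groups)],
            centroid=centroid,
            covariance=cov,
            envelope_radius=float(rng.uniform(*radius_range)),
            occurrence_count=occurrence_count,
        ))
    return truths


@dataclass
class SpeciesAnalysis:
    """Everything the pipeline derives for one species."""

    species_id: str
    group: str
    range_pixels: RangePixels
    niche: NicheModel
    nmi: dict[str, NMIMap]  # period/scenario id -> map
    transitions: dict[str, TransitionMap]  # scenario id -> map


def analyze_species(
    world: World,
    species: SpeciesData,
    cal: Calibration,
    rule: ThresholdRule = ThresholdRule(),
    grid_size: int = 150,
    apply_landcover_filter: bool = True,
    scenarios: Sequence[str] | None = None,
) -> SpeciesAnalysis:
    """Niche model, per-period NMI and per-scenario transitions.

    The niche is calibrated on the species' current-period scores and
    frozen; future scores are projected through the same calibration and
    evaluated against the same margin.
    """
    rp = RangePixels(species_id=species.truth.species_id,
                     pixel_ids=species.range_pixel_ids,
                     source="synthetic-envelope")
    if apply_landcover_filter:
        rp = filter_range_by_landcover(rp, world.landcover,
                                       species.occurrences)

    current = world.climate["current"]
    table_now = current.flat_table()[rp.pixel_ids]
    scores_now = project_scores(cal, table_now, pixel_ids=rp.pixel_ids)

    # the niche grid spans the world's latent cloud so margins never
    # start at the species' own bounding box
    _, latent = latent_environment(world)
    finite = latent.scores[np.all(np.isfinite(latent.scores), axis=1)]
    extent = ((finite[:, 0].min(), finite[:, 0].max()),
              (finite[:, 1].min(), finite[:, 1].max()))
    niche = estimate_niche(scores_now, species_id=rp.species_id,
                           grid_size=grid_size, extent=extent)

    nmi_maps = {"current": compute_nmi(niche, scores_now, period="current")}
    trans = {}
    scenario_ids = (scenarios if scenarios is not None
                    else [s.scenario_id for s in world.config.scenarios])
    for sid in scenario_ids:
        table_fut = world.climate[sid].flat_table()[rp.pixel_ids]
        scores_fut = project_scores(cal, table_fut, pixel_ids=rp.pixel_ids)
        nmi_fut = compute_nmi(niche, scores_fut, period=sid)
        nmi_maps[sid] = nmi_fut
        trans[sid] = classify_transitions(nmi_maps["current"], nmi_fut, rule)
    return SpeciesAnalysis(
        species_id=rp.species_id, group=species.truth.group,
        range_pixels=rp, niche=niche, nmi=nmi_maps, transitions=trans)


def nmi_map_to_raster(world: World, nmi_map: NMIMap) -> Raster:
    return nmi_map.to_raster(world.grid)


def scores_for_pixels(cal: Calibration, climate: Raster,
                      pixel_ids: np.ndarray) -> ScoreSet:
    table = climate.flat_table()[pixel_ids]
    return project_scores(cal, table, pixel_ids=pixel_ids)
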