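"""Multispecies stacking and country-level tallies of marginality.

Per-species transition maps are stacked into joint-marginality rasters
(the per-pixel count of species in a given category) and converted to
per-country species tallies: a species counts toward a country and
category when at least one pixel of that category has its center inside
the clipped country polygon (a configurable minimum-pixel rule).

Four tallies per country, group and scenario mirror the standard report:
species with current trailing-edge marginality, with future trailing
marginality, newly experiencing marginal habitat, and experiencing loss
of suitable conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.validation import make_valid

from .grids import GridSpec, Raster
from .transitions import FUTURE_MARGINAL, LOSS, Category, TransitionMap

logger = logging.getLogger(__name__)

#: the real study's clip window (lon_min, lon_max, lat_min, lat_max)
EUROPE_BBOX = (-25.0, 57.0, 29.1, 73.0)


@dataclass
class StudyRegion:
    """Clipped country polygons defining the reporting extent."""

    country_ids: list[str]
    polygons: list
    bbox: tuple[float, float, float, float]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names:
            self.names = list(self.country_ids)


def clip_region(
    country_ids: Sequence[str],
    polygons: Sequence,
    bbox: tuple[float, float, float, float] = EUROPE_BBOX,
    exclusions: Sequence[str] = (),
) -> StudyRegion:
    """Intersect country polygons with the bounding box, drop exclusions.

    Invalid geometries are repaired once (``make_valid``); a repair
    failure raises with the offending country id.  Countries whose
    clipped geometry is empty are dropped with a log line.
    """
    lon_min, lon_max, lat_min, lat_max = bbox
    if not (lon_min < lon_max and lat_min < lat_max):
        raise ValueError("bounding box must be well ordered")
    window = box(lon_min, lat_min, lon_max, lat_max)
    keep_ids, keep_polys = [], []
    for cid, poly in zip(country_ids, polygons):
        if cid in exclusions:
            logger.info("clip_region: excluding %s", cid)
            continue
        if not poly.is_valid:
            poly = make_valid(poly)
            if not poly.is_valid:
                raise ValueError(f"unrepairable geometry for country {cid}")
        clipped = poly.intersection(window)
        if clipped.is_empty:
            logger.info("clip_region: %s falls outside the bbox, dropped",
                        cid)
            continue
        keep_ids.append(cid)
        keep_polys.append(clipped)
    return StudyRegion(country_ids=keep_ids, polygons=keep_polys, bbox=bbox)


def joint_count_map(
    maps: Sequence[TransitionMap],
    category: Category | Sequence[Category],
    grid: GridSpec,
) -> Raster:
    """Per-pixel count of species currently in the requested category."""
    cats = ([category] if isinstance(category, Category) else list(category))
    counts = np.zeros(grid.n_pixels, dtype=float)
    for tm in maps:
        if tm.pixel_ids.size and tm.pixel_ids.max() >= grid.n_pixels:
            raise ValueError(
                f"species {tm.species_id}: pixel ids exceed the lattice")
        counts[tm.pixels_in(*cats)] += 1
    label = "_".join(c.name.lower() for c in cats)
    return Raster(grid, counts.reshape(grid.shape),
                  band_names=[f"n_species_{label}"])


def _pixels_per_country(grid: GridSpec, region: StudyRegion) -> np.ndarray:
    """Country index per pixel center (-1 = no country); border ties go to
    the first country in id order."""
    lon, lat = grid.center_coords()
    pts = shapely.points(lon.ravel(), lat.ravel())
    tree = shapely.STRtree(pts)
    assign = np.full(grid.n_pixels, -1, dtype=int)
    order = np.argsort(region.country_ids)
    for k in order[::-1]:  # reversed so first-in-order wins ties
        idx = tree.query(region.polygons[k], predicate="intersects")
        assign[idx] = k
    return assign


# tally metric -> categories whose presence makes a species count
TALLY_METRICS: Mapping[str, tuple[Category, ...]] = {
    "current_trailing_species": (Category.MARGINAL_TRAILING,),
    "future_trailing_species": (Category.MARGINAL_TRAILING,
                                Category.NEWLY_MARGINAL),
    "newly_marginal_species": (Category.NEWLY_MARGINAL,),
    "loss_species": LOSS,
}


def country_species_tallies(
    maps: Sequence[TransitionMap],
    region: StudyRegion,
    grid: GridSpec,
    groups: Mapping[str, str],
    min_pixels: int = 1,
) -> pd.DataFrame:
    """Tidy per-country, per-group species tallies (long format).

    ``groups`` maps species id -> group label.  A species counts toward
    a country/metric when at least ``min_pixels`` of its pixels in the
    metric's categories fall inside the country's clipped polygon.
    Pixels belonging to no country are counted in the log only.
    """
    assign = _pixels_per_country(grid, region)
    n_orphan = 0
    rows: dict[tuple, int] = {}
    scenario_ids = sorted({tm.scenario_id for tm in maps})
    group_labels = sorted(set(groups.values()))
    for cid in region.country_ids:
        for g in group_labels:
            for sc in scenario_ids:
                for metric in TALLY_METRICS:
                    rows[(cid, g, sc, metric)] = 0
    for tm in maps:
        group = groups.get(tm.species_id, "ungrouped")
        for metric, cats in TALLY_METRICS.items():
            pix = tm.pixels_in(*cats)
            if pix.size == 0:
                continue
            owner = assign[pix]
            n_orphan += int((owner < 0).sum())
            hit, n_hit = np.unique(owner[owner >= 0], return_counts=True)
            for k, n in zip(hit, n_hit):
                if n >= min_pixels:
                    key = (region.country_ids[k], group, tm.scenario_id,
                           metric)
                    rows[key] = rows.get(key, 0) + 1
    if n_orphan:
        logger.info("country_species_tallies: %d category pixels in no "
                    "country", n_orphan)
    out = pd.DataFrame(
        [(c, g, s, m, v) for (c, g, s, m), v in rows.items()],
        columns=["country_id", "group", "scenario_id", "metric", "value"],
    )
    return out.sort_values(
        ["country_id", "group", "scenario_id", "metric"]).reset_index(drop=True)
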