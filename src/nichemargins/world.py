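"""Synthetic study systems: climate fields, countries, species and projects.

The generator builds a self-contained miniature of the inputs the
marginality/monitoring analysis consumes:

* climate rasters for a current period plus future scenarios, as smooth
  Gaussian random fields with linear latitudinal/longitudinal gradients —
  the structure a principal component analysis of real bioclimatic
  variables must recover;
* a categorical land-cover raster from smoothed random fields;
* a country tiling (Voronoi cells of random seed points) with area and
  per-capita-GDP covariates;
* species whose realized ranges are climate envelopes with known niche
  centroids and margins in the latent 2-D environment space; and
* monitoring-project tables drawn from a negative-binomial count model
  with optional spatially structured noise.

Every stage derives its randomness from a single master seed through
named substreams, so identical configurations reproduce byte-identical
outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, box
from shapely.ops import voronoi_diagram

from .climate import Calibration, ScoreSet, fit_calibration, project_raster
from .grids import GridSpec, Raster

logger = logging.getLogger(__name__)

KM_PER_DEGREE = 111.32  # meridian arc length at the equator

GROUPS = ("amphibian", "bird", "carnivoran", "tree")


class ConfigurationError(ValueError):
    pass


class EmptyRangeError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """Future climate as an affine pixelwise update of the current period."""

    scenario_id: str
    shift: np.ndarray | float = 0.0  # additive delta per variable
    scale: np.ndarray | float = 1.0  # multiplicative factor per variable


@dataclass
class WorldConfig:
    x_min: float = 0.0
    y_min: float = 40.0
    resolution: float = 0.1  # degrees / pixel
    n_rows: int = 100
    n_cols: int = 100
    n_climate_vars: int = 19
    smoothness: float = 1.0  # Gaussian correlation length, degrees
    scenarios: Sequence[Scenario] = field(default_factory=lambda: (
        Scenario("mild", shift=0.5, scale=1.0),
        Scenario("harsh", shift=1.5, scale=1.1),
    ))
    n_countries: int = 8
    n_landcover_classes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.smoothness < 0:
            raise ConfigurationError("smoothness must be non-negative")
        if self.n_climate_vars < 2:
            raise ConfigurationError("need at least 2 climate variables")
        ids = [s.scenario_id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("scenario ids must be unique")
        if self.n_countries < 1:
            raise ConfigurationError("need at least one country")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.x_min, self.y_min, self.resolution,
                        self.n_rows, self.n_cols)


@dataclass
class SpeciesTruth:
    """Ground-truth niche of a synthetic species in the latent 2-D space."""

    species_id: str
    group: str
    centroid: np.ndarray  # 2-vector, latent PC units
    covariance: np.ndarray  # 2x2 SPD
    envelope_radius: float  # Mahalanobis units
    occurrence_count: int = 100

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.envelope_radius <= 0:
            raise ConfigurationError(
                f"{self.species_id}: envelope radius must be positive")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ConfigurationError(
                f"{self.species_id}: covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise ConfigurationError(
                f"{self.species_id}: covariance must be positive-definite")


@dataclass
class World:
    config: WorldConfig
    climate: dict[str, Raster]  # period/scenario id -> raster
    landcover: Raster  # single integer band
    country_ids: list[str]
    country_polygons: list[shapely.Geometry]
    country_raster: np.ndarray  # (rows, cols) index into country_ids
    covariates: pd.DataFrame  # country_id, area_km2, gdp_pc, centroid lon/lat

    @property
    def grid(self) -> GridSpec:
        return self.config.grid


@dataclass
class SpeciesData:
    truth: SpeciesTruth
    range_mask: np.ndarray  # boolean (rows, cols)
    occurrences: pd.DataFrame  # species, lon, lat, pixel_id

    @property
    def range_pixel_ids(self) -> np.ndarray:
        return np.flatnonzero(self.range_mask.ravel())


def _substream(seed: int, label: str) -> np.random.Generator:
    """Named child stream of the master seed (stable across processes)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_pixels: float) -> np.ndarray:
    """Unit-variance Gaussian random field from kernel-convolved noise."""
    noise = rng.standard_normal(shape)
    if sigma_pixels <= 0:
        return noise
    fld = ndimage.gaussian_filter(noise, sigma_pixels, mode="wrap")
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def generate_world(config: WorldConfig) -> World:
    """Build climate, land cover, countries and covariates from the config."""
    grid = config.grid
    sigma = config.smoothness / config.resolution

    # --- climate: GRF + linear lat/lon gradient per variable -------------
    rng_clim = _substream(config.seed, "climate")
    lon, lat = grid.center_coords()
    lon_u = (lon - lon.mean()) / max(lon.std(), 1e-12)
    lat_u = (lat - lat.mean()) / max(lat.std(), 1e-12)
    # gradient amplitude scales with smoothness so the smoothness->0 limit
    # is pure white noise (no large-scale structure)
    grad_amp = min(1.0, sigma)
    bands = []
    for _ in range(config.n_climate_vars):
        g_lat, g_lon = rng_clim.normal(0.0, 1.0, size=2)
        fld = _smooth_field(rng_clim, grid.shape, sigma)
        bands.append(fld + grad_amp * (g_lat * lat_u + g_lon * lon_u))
    current = np.stack(bands)
    names = [f"bio{i + 1}" for i in range(config.n_climate_vars)]
    climate = {"current": Raster(grid, current, band_names=list(names))}
    for sc in config.scenarios:
        shift = np.broadcast_to(np.asarray(sc.shift, dtype=float),
                                (config.n_climate_vars,))
        scale = np.broadcast_to(np.asarray(sc.scale, dtype=float),
                                (config.n_climate_vars,))
        future = shift[:, None, None] + scale[:, None, None] * current
        climate[sc.scenario_id] = Raster(grid, future, band_names=list(names))

    # --- land cover: argmax over smoothed categorical propensity fields --
    rng_lc = _substream(config.seed, "landcover")
    propensity = np.stack([
        _smooth_field(rng_lc, grid.shape, max(sigma, 1.0))
        for _ in range(config.n_landcover_classes)
    ])
    landcover = Raster(grid, (np.argmax(propensity, axis=0) + 1).astype(float),
                       band_names=["landcover"])

    # --- countries: Voronoi tiling of random seed points -----------------
    rng_cty = _substream(config.seed, "countries")
    seeds_x = rng_cty.uniform(grid.x_min, grid.x_max, config.n_countries)
    seeds_y = rng_cty.uniform(grid.y_min, grid.y_max, config.n_countries)
    extent = box(grid.x_min, grid.y_min, grid.x_max, grid.y_max)
    if config.n_countries == 1:
        polys = [extent]
    else:
        cells = voronoi_diagram(MultiPoint(list(zip(seeds_x, seeds_y))),
                                envelope=extent)
        # voronoi_diagram does not preserve seed order: match by containment
        polys = [None] * config.n_countries
        pts = shapely.points(seeds_x, seeds_y)
        for cell in cells.geoms:
            hit = np.flatnonzero(shapely.contains(cell, pts))
            for k in hit:
                polys[k] = cell.intersection(extent)
        if any(p is None for p in polys):  # pragma: no cover - degenerate seeds
            raise ConfigurationError("Voronoi cell/seed matching failed")
    country_ids = [f"C{i:02d}" for i in range(config.n_countries)]

    # raster assignment = nearest seed, which IS the Voronoi partition
    d2 = ((lon[..., None] - seeds_x) ** 2 + (lat[..., None] - seeds_y) ** 2)
    country_raster = np.argmin(d2, axis=-1)

    rows = []
    for cid, poly in zip(country_ids, polys):
        c = poly.centroid
        # equirectangular approximation is adequate at desk scale
        area_km2 = poly.area * KM_PER_DEGREE ** 2 * np.cos(np.radians(c.y))
        rows.append({"country_id": cid, "area_km2": area_km2,
                     "centroid_lon": c.x, "centroid_lat": c.y})
    covariates = pd.DataFrame(rows)
    covariates["gdp_pc"] = np.exp(rng_cty.normal(10.0, 0.6,
                                                 config.n_countries))
    return World(config=config, climate=climate, landcover=landcover,
                 country_ids=country_ids, country_polygons=list(polys),
                 country_raster=country_raster, covariates=covariates)


def latent_environment(world: World) -> tuple[Calibration, ScoreSet]:
    """First two standardized PCs of the world's current climate."""
    cal = fit_calibration(world.climate["current"])
    return cal, project_raster(cal, world.climate["current"])


def mahalanobis_distance(scores: np.ndarray, truth: SpeciesTruth) -> np.ndarray:
    delta = scores - truth.centroid
    vi = np.linalg.inv(truth.covariance)
    return np.sqrt(np.einsum("ij,jk,ik->i", delta, vi, delta))


def generate_species_set(
    world: World,
    truths: Sequence[SpeciesTruth],
    seed: int | None = None,
) -> tuple[list[SpeciesData], Calibration]:
    """Realize species ranges and occurrences from niche ground truth.

    The realized range is every pixel whose latent score lies within the
    species' Mahalanobis envelope; occurrences are drawn from range pixels
    with probability decaying in Mahalanobis distance (exp(-d^2 / 2)).
    """
    seed = world.config.seed if seed is None else seed
    cal, latent = latent_environment(world)
    grid = world.grid
    lon, lat = grid.center_coords()
    out = []
    for truth in truths:
        d = mahalanobis_distance(latent.scores, truth)
        mask = (d < truth.envelope_radius).reshape(grid.shape)
        if not mask.any():
            raise EmptyRangeError(
                f"species {truth.species_id}: climate envelope contains "
                "zero pixels")
        rng = _substream(seed, f"species:{truth.species_id}")
        pix = np.flatnonzero(mask.ravel())
        w = np.exp(-0.5 * d[pix] ** 2)
        w /= w.sum()
        chosen = rng.choice(pix, size=truth.occurrence_count, replace=True,
                            p=w)
        occ = pd.DataFrame({
            "species": truth.species_id,
            "lon": lon.ravel()[chosen],
            "lat": lat.ravel()[chosen],
            "pixel_id": chosen,
        })
        out.append(SpeciesData(truth=truth, range_mask=mask, occurrences=occ))
    return out, cal


@dataclass
class EffortParams:
    """Coefficients of the log-mean of the per-country project-count model."""

    beta0: float = 0.5
    beta_area: float = 0.5  # per SD of standardized area
    beta_gdp1: float = 0.5  # orthogonal-polynomial GDP, degree 1
    beta_gdp2: float = -0.5  # degree 2 (the inverted-U of effort vs wealth)
    dispersion: float = 2.0  # NB size theta; np.inf = Poisson limit
    spatial_noise: float = 0.0  # amplitude of MEM-1-structured log-mean noise

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")


def effort_design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """(n, 3) matrix: standardized area, orthogonal GDP polynomial (2 cols)."""
    from .gme import orthogonal_poly  # deferred: avoids import cycle

    area = covariates["area_km2"].to_numpy(dtype=float)
    area_std = (area - area.mean()) / area.std(ddof=0)
    gdp_poly = orthogonal_poly(covariates["gdp_pc"].to_numpy(dtype=float), 2)
    return np.column_stack([area_std, gdp_poly])


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               theta: float) -> np.ndarray:
    """NB2 draw via the gamma-Poisson mixture; theta=inf is Poisson."""
    if np.isinf(theta):
        return rng.poisson(mu)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


_VALID_TEMPLATE = dict(
    barcoding=False, within_species_diversity=True,
    temporal_category="horizontal", annual_sampling=False,
    political_extent="national", marker_type="microsatellite",
    strict_relaxed="strict", eu_directive="none",
    documentation_type="scientific publication", document_format="PDF",
    conservation_goal=True, n_time_points=2, time_span_years=10.0,
    generation_time_years=1.0, same_populations=True,
    pgd_index_reported=True, notes="",
)

# first-failing-rule label -> field overrides producing that failure
_INVALID_RECIPES = {
    "documentation": {"documentation_type": "not available",
                      "document_format": "not available"},
    "conservation_goal": {"conservation_goal": False},
    "temporal_replication": {"n_time_points": 1, "time_span_years": 0.0},
    "same_populations": {"same_populations": False},
}


def generate_project_table(
    world: World,
    effort_params: EffortParams,
    seed: int | None = None,
    groups: Sequence[str] = GROUPS,
    invalid_per_rule: int = 2,
    category1_records: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Draw per-country Category II counts, expand to project records.

    Counts follow a negative-binomial model whose log-mean is linear in
    standardized country area and an orthogonal quadratic in per-capita
    GDP, optionally perturbed by noise aligned with the leading Moran
    eigenvector of the country neighbour graph.  Each count becomes one
    valid Category II record; controlled numbers of invalid and
    Category I records are appended so the validity decision tree has
    known labels to recover.

    Returns the record table and a truth dict (coefficients, intended
    per-country counts, and per-record intended labels are embedded in
    the table's ``intended_*`` columns).
    """
    seed = world.config.seed if seed is None else seed
    rng = _substream(seed, "projects")
    X = effort_design_matrix(world.covariates)
    eta = (effort_params.beta0
           + effort_params.beta_area * X[:, 0]
           + effort_params.beta_gdp1 * X[:, 1]
           + effort_params.beta_gdp2 * X[:, 2])
    mem_noise = np.zeros(len(eta))
    if effort_params.spatial_noise > 0:
        from .gme import build_mem  # deferred: avoids import cycle

        centroids = world.covariates[["centroid_lon", "centroid_lat"]].to_numpy()
        mem = build_mem(centroids)
        mem_noise = effort_params.spatial_noise * mem.eigenvectors[:, 0]
    mu = np.exp(eta + mem_noise)
    counts = _nb_counts(rng, mu, effort_params.dispersion)

    records = []
    k = 0
    for cid, n in zip(world.country_ids, counts):
        for _ in range(int(n)):
            rec = dict(_VALID_TEMPLATE)
            rec.update(
                project_id=f"P{k:04d}", contributor=f"contributor_{k}",
                description=f"synthetic Category II monitoring project {k}",
                programme=f"programme_{k}", countries=cid,
                focal_group=groups[k % len(groups)],
                taxa=f"Species sp{k}", series_id=f"S{k:04d}",
                document_locator=f"doi:10.0000/synthetic.{k}",
                intended_valid=True, intended_category="II",
                intended_failing_rule="",
            )
            records.append(rec)
            k += 1
    for rule, overrides in _INVALID_RECIPES.items():
        for _ in range(invalid_per_rule):
            cid = world.country_ids[int(rng.integers(len(world.country_ids)))]
            rec = dict(_VALID_TEMPLATE)
            rec.update(overrides)
            rec.update(
                project_id=f"P{k:04d}", contributor=f"contributor_{k}",
                description=f"synthetic invalid submission ({rule})",
                programme=f"programme_{k}", countries=cid,
                focal_group=groups[k % len(groups)],
                taxa=f"Species sp{k}", series_id=f"S{k:04d}",
                document_locator="", intended_valid=False,
                intended_category="none", intended_failing_rule=rule,
            )
            records.append(rec)
            k += 1
    for _ in range(category1_records):
        cid = world.country_ids[int(rng.integers(len(world.country_ids)))]
        rec = dict(_VALID_TEMPLATE)
        rec.update(pgd_index_reported=False, barcoding=True,
                   within_species_diversity=False)
        rec.update(
            project_id=f"P{k:04d}", contributor=f"contributor_{k}",
            description="synthetic identification-only project",
            programme=f"programme_{k}", countries=cid,
            focal_group=groups[k % len(groups)], taxa=f"Species sp{k}",
            series_id=f"S{k:04d}", document_locator="",
            intended_valid=True, intended_category="I",
            intended_failing_rule="",
        )
        records.append(rec)
        k += 1

    table = pd.DataFrame(records)
    truth = {
        "beta0": effort_params.beta0,
        "beta_area": effort_params.beta_area,
        "beta_gdp1": effort_params.beta_gdp1,
        "beta_gdp2": effort_params.beta_gdp2,
        "dispersion": effort_params.dispersion,
        "spatial_noise": effort_params.spatial_noise,
        "category2_counts": dict(zip(world.country_ids,
                                     (int(c) for c in counts))),
    }
    return table, truth
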