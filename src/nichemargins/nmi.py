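"""Niche delineation and the Niche Margin Index (NMI).

A species' climatic niche is delineated in the 2-D environment space by
Gaussian kernel density estimation of its range-pixel scores.  The niche
margin is the boundary of the highest-density region enclosing a fraction
``q`` (default 0.99) of the KDE mass.  The NMI of a climate score ``z``
measures its position relative to that margin:

    NMI(z) = 1 - |z - c| / |m - c|

where ``c`` is the density-weighted niche centroid and ``m`` is the
outermost intersection of the ray from ``c`` through ``z`` with the margin
polylines.  NMI is 1 at the niche centre, 0 on the margin, and negative
outside the margin.  Interior values are clamped to [0, 1] (clamp events
logged) so fragmented or strongly non-convex margins cannot push interior
pixels above 1.  A nearest-distance variant (signed distance to the
margin, normalized by the centroid's distance to the margin) is available
via ``method="nearest"``.

The 0.99-quantile margin is interpreted as a highest-density region
(well defined for multimodal densities); an alternative rule that takes
the density level at the 1% quantile of point-wise densities is available
via ``margin_rule="density_quantile"``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiLineString, Point
from skimage import measure

from .climate import ScoreSet
from .grids import GridSpec, Raster

logger = logging.getLogger(__name__)


class DegenerateNicheError(ValueError):
    pass


class EmptyRangeError(ValueError):
    pass


@dataclass
class RangePixels:
    """A species' occupied pixels (after any land-cover filtering)."""

    species_id: str
    pixel_ids: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.pixel_ids = np.unique(np.asarray(self.pixel_ids))
        if self.pixel_ids.size == 0:
            raise EmptyRangeError(
                f"species {self.species_id}: empty range")


@dataclass
class NicheModel:
    """KDE niche surface, margin contour(s) and centroid in PC units."""

    species_id: str
    x_grid: np.ndarray  # (R,) cell-center coordinates, axis 1
    y_grid: np.ndarray  # (R,) cell-center coordinates, axis 2
    density: np.ndarray  # (R, R) indexed [iy, ix]; integrates to 1
    level: float  # density value at the q-margin
    q: float
    contours: list  # list of (k, 2) closed polylines, columns (x, y)
    centroid: np.ndarray  # 2-vector
    bandwidth: np.ndarray  # per-axis Gaussian sd
    _margin: MultiLineString = field(default=None, repr=False)

    @property
    def cell_area(self) -> float:
        return float((self.x_grid[1] - self.x_grid[0])
                     * (self.y_grid[1] - self.y_grid[0]))

    @property
    def margin(self) -> MultiLineString:
        if self._margin is None:
            self._margin = MultiLineString(
                [LineString(c) for c in self.contours])
        return self._margin

    def enclosed_mass(self) -> float:
        return float(self.density[self.density >= self.level].sum()
                     * self.cell_area)

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """Bilinear sample of the density surface at (n, 2) points."""
        points = np.atleast_2d(points)
        dx = self.x_grid[1] - self.x_grid[0]
        dy = self.y_grid[1] - self.y_grid[0]
        fx = (points[:, 0] - self.x_grid[0]) / dx
        fy = (points[:, 1] - self.y_grid[0]) / dy
        return ndimage.map_coordinates(self.density, [fy, fx], order=1,
                                       mode="constant", cval=0.0)

    def to_json(self, path: str | Path, include_density: bool = False) -> None:
        doc = {
            "species_id": self.species_id,
            "q": self.q,
            "level": self.level,
            "centroid": self.centroid.tolist(),
            "bandwidth": self.bandwidth.tolist(),
            "x_grid": [float(self.x_grid[0]), float(self.x_grid[-1]),
                       len(self.x_grid)],
            "y_grid": [float(self.y_grid[0]), float(self.y_grid[-1]),
                       len(self.y_grid)],
            "contours": [c.tolist() for c in self.contours],
        }
        if include_density:
            doc["density"] = self.density.tolist()
        Path(path).write_text(json.dumps(doc))


@dataclass
class NMIMap:
    """Per-pixel NMI values of one species for one period/scenario."""

    species_id: str
    period: str
    pixel_ids: np.ndarray
    nmi: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pixel_ids) != len(self.nmi):
            raise ValueError("pixel_ids and nmi must align")

    def to_raster(self, grid: GridSpec) -> Raster:
        band = np.full(grid.n_pixels, np.nan)
        band[self.pixel_ids] = self.nmi
        return Raster(grid, band.reshape(grid.shape),
                      band_names=[f"nmi_{self.species_id}_{self.period}"])


def filter_range_by_landcover(
    rng: RangePixels,
    landcover: Raster,
    occurrences,
) -> RangePixels:
    """Drop range pixels in land-cover classes with no species occurrence.

    The allowed classes are exactly those containing at least one
    occurrence of the species; every range pixel whose class is not
    allowed is removed.  ``occurrences`` is a DataFrame with either a
    ``pixel_id`` column or ``lon``/``lat`` columns on the land-cover
    raster's lattice.
    """
    if len(occurrences) == 0:
        raise EmptyRangeError(
            f"species {rng.species_id}: zero occurrences, no land-cover "
            "evidence")
    grid = landcover.grid
    lc = landcover.band(0).ravel()
    if "pixel_id" in occurrences:
        occ_pix = occurrences["pixel_id"].to_numpy(dtype=int)
    else:
        col = np.floor((occurrences["lon"].to_numpy() - grid.x_min)
                       / grid.resolution).astype(int)
        row = np.floor((grid.y_max - occurrences["lat"].to_numpy())
                       / grid.resolution).astype(int)
        ok = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
        occ_pix = (row[ok] * grid.n_cols + col[ok])
    allowed = set(np.unique(lc[occ_pix]).tolist())
    keep = np.isin(lc[rng.pixel_ids], list(allowed))
    removed = int((~keep).sum())
    if removed:
        logger.info("land-cover filter removed %d of %d pixels for %s",
                    removed, len(rng.pixel_ids), rng.species_id)
    if not keep.any():
        raise EmptyRangeError(
            f"species {rng.species_id}: land-cover filter removed all pixels")
    return RangePixels(species_id=rng.species_id,
                       pixel_ids=rng.pixel_ids[keep],
                       source=rng.source + "|landcover-filtered")


def _silverman_bandwidth(pts: np.ndarray) -> np.ndarray:
    """Per-axis Silverman rule for a 2-D Gaussian KDE: sd * n^(-1/6)."""
    n = len(pts)
    return pts.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)


def _binned_kde(pts: np.ndarray, x_grid: np.ndarray, y_grid: np.ndarray,
                bandwidth: np.ndarray) -> np.ndarray:
    """Gaussian KDE on a regular grid by binning + separable convolution."""
    dx = x_grid[1] - x_grid[0]
    dy = y_grid[1] - y_grid[0]
    x_edges = np.concatenate([x_grid - dx / 2, [x_grid[-1] + dx / 2]])
    y_edges = np.concatenate([y_grid - dy / 2, [y_grid[-1] + dy / 2]])
    hist, _, _ = np.histogram2d(pts[:, 1], pts[:, 0],
                                bins=[y_edges, x_edges])
    dens = ndimage.gaussian_filter(
        hist, sigma=(bandwidth[1] / dy, bandwidth[0] / dx),
        mode="constant", truncate=6.0)
    total = dens.sum() * dx * dy
    return dens / total


def _hdr_level(density: np.ndarray, cell_area: float, q: float) -> float:
    """Density level of the highest-density region holding mass q."""
    vals = np.sort(density.ravel())[::-1]
    mass = np.cumsum(vals) * cell_area
    idx = int(np.searchsorted(mass, q))
    idx = min(idx, len(vals) - 1)
    return float(vals[idx])


def _extract_contours(density: np.ndarray, level: float,
                      x_grid: np.ndarray, y_grid: np.ndarray) -> list:
    """Closed margin polylines in PC units at the given density level."""
    # zero-pad one cell so every contour closes even at the grid boundary
    padded = np.pad(density, 1, constant_values=0.0)
    dx = x_grid[1] - x_grid[0]
    dy = y_grid[1] - y_grid[0]
    out = []
    for c in measure.find_contours(padded, level):
        xy = np.column_stack([
            x_grid[0] + (c[:, 1] - 1) * dx,
            y_grid[0] + (c[:, 0] - 1) * dy,
        ])
        if not np.allclose(xy[0], xy[-1]):
            xy = np.vstack([xy, xy[0]])
        out.append(xy)
    if not out:
        raise DegenerateNicheError("no margin contour at the q level")
    return out


def estimate_niche(
    scores,
    species_id: str = "",
    grid_size: int = 200,
    padding: float = 0.1,
    q: float = 0.99,
    extent: tuple | None = None,
    bandwidth: np.ndarray | None = None,
    margin_rule: str = "hdr",
) -> NicheModel:
    """Kernel-density niche surface with its q-quantile margin.

    Parameters
    ----------
    scores : (n, 2) array or :class:`ScoreSet` of the species' range-pixel
        scores in PC units.
    extent : optional ((x0, x1), (y0, y1)) of the working space; defaults
        to the score extent.  Padded by ``padding`` (fraction of span) on
        each side.
    margin_rule : ``"hdr"`` (default) takes the boundary of the
        highest-density region enclosing mass q; ``"density_quantile"``
        takes the density level at the (1-q) quantile of the point-wise
        densities of the scores.
    """
    if isinstance(scores, ScoreSet):
        pts = scores.scores[scores.finite_mask]
    else:
        pts = np.asarray(scores, dtype=float)
        pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) < 10:
        raise ValueError(f"need >= 10 score pairs, got {len(pts)}")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if np.allclose(pts.std(axis=0), 0):
        raise DegenerateNicheError(
            f"species {species_id}: all scores identical")
    if bandwidth is None:
        bandwidth = _silverman_bandwidth(pts)
    bandwidth = np.maximum(np.asarray(bandwidth, dtype=float), 1e-12)

    if extent is None:
        extent = ((pts[:, 0].min(), pts[:, 0].max()),
                  (pts[:, 1].min(), pts[:, 1].max()))

    def build(ext):
        (x0, x1), (y0, y1) = ext
        # pad by the requested fraction plus 3 bandwidths of kernel tail
        px = padding * (x1 - x0) + 3 * bandwidth[0]
        py = padding * (y1 - y0) + 3 * bandwidth[1]
        xg = np.linspace(x0 - px, x1 + px, grid_size)
        yg = np.linspace(y0 - py, y1 + py, grid_size)
        dens = _binned_kde(pts, xg, yg, bandwidth)
        return xg, yg, dens

    x_grid, y_grid, density = build(extent)
    cell_area = (x_grid[1] - x_grid[0]) * (y_grid[1] - y_grid[0])
    if margin_rule == "hdr":
        level = _hdr_level(density, cell_area, q)
    elif margin_rule == "density_quantile":
        tmp = NicheModel(species_id, x_grid, y_grid, density, 0.0, q, [],
                         np.zeros(2), bandwidth)
        level = float(np.quantile(tmp.density_at(pts), 1 - q))
    else:
        raise ValueError(f"unknown margin_rule {margin_rule!r}")

    region = density >= level
    touches = (region[0].any() or region[-1].any()
               or region[:, 0].any() or region[:, -1].any())
    if touches:
        warnings.warn("q-region touches the KDE grid boundary; expanding "
                      "the grid once", RuntimeWarning)
        (x0, x1), (y0, y1) = extent
        sx, sy = (x1 - x0), (y1 - y0)
        x_grid, y_grid, density = build(
            ((x0 - sx * padding, x1 + sx * padding),
             (y0 - sy * padding, y1 + sy * padding)))
        cell_area = (x_grid[1] - x_grid[0]) * (y_grid[1] - y_grid[0])
        if margin_rule == "hdr":
            level = _hdr_level(density, cell_area, q)
        region = density >= level

    contours = _extract_contours(density, level, x_grid, y_grid)

    # centroid: density-weighted mean of the highest-mass component
    labels, n_comp = ndimage.label(region)
    if n_comp > 1:
        logger.warning("species %s: fragmented niche margin (%d components);"
                       " centroid taken on the highest-mass component",
                       species_id, n_comp)
        masses = ndimage.sum_labels(density, labels, np.arange(1, n_comp + 1))
        main = int(np.argmax(masses)) + 1
        comp = labels == main
    else:
        comp = region
    w = density * comp
    wx = (w.sum(axis=0) * x_grid).sum() / w.sum()
    wy = (w.sum(axis=1) * y_grid).sum() / w.sum()
    centroid = np.array([wx, wy])

    return NicheModel(species_id=species_id, x_grid=x_grid, y_grid=y_grid,
                      density=density, level=level, q=q, contours=contours,
                      centroid=centroid, bandwidth=bandwidth)


def _ray_outermost_crossing(origin: np.ndarray, directions: np.ndarray,
                            segments_p: np.ndarray,
                            segments_d: np.ndarray) -> np.ndarray:
    """Distance along each unit-direction ray to its outermost crossing
    of the margin segments; NaN when a ray misses entirely."""
    rel = segments_p - origin  # (m, 2)
    out = np.full(len(directions), np.nan)
    for i, u in enumerate(directions):
        denom = u[0] * segments_d[:, 1] - u[1] * segments_d[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (rel[:, 0] * segments_d[:, 1]
                 - rel[:, 1] * segments_d[:, 0]) / denom
            s = (rel[:, 0] * u[1] - rel[:, 1] * u[0]) / denom
        ok = (np.abs(denom) > 1e-300) & (s >= 0) & (s <= 1) & (t > 1e-12)
        if ok.any():
            out[i] = t[ok].max()
    return out


def compute_nmi(
    niche: NicheModel,
    points,
    period: str = "current",
    method: str = "radial",
) -> NMIMap:
    """Niche Margin Index of score points against a frozen niche model.

    ``method="radial"`` (default) scales by the outermost crossing of the
    centroid ray with the margin; ``method="nearest"`` uses the signed
    nearest distance to the margin normalized by the centroid's nearest
    distance.  Points whose ray misses the margin entirely receive NaN
    and are logged.
    """
    if isinstance(points, ScoreSet):
        pix = points.pixel_ids
        z = points.scores
    else:
        z = np.atleast_2d(np.asarray(points, dtype=float))
        pix = np.arange(len(z))
    nmi = np.full(len(z), np.nan)
    finite = np.all(np.isfinite(z), axis=1)
    c = niche.centroid

    if method == "radial":
        segs_p = []
        segs_d = []
        for contour in niche.contours:
            segs_p.append(contour[:-1])
            segs_d.append(np.diff(contour, axis=0))
        segments_p = np.vstack(segs_p)
        segments_d = np.vstack(segs_d)

        delta = z[finite] - c
        dist = np.hypot(delta[:, 0], delta[:, 1])
        vals = np.empty(len(delta))
        at_c = dist < 1e-12
        vals[at_c] = 1.0
        if (~at_c).any():
            u = delta[~at_c] / dist[~at_c, None]
            m = _ray_outermost_crossing(c, u, segments_p, segments_d)
            miss = np.isnan(m)
            if miss.any():
                logger.warning("compute_nmi: %d point(s) with no ray-margin "
                               "intersection excluded", int(miss.sum()))
            vals[~at_c] = 1.0 - dist[~at_c] / m
    elif method == "nearest":
        margin = niche.margin
        pts_geom = shapely.points(z[finite, 0], z[finite, 1])
        d_near = shapely.distance(margin, pts_geom)
        d_c = float(margin.distance(Point(c)))
        inside = niche.density_at(z[finite]) >= niche.level
        sign = np.where(inside, 1.0, -1.0)
        vals = sign * d_near / d_c
    else:
        raise ValueError(f"unknown method {method!r}")

    # clamp interior values into [0, 1]
    inside = niche.density_at(z[finite]) >= niche.level
    clamped = inside & ((vals > 1.0) | (vals < 0.0))
    if clamped.any():
        logger.info("compute_nmi: clamped %d interior value(s) to [0, 1]",
                    int(clamped.sum()))
        vals = np.where(inside, np.clip(vals, 0.0, 1.0), vals)
    nmi[finite] = vals
    return NMIMap(species_id=niche.species_id, period=period,
                  pixel_ids=np.asarray(pix), nmi=nmi)
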