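"""Raster lattice container and plain-text geospatial I/O.

Rasters live on a regular WGS84 lon/lat lattice with pixel-center
registration and row 0 at the northern edge.  Single bands round-trip
through the ESRI ASCII grid format (``.asc``); multiband stacks are a
directory of one ``.asc`` per band plus a JSON manifest.  Vector data
round-trip through GeoJSON via shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat lattice (pixel-center registered)."""

    x_min: float  # west edge, degrees lon
    y_min: float  # south edge, degrees lat
    resolution: float  # degrees per pixel, square pixels
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.resolution

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def lon_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        """Latitudes per row, row 0 = north."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols)."""
        lon = np.broadcast_to(self.lon_centers(), self.shape)
        lat = np.broadcast_to(self.lat_centers()[:, None], self.shape)
        return lon, lat

    def pixel_ids(self) -> np.ndarray:
        """Row-major flat pixel identifiers."""
        return np.arange(self.n_pixels)


@dataclass
class Raster:
    """One or more bands of values on a shared :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray  # (n_rows, n_cols) or (n_bands, n_rows, n_cols)
    band_names: list[str] = field(default_factory=list)
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.values.ndim == 2:
            self.values = self.values[None, :, :]
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape[1:]} does not match grid "
                f"{self.grid.shape}"
            )
        if not self.band_names:
            self.band_names = [f"band_{i + 1}" for i in range(self.n_bands)]
        if len(self.band_names) != self.n_bands:
            raise ValueError("band_names length must equal band count")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    def band(self, name_or_index: str | int) -> np.ndarray:
        if isinstance(name_or_index, str):
            idx = self.band_names.index(name_or_index)
        else:
            idx = name_or_index
        return self.values[idx]

    def flat_table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Pixels-by-bands matrix (row-major pixel order, masked rows kept)."""
        table = self.values.reshape(self.n_bands, -1).T
        if mask is not None:
            table = table[mask.ravel()]
        return table


def write_ascii_grid(path: str | Path, grid: GridSpec, band: np.ndarray,
                     nodata: float = NODATA) -> None:
    """Write one band as an ESRI ASCII grid (plain text, xllcorner form)."""
    band = np.asarray(band, dtype=float)
    out = np.where(np.isfinite(band), band, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_min!r}\n"
        f"yllcorner {grid.y_min!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    grid = GridSpec(
        x_min=meta["xllcorner"],
        y_min=meta["yllcorner"],
        resolution=meta["cellsize"],
        n_rows=int(meta["nrows"]),
        n_cols=int(meta["ncols"]),
    )
    nodata = meta.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    return grid, data


def write_raster(directory: str | Path, raster: Raster) -> None:
    """Write a multiband raster as a directory of .asc files + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, band in zip(raster.band_names, raster.values):
        write_ascii_grid(directory / f"{name}.asc", raster.grid, band,
                         raster.nodata)
    manifest = {
        "crs": "EPSG:4326",
        "band_names": raster.band_names,
        "nodata": raster.nodata,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_raster(directory: str | Path) -> Raster:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    bands = []
    grid = None
    for name in manifest["band_names"]:
        grid, band = read_ascii_grid(directory / f"{name}.asc")
        bands.append(band)
    assert grid is not None
    return Raster(grid=grid, values=np.stack(bands),
                  band_names=list(manifest["band_names"]),
                  nodata=manifest.get("nodata", NODATA))


def geometries_to_geojson(
    geometries: Sequence[BaseGeometry],
    properties: Iterable[dict] | None = None,
) -> dict:
    props = list(properties) if properties is not None else [{}] * len(geometries)
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": prop}
        for geom, prop in zip(geometries, props)
    ]
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path: str | Path, geometries: Sequence[BaseGeometry],
                  properties: Iterable[dict] | None = None) -> None:
    Path(path).write_text(
        json.dumps(geometries_to_geojson(geometries, properties)))


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return geoms, props


def pixel_centers_in_polygon(grid: GridSpec, polygon: BaseGeometry) -> np.ndarray:
    """Boolean (n_rows, n_cols) mask of pixels whose center is inside."""
    lon, lat = grid.center_coords()
    pts = shapely.points(lon.ravel(), lat.ravel())
    inside = shapely.contains(polygon, pts)
    return inside.reshape(grid.shape)
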