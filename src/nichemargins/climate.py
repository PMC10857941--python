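"""Two-dimensional climate-space calibration by principal component analysis.

The working environmental space is spanned by the first two principal
components of the standardized climate variables over a calibration extent
(typically the full terrestrial lattice of the current period).  The
calibration — per-variable means and standard deviations plus the loading
matrix — is frozen once fitted: future climate is projected through the
*same* transform, which encodes the niche-stability assumption of the
downstream marginality analysis.

PCA is run on standardized variables (a correlation-matrix PCA) because
bioclimatic variables carry incommensurate units.  The sign of each axis
is fixed so its largest-magnitude loading is positive, making projections
deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import Raster

logger = logging.getLogger(__name__)

N_AXES = 2  # working environmental space is two-dimensional


class DegenerateVariableError(ValueError):
    """A climate variable is constant over the calibration mask."""


@dataclass
class Calibration:
    """Frozen standardization + loading transform into the 2-D climate space.

    Attributes
    ----------
    means, sds : per-variable statistics over the calibration pixels.
    loadings : (n_vars, 2) matrix; columns are orthonormal PC axes.
    explained_variance : fraction of total variance per axis, for *all*
        axes (sums to 1); the first two entries describe the retained space.
    period : label of the calibration period (metadata only).
    mask_description : free-text provenance of the calibration extent.
    """

    variable_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    period: str = "current"
    mask_description: str = "all finite pixels"
    axis_variances: np.ndarray = field(default=None)  # retained-axis eigenvalues

    def __post_init__(self) -> None:
        if np.any(self.sds <= 0):
            bad = [n for n, s in zip(self.variable_names, self.sds) if s <= 0]
            raise DegenerateVariableError(
                f"constant variable(s) over calibration mask: {bad}")

    @property
    def n_vars(self) -> int:
        return len(self.variable_names)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "variable_names": self.variable_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "axis_variances": self.axis_variances.tolist(),
            "period": self.period,
            "mask_description": self.mask_description,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Calibration":
        doc = json.loads(Path(path).read_text())
        return cls(
            variable_names=doc["variable_names"],
            means=np.asarray(doc["means"]),
            sds=np.asarray(doc["sds"]),
            loadings=np.asarray(doc["loadings"]),
            explained_variance=np.asarray(doc["explained_variance"]),
            axis_variances=np.asarray(doc["axis_variances"]),
            period=doc.get("period", "current"),
            mask_description=doc.get("mask_description", ""),
        )


@dataclass
class ScoreSet:
    """Per-pixel score pairs z = (z1, z2) in PC units."""

    pixel_ids: np.ndarray
    scores: np.ndarray  # (n_pixels, 2); NaN rows mark propagated missing

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.pixel_ids), N_AXES):
            raise ValueError("scores must be (n_pixels, 2)")

    @property
    def finite_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.scores), axis=1)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_calibration(
    climate: Raster,
    mask: np.ndarray | None = None,
    period: str = "current",
) -> Calibration:
    """Standardize masked climate pixels and fit the 2-axis PCA.

    Parameters
    ----------
    climate : multiband raster, one band per climate variable.
    mask : optional boolean (n_rows, n_cols) calibration mask.  Pixels with
        any non-finite value are always excluded.
    """
    finite = np.all(np.isfinite(climate.values), axis=0)
    if mask is not None:
        finite &= mask.astype(bool)
    table = climate.flat_table(finite)
    n_pix, n_vars = table.shape
    if n_pix < 3:
        raise ValueError(f"need >= 3 calibration pixels, got {n_pix}")
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [climate.band_names[i] for i in np.where(sds <= 0)[0]]
        raise DegenerateVariableError(
            f"constant variable(s) over calibration mask: {bad}")
    if n_pix < n_vars:
        warnings.warn(
            f"fewer calibration pixels ({n_pix}) than variables ({n_vars}); "
            "fit proceeds on available rank", RuntimeWarning)
    z = (table - means) / sds
    # economy SVD of the standardized matrix; eigenvalues of the
    # correlation matrix are s**2 / (n - 1)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s ** 2 / (n_pix - 1)
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else eigvals
    loadings = _fix_signs(vt[:N_AXES].T)
    return Calibration(
        variable_names=list(climate.band_names),
        means=means,
        sds=sds,
        loadings=loadings,
        explained_variance=explained,
        axis_variances=eigvals[:N_AXES],
        period=period,
        mask_description="caller mask" if mask is not None else "all finite pixels",
    )


def project_scores(
    cal: Calibration,
    values: np.ndarray,
    pixel_ids: np.ndarray | None = None,
) -> ScoreSet:
    """Project climate vectors into the calibrated 2-D space.

    ``values`` is (n_pixels, n_vars) in the calibration's variable order.
    Rows with missing (non-finite) entries propagate to NaN scores, which
    are counted and logged rather than dropped, so pixel alignment is
    preserved.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != cal.n_vars:
        raise ValueError(
            f"expected {cal.n_vars} variables, got {values.shape[1]}")
    if pixel_ids is None:
        pixel_ids = np.arange(values.shape[0])
    z = (values - cal.means) / cal.sds
    scores = z @ cal.loadings
    bad = ~np.all(np.isfinite(values), axis=1)
    if bad.any():
        scores[bad] = np.nan
        logger.info("project_scores: %d pixel(s) with missing values "
                    "propagated to missing scores", int(bad.sum()))
    return ScoreSet(pixel_ids=np.asarray(pixel_ids), scores=scores)


def project_raster(cal: Calibration, climate: Raster) -> ScoreSet:
    """Project every pixel of a climate raster (row-major pixel ids)."""
    table = climate.flat_table()
    return ScoreSet(pixel_ids=climate.grid.pixel_ids(),
                    scores=project_scores(cal, table).scores)
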