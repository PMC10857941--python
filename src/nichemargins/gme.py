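"""Genetic-monitoring-effort accounting and spatially filtered regression.

Three stages:

1. a decision tree classifying submitted monitoring projects as valid
   Category I/II monitoring or invalid (first failing rule recorded);
2. the per-country tally of valid Category II projects (the GME), with
   every sampling country of a multi-country project credited once and
   follow-up reanalyses of the same population series de-duplicated;
3. count regression of GME on country area (linear) and per-capita GDP
   (orthogonal quadratic) with a negative-binomial (or Poisson) GLM,
   a distance-band Moran's I permutation correlogram on the deviance
   residuals, and iterative augmentation with Moran's Eigenvector Maps
   until residual spatial autocorrelation is non-significant.

Goodness of fit is the Veall–Zimmermann pseudo-R²: the Aldrich–Nelson
likelihood-ratio measure normalized by its attainable upper bound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


# --------------------------------------------------------------------------
# project validity
# --------------------------------------------------------------------------

MISSING_DOCUMENTATION = {"", "not available", "none", "nan"}

#: ordered validity rules; the first failure is recorded
RULE_ORDER = ("documentation", "conservation_goal", "temporal_replication",
              "same_populations", "cost_sampling")


@dataclass(frozen=True)
class ValidityDecision:
    project_id: str
    valid: bool
    category: str  # "I" | "II" | "none"
    failing_rule: str = ""  # first failed criterion, empty when valid


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes", "t"}
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return bool(value)


def _countries_of(record: Mapping) -> list[str]:
    raw = record.get("countries", "")
    if isinstance(raw, str):
        return [c.strip() for c in raw.split(";") if c.strip()]
    return list(raw or [])


def evaluate_project_validity(
    record: Mapping,
    member_countries: Sequence[str] | None = None,
) -> ValidityDecision:
    """Classify one project record through the ordered decision tree.

    Rules, in order: written documentation exists; a conservation or
    management goal is declared; genotype data span >= 2 time points at
    least max(1 year, 1 generation) apart; the same populations or
    identical locations were re-sampled; and (when ``member_countries``
    is given) at least one sampling country is a member country.  A
    surviving project is Category II when it reports at least one index
    of population genetic diversity, otherwise Category I
    (individual/species identification only).  Missing fields count as
    false/absent.
    """
    pid = str(record.get("project_id", ""))

    doc = str(record.get("documentation_type", "")).strip().lower()
    if doc in MISSING_DOCUMENTATION:
        return ValidityDecision(pid, False, "none", "documentation")

    if not _as_bool(record.get("conservation_goal")):
        return ValidityDecision(pid, False, "none", "conservation_goal")

    n_tp = record.get("n_time_points", 0)
    n_tp = 0 if pd.isna(n_tp) else int(n_tp)
    span = record.get("time_span_years", 0.0)
    span = 0.0 if pd.isna(span) else float(span)
    gen = record.get("generation_time_years", np.nan)
    gen = 1.0 if pd.isna(gen) else float(gen)  # one-year floor when absent
    if n_tp < 2 or span < max(1.0, gen):
        return ValidityDecision(pid, False, "none", "temporal_replication")

    if not _as_bool(record.get("same_populations")):
        return ValidityDecision(pid, False, "none", "same_populations")

    countries = _countries_of(record)
    if member_countries is not None:
        if not set(countries) & set(member_countries):
            return ValidityDecision(pid, False, "none", "cost_sampling")

    if _as_bool(record.get("pgd_index_reported")):
        return ValidityDecision(pid, True, "II")
    return ValidityDecision(pid, True, "I")


def evaluate_table(records: pd.DataFrame,
                   member_countries: Sequence[str] | None = None
                   ) -> pd.DataFrame:
    """Vector version of :func:`evaluate_project_validity` over a table."""
    rows = [evaluate_project_validity(rec, member_countries)
            for rec in records.to_dict("records")]
    return pd.DataFrame([r.__dict__ for r in rows])


def tally_effort(
    records: pd.DataFrame,
    decisions: pd.DataFrame,
    region_countries: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-country GME: the tally of valid Category II projects sampling it.

    Each valid Category II project increments every listed sampling
    country (restricted to ``region_countries`` when given).  Records
    sharing a ``series_id`` are follow-up reanalyses of one population
    series and are counted once (first record kept).  Projects listing
    zero countries are excluded with a log entry.

    Returns a table with columns ``country_id`` and ``count`` covering
    every country in ``region_countries`` (zeros included) or every
    country seen.
    """
    valid2 = set(decisions.loc[
        decisions["valid"] & (decisions["category"] == "II"), "project_id"])
    counts: dict[str, int] = (
        {c: 0 for c in region_countries} if region_countries is not None
        else {})
    seen_series: set[str] = set()
    for rec in records.to_dict("records"):
        if str(rec.get("project_id", "")) not in valid2:
            continue
        series = str(rec.get("series_id", "") or rec.get("project_id"))
        if series in seen_series:
            logger.info("tally_effort: %s is a follow-up of series %s, "
                        "not counted", rec.get("project_id"), series)
            continue
        seen_series.add(series)
        countries = _countries_of(rec)
        if region_countries is not None:
            countries = [c for c in countries if c in set(region_countries)]
        if not countries:
            logger.info("tally_effort: project %s lists no in-region "
                        "sampling country, excluded", rec.get("project_id"))
            continue
        for c in countries:
            counts[c] = counts.get(c, 0) + 1
    return (pd.DataFrame({"country_id": list(counts), "count": list(counts.values())})
            .sort_values("country_id").reset_index(drop=True))


# --------------------------------------------------------------------------
# count regression
# --------------------------------------------------------------------------


def orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis of ``x`` (columns 1..degree), the
    centered QR construction used for regression polynomials."""
    x = np.asarray(x, dtype=float)
    xbar = x.mean()
    raw = np.vander(x - xbar, degree + 1, increasing=True)
    q, r = np.linalg.qr(raw)
    # fix column signs so the basis is deterministic
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return q[:, 1:]


@dataclass
class CountFitResult:
    """A fitted count GLM of effort on area and GDP (plus spatial filters)."""

    family: str
    term_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    llf: float  # L1
    llf_null: float  # L0
    n: int
    deviance_resid: np.ndarray
    dispersion: float  # NB alpha (0 for Poisson); var = mu + alpha mu^2
    pearson_dispersion: float
    pseudo_r2: float = np.nan
    filter_ids: list[int] = field(default_factory=list)
    country_ids: list[str] = field(default_factory=list)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.term_names, "coef": self.params, "se": self.bse,
            "z": self.zvalues, "p": self.pvalues,
        })

    def term(self, name: str) -> dict:
        i = self.term_names.index(name)
        return {"coef": self.params[i], "se": self.bse[i],
                "z": self.zvalues[i], "p": self.pvalues[i]}


class FitError(RuntimeError):
    pass


def _estimate_nb_alpha(y: np.ndarray, X: np.ndarray) -> float:
    """ML estimate of the NB2 dispersion alpha (boundary-safe)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(y, X)
            res = model.fit(disp=0, maxiter=500, method="bfgs")
            if not res.mle_retvals.get("converged", True):
                res = model.fit(disp=0, maxiter=2000, method="nm")
        except Exception:
            return 1e-8
    alpha = float(res.params[-1])
    if not np.isfinite(alpha) or alpha <= 0:
        return 1e-8
    # boundary case: when NB gains no appreciable likelihood over Poisson
    # the MLE of alpha is 0 and the optimizer merely stalled near it
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        llf_pois = float(sm.GLM(y, X, family=sm.families.Poisson())
                         .fit().llf)
    if float(res.llf) - llf_pois < 1e-3:
        return 1e-8
    return alpha


def _glm_fit(y: np.ndarray, X: np.ndarray, family: str,
             alpha: float | None = None):
    if family == "poisson":
        fam = sm.families.Poisson()
        disp = 0.0
    elif family == "negative_binomial":
        if alpha is None:
            alpha = _estimate_nb_alpha(y, X)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        disp = alpha
    elif family == "hermite":
        raise NotImplementedError(
            "the Hermite count family is reserved but not implemented")
    else:
        raise ValueError(f"unknown family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=fam).fit(maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise FitError("GLM did not converge to finite coefficients")
    return res, disp


def fit_count_glm(
    effort: pd.DataFrame,
    family: str = "negative_binomial",
    exclusions: Sequence[str] = (),
    extra_terms: pd.DataFrame | None = None,
    raw_poly: bool = False,
    terms: Sequence[str] = ("area", "gdp"),
) -> CountFitResult:
    """Fit counts ~ area + poly(GDP, 2) by maximum likelihood (log link).

    ``effort`` must have columns ``country_id``, ``count``, ``area_km2``
    and ``gdp_pc``.  Area enters standardized (per-SD); GDP enters as an
    orthogonal quadratic polynomial (or raw centered powers when
    ``raw_poly``).  ``extra_terms`` (aligned by country after
    exclusions) appends columns — used for spatial filters.  The null
    model for L0 is the intercept-only fit of the same family and does
    not include the filters.
    """
    data = effort.loc[~effort["country_id"].isin(set(exclusions))]
    data = data.reset_index(drop=True)
    if len(data) < 5:
        raise FitError(f"need >= 5 countries after exclusions, got {len(data)}")
    y = data["count"].to_numpy(dtype=float)
    names = ["intercept"]
    cols = [np.ones_like(y)]
    if "area" in terms:
        area = data["area_km2"].to_numpy(dtype=float)
        if area.std() == 0:
            raise FitError("zero-variance area covariate (singular design)")
        cols.append((area - area.mean()) / area.std(ddof=0))
        names.append("area")
    if "gdp" in terms:
        gdp = data["gdp_pc"].to_numpy(dtype=float)
        if gdp.std() == 0:
            raise FitError("zero-variance GDP covariate (singular design)")
        if raw_poly:
            g = gdp - gdp.mean()
            cols += [g, g ** 2]
        else:
            cols += list(orthogonal_poly(gdp, 2).T)
        names += ["gdp_poly1", "gdp_poly2"]
    X = np.column_stack(cols)
    filter_ids: list[int] = []
    if extra_terms is not None and extra_terms.shape[1] > 0:
        X = np.column_stack([X, extra_terms.to_numpy(dtype=float)])
        names += list(extra_terms.columns)
        filter_ids = [int(str(c).rsplit("_", 1)[-1]) for c in extra_terms.columns]

    res, disp = _glm_fit(y, X, family)
    null_res, _ = _glm_fit(y, np.ones((len(y), 1)), family)
    n_terms = X.shape[1]
    pearson = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    fit = CountFitResult(
        family=family, term_names=names,
        params=np.asarray(res.params), bse=np.asarray(res.bse),
        zvalues=np.asarray(res.tvalues), pvalues=np.asarray(res.pvalues),
        llf=float(res.llf), llf_null=float(null_res.llf), n=len(y),
        deviance_resid=np.asarray(res.resid_deviance),
        dispersion=disp, pearson_dispersion=pearson,
        filter_ids=filter_ids,
        country_ids=data["country_id"].tolist(),
    )
    fit.pseudo_r2 = pseudo_r2_vz(fit)
    return fit


def pseudo_r2_vz(fit: CountFitResult) -> float:
    """Veall–Zimmermann pseudo-R²: Aldrich–Nelson ratio over its bound.

    With lambda = 2 (L1 - L0): R²_AN = lambda / (lambda + n), bound =
    -2 L0 / (-2 L0 + n); returns R²_AN / bound clipped to [0, 1].
    """
    lam = 2.0 * (fit.llf - fit.llf_null)
    if lam < -1e-8:
        raise ValueError("model likelihood below null likelihood")
    lam = max(lam, 0.0)
    r2_an = lam / (lam + fit.n)
    bound = (-2.0 * fit.llf_null) / (-2.0 * fit.llf_null + fit.n)
    if bound <= 0:
        return 0.0
    return float(np.clip(r2_an / bound, 0.0, 1.0))


# --------------------------------------------------------------------------
# spatial structure
# --------------------------------------------------------------------------


def haversine_matrix(centroids: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) for (n, 2) lon/lat degrees."""
    lon = np.radians(centroids[:, 0])
    lat = np.radians(centroids[:, 1])
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with the textbook normalization."""
    z = values - values.mean()
    s0 = weights.sum()
    denom = (z ** 2).sum()
    if denom == 0:
        raise ValueError("zero-variance values: Moran's I undefined")
    if s0 == 0:
        return np.nan
    return float(len(values) / s0 * (z @ weights @ z) / denom)


@dataclass
class Correlogram:
    band_edges_km: np.ndarray  # (k+1,), contiguous from 0
    morans: np.ndarray
    pvalues: np.ndarray
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "band_from_km": self.band_edges_km[:-1],
            "band_to_km": self.band_edges_km[1:],
            "morans_i": self.morans,
            "p_value": self.pvalues,
            "n_pairs": self.pair_counts,
        })

    def all_nonsignificant(self, alpha: float = 0.05,
                           round_digits: int = 2) -> bool:
        p = self.pvalues[np.isfinite(self.pvalues)]
        return bool(np.all(np.round(p, round_digits) >= alpha))


def moran_correlogram(
    residuals: np.ndarray,
    centroids: np.ndarray,
    band_km: float = 300.0,
    max_km: float = 1500.0,
    n_perm: int = 999,
    seed: int = 0,
) -> Correlogram:
    """Distance-band Moran's I of residuals with permutation p-values.

    Bands are contiguous from 0 in steps of ``band_km`` up to ``max_km``;
    connectivity within a band is binary on great-circle distance between
    centroids.  The p-value is two-sided around the permutation-null
    expectation E[I] = -1/(n-1), from ``n_perm`` random relabelings.
    Bands with no pairs report NaN.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    if n < 5:
        raise ValueError("need >= 5 units")
    if not np.all(np.isfinite(residuals)):
        raise ValueError("residuals must be finite")
    if residuals.std() == 0:
        raise ValueError("zero-variance residuals: Moran's I undefined")
    dist = haversine_matrix(np.asarray(centroids, dtype=float))
    edges = np.arange(0.0, max_km + band_km / 2, band_km)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    z = residuals - residuals.mean()
    denom = (z ** 2).sum()
    expect = -1.0 / (n - 1)
    morans = np.full(len(edges) - 1, np.nan)
    pvals = np.full(len(edges) - 1, np.nan)
    pairs = np.zeros(len(edges) - 1, dtype=int)
    off_diag = ~np.eye(n, dtype=bool)
    for b in range(len(edges) - 1):
        w = ((dist > edges[b]) & (dist <= edges[b + 1]) & off_diag
             ).astype(float)
        if b == 0:
            w = ((dist <= edges[1]) & off_diag).astype(float)
        s0 = w.sum()
        pairs[b] = int(s0)
        if s0 == 0:
            continue
        i_obs = n / s0 * (z @ w @ z) / denom
        zp = z[perms]  # (n_perm, n)
        i_perm = n / s0 * np.einsum("pi,ij,pj->p", zp, w, zp) / denom
        more_extreme = np.abs(i_perm - expect) >= np.abs(i_obs - expect) - 1e-15
        pvals[b] = (1 + int(more_extreme.sum())) / (n_perm + 1)
        morans[b] = i_obs
    return Correlogram(band_edges_km=edges, morans=morans, pvalues=pvals,
                       pair_counts=pairs)


@dataclass
class MEMBasis:
    """Moran's Eigenvector Maps of a country neighbour graph."""

    eigenvectors: np.ndarray  # (n, k), orthonormal, mean zero
    eigenvalues: np.ndarray  # (k,), decreasing
    link_threshold_km: float
    weight_style: str = "row-standardized"

    @property
    def positive(self) -> np.ndarray:
        """Column indices of positive-eigenvalue (positive-SAC) vectors."""
        return np.flatnonzero(self.eigenvalues > 1e-10)


def build_mem(
    centroids: np.ndarray,
    link_threshold_km: float | None = None,
) -> MEMBasis:
    """Spatial eigenvectors of the double-centered neighbour-weight matrix.

    The neighbour graph links centroid pairs within ``link_threshold_km``
    (default: the smallest distance guaranteeing every unit at least one
    neighbour).  Binary links are row-standardized, symmetrized, double
    centered and eigen-decomposed; eigenvectors are returned in
    decreasing-eigenvalue order with near-zero eigenvalues dropped.
    """
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    if n < 3:
        raise ValueError("need >= 3 units")
    dist = haversine_matrix(centroids)
    np.fill_diagonal(dist, np.inf)
    forced = link_threshold_km is not None
    if link_threshold_km is None:
        link_threshold_km = float(dist.min(axis=1).max()) * (1 + 1e-9)
    adj = (dist <= link_threshold_km)
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1 and forced:
        sizes = np.bincount(comp)
        warnings.warn(
            f"neighbour graph is disconnected at {link_threshold_km:.1f} km: "
            f"{n_comp} components with sizes {sizes.tolist()}",
            RuntimeWarning)
    w = adj.astype(float)
    row_sums = w.sum(axis=1, keepdims=True)
    nz = row_sums[:, 0] > 0
    w[nz] = w[nz] / row_sums[nz]
    w_sym = (w + w.T) / 2.0
    h = np.eye(n) - np.ones((n, n)) / n
    b = h @ w_sym @ h
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    keep = np.abs(eigvals) > 1e-10
    # deterministic sign: largest-magnitude element positive
    eigvecs = eigvecs[:, keep]
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return MEMBasis(eigenvectors=eigvecs, eigenvalues=eigvals[keep],
                    link_threshold_km=link_threshold_km)


def select_spatial_filters(
    effort: pd.DataFrame,
    mem: MEMBasis,
    family: str = "negative_binomial",
    exclusions: Sequence[str] = (),
    alpha: float = 0.05,
    band_km: float = 300.0,
    max_km: float = 1500.0,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[CountFitResult, Correlogram]:
    """Add MEM eigenvectors until residual SAC is non-significant.

    Positive-eigenvalue eigenvectors are added one at a time in
    decreasing-eigenvalue order as linear terms (kept regardless of their
    own significance); after each refit the Moran correlogram of the
    deviance residuals is recomputed, and the procedure stops when every
    band p-value (rounded to two decimals) is >= ``alpha`` for lags up to
    ``max_km``.  Exhausting the basis raises a warning and returns the
    fullest fit.

    ``mem`` must be built on the same countries, in the same order, as
    the post-exclusion rows of ``effort``.
    """
    included = effort.loc[~effort["country_id"].isin(set(exclusions))]
    if len(included) != mem.eigenvectors.shape[0]:
        raise ValueError(
            "MEM basis and post-exclusion effort table have different sizes")
    cent = included[["centroid_lon", "centroid_lat"]].to_numpy(dtype=float)
    pos = mem.positive
    best_fit, best_cor = None, None
    for k in range(len(pos) + 1):
        cols = pos[:k]
        extra = (pd.DataFrame(
            mem.eigenvectors[:, cols],
            columns=[f"mem_{int(c) + 1}" for c in cols],
            index=included.index)
            if k else None)
        fit = fit_count_glm(effort, family=family, exclusions=exclusions,
                            extra_terms=extra)
        cor = moran_correlogram(fit.deviance_resid, cent, band_km=band_km,
                                max_km=max_km, n_perm=n_perm, seed=seed)
        best_fit, best_cor = fit, cor
        if cor.all_nonsignificant(alpha):
            logger.info("select_spatial_filters: stopped after %d filter(s)",
                        k)
            return fit, cor
    warnings.warn("spatial-filter selection exhausted the positive MEM "
                  "basis without removing all residual autocorrelation",
                  RuntimeWarning)
    return best_fit, best_cor


def effort_table(
    tally: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Join the GME tally with country covariates into the model input."""
    out = covariates.merge(tally, on="country_id", how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    return out
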