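"""Project validity, effort tallies, the count GLM, Veall-Zimmermann
pseudo-R², Moran correlograms and MEM spatial filtering — each against an
independent oracle or a known simulation truth."""

import numpy as np
import pandas as pd
import pytest

import nichemargins as nm
from nichemargins.gme import (CountFitResult, effort_table, fit_count_glm,
                              haversine_matrix, orthogonal_poly,
                              pseudo_r2_vz)
from nichemargins.world import EffortParams, _nb_counts


# ---------------------------------------------------------------------------
# validity decision tree
# ---------------------------------------------------------------------------

BASE_RECORD = dict(
    project_id="P1", documentation_type="scientific publication",
    conservation_goal=True, n_time_points=2, time_span_years=10.0,
    generation_time_years=1.0, same_populations=True,
    pgd_index_reported=True, countries="SE",
)


def test_missing_documentation_is_first_failing_rule():
    rec = dict(BASE_RECORD, documentation_type="not available",
               conservation_goal=False)
    d = nm.evaluate_project_validity(rec)
    assert not d.valid and d.category == "none"
    assert d.failing_rule == "documentation"


def test_heterozygosity_over_two_years_is_category_ii():
    """A documented, conservation-motivated project re-sampling the same
    populations 10 years apart and reporting expected heterozygosity is
    valid Category II monitoring."""
    d = nm.evaluate_project_validity(dict(BASE_RECORD))
    assert d.valid and d.category == "II" and d.failing_rule == ""


def test_identification_only_project_is_category_i():
    d = nm.evaluate_project_validity(
        dict(BASE_RECORD, pgd_index_reported=False))
    assert d.valid and d.category == "I"


def test_generation_time_extends_required_spacing():
    rec = dict(BASE_RECORD, time_span_years=3.0, generation_time_years=5.0)
    d = nm.evaluate_project_validity(rec)
    assert not d.valid and d.failing_rule == "temporal_replication"
    # with the one-year floor only, three years suffice
    rec["generation_time_years"] = np.nan
    assert nm.evaluate_project_validity(rec).valid


def test_non_member_sampling_fails_when_membership_enforced():
    d = nm.evaluate_project_validity(dict(BASE_RECORD, countries="XX"),
                                     member_countries=["SE", "FI"])
    assert not d.valid and d.failing_rule == "cost_sampling"


def test_synthetic_table_labels_recovered_exactly():
    """The generator writes intended validity labels; the decision tree
    must reproduce every one of them."""
    cfg = nm.WorldConfig(n_rows=10, n_cols=10, n_countries=30, seed=17)
    world = nm.generate_world(cfg)
    table, _ = nm.generate_project_table(
        world, EffortParams(beta0=1.6), invalid_per_rule=8,
        category1_records=10)
    assert len(table) >= 150
    decisions = nm.evaluate_table(table)
    np.testing.assert_array_equal(decisions["valid"].to_numpy(),
                                  table["intended_valid"].to_numpy())
    np.testing.assert_array_equal(decisions["category"].to_numpy(),
                                  table["intended_category"].to_numpy())
    np.testing.assert_array_equal(decisions["failing_rule"].to_numpy(),
                                  table["intended_failing_rule"].to_numpy())


# ---------------------------------------------------------------------------
# effort tallies
# ---------------------------------------------------------------------------


def _records(rows):
    recs = []
    for i, row in enumerate(rows):
        rec = dict(BASE_RECORD, project_id=f"P{i}", series_id=f"S{i}")
        rec.update(row)
        recs.append(rec)
    return pd.DataFrame(recs)


def test_two_country_project_counts_in_both():
    records = _records([{"countries": "SE;FI"}])
    decisions = nm.evaluate_table(records)
    tally = nm.tally_effort(records, decisions, ["SE", "FI", "NO"])
    got = tally.set_index("country_id")["count"].to_dict()
    assert got == {"FI": 1, "NO": 0, "SE": 1}
    assert tally["count"].sum() == 2  # national-level total


def test_empty_decision_set_gives_all_zero_table():
    records = _records([])
    decisions = pd.DataFrame(columns=["project_id", "valid", "category",
                                      "failing_rule"])
    tally = nm.tally_effort(records, decisions, ["A", "B"])
    assert (tally["count"] == 0).all()


def test_followup_of_same_series_not_double_counted():
    records = _records([{"countries": "SE", "series_id": "X"},
                        {"countries": "SE", "series_id": "X"},
                        {"countries": "SE", "series_id": "Y"}])
    decisions = nm.evaluate_table(records)
    tally = nm.tally_effort(records, decisions, ["SE"])
    assert tally.loc[0, "count"] == 2


def test_constructed_tally_truth():
    """Engineered mixture of valid/invalid, single- and multi-country
    records reproduces hand-computed per-country totals, conserving the
    sum over valid projects of their sampling-country counts."""
    records = _records([
        {"countries": "A"}, {"countries": "A;B"},
        {"countries": "B", "pgd_index_reported": False},  # Category I
        {"countries": "C", "documentation_type": "not available"},
        {"countries": "A;C"}, {"countries": ""},
    ])
    decisions = nm.evaluate_table(records)
    tally = nm.tally_effort(records, decisions, ["A", "B", "C"])
    got = tally.set_index("country_id")["count"].to_dict()
    assert got == {"A": 3, "B": 1, "C": 1}
    n_country_slots = 2 + 1 + 2  # valid Cat II projects' country counts
    assert tally["count"].sum() == n_country_slots


# ---------------------------------------------------------------------------
# count GLM
# ---------------------------------------------------------------------------


def _effort_frame(counts, rng=None, n=None):
    n = len(counts) if n is None else n
    rng = rng or np.random.default_rng(0)
    lon = rng.uniform(0, 30, n)
    lat = rng.uniform(35, 60, n)
    return pd.DataFrame({
        "country_id": [f"C{i}" for i in range(n)],
        "count": counts,
        "area_km2": rng.uniform(1e4, 8e5, n),
        "gdp_pc": rng.uniform(5e3, 9e4, n),
        "centroid_lon": lon, "centroid_lat": lat,
    })


def test_intercept_only_poisson_recovers_sample_mean():
    eff = _effort_frame([1, 2, 3, 1, 2, 3])
    fit = fit_count_glm(eff, family="poisson", terms=())
    assert np.exp(fit.params[0]) == pytest.approx(2.0, abs=1e-8)


def test_orthogonal_poly_properties():
    x = np.random.default_rng(1).uniform(0, 100, 40)
    q = orthogonal_poly(x, 2)
    np.testing.assert_allclose(q.T @ q, np.eye(2), atol=1e-10)
    np.testing.assert_allclose(q.mean(axis=0), 0.0, atol=1e-12)


def test_fit_invariant_under_row_permutation():
    rng = np.random.default_rng(2)
    eff = _effort_frame(rng.poisson(3, 30), rng=rng)
    fit_a = fit_count_glm(eff, family="negative_binomial")
    perm = rng.permutation(len(eff))
    fit_b = fit_count_glm(eff.iloc[perm].reset_index(drop=True),
                          family="negative_binomial")
    np.testing.assert_allclose(fit_a.params, fit_b.params, atol=1e-10)


def test_nb_agrees_with_poisson_when_equidispersed():
    rng = np.random.default_rng(3)
    eff = _effort_frame(rng.poisson(4, 500), rng=rng)
    fit_p = fit_count_glm(eff, family="poisson")
    fit_nb = fit_count_glm(eff, family="negative_binomial")
    np.testing.assert_allclose(fit_nb.params, fit_p.params, atol=1e-4)


def test_hermite_family_reserved():
    eff = _effort_frame([1, 2, 3, 4, 5, 6])
    with pytest.raises(NotImplementedError):
        fit_count_glm(eff, family="hermite")


def test_parameter_recovery_on_simulated_counts():
    """beta-hat within 3 SE of the simulation truth for every coefficient
    in >= 95% of replicates (negative binomial, n = 500 countries)."""
    cfg = nm.WorldConfig(n_rows=12, n_cols=12, n_countries=500, seed=40)
    world = nm.generate_world(cfg)
    params = EffortParams(beta0=0.5, beta_area=0.4, beta_gdp1=0.6,
                          beta_gdp2=-0.5, dispersion=2.0)
    truth = np.array([params.beta0, params.beta_area, params.beta_gdp1,
                      params.beta_gdp2])
    hits = np.zeros(4)
    n_rep = 100
    for rep in range(n_rep):
        _, t = nm.generate_project_table(world, params, seed=5000 + rep,
                                         invalid_per_rule=0,
                                         category1_records=0)
        eff = world.covariates.assign(
            count=[t["category2_counts"][c] for c in
                   world.covariates["country_id"]])
        fit = fit_count_glm(eff, family="negative_binomial")
        hits += (np.abs(fit.params[:4] - truth) <= 3 * fit.bse[:4])
    assert np.all(hits / n_rep >= 0.95)


def test_pseudo_r2_formula_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        l0 = -rng.uniform(20, 200)
        l1 = l0 + rng.uniform(0, 50)
        n = int(rng.integers(10, 200))
        fit = CountFitResult(
            family="poisson", term_names=["intercept"],
            params=np.zeros(1), bse=np.ones(1), zvalues=np.zeros(1),
            pvalues=np.ones(1), llf=l1, llf_null=l0, n=n,
            deviance_resid=np.zeros(n), dispersion=0.0,
            pearson_dispersion=1.0)
        lam = 2 * (l1 - l0)
        expected = (lam / (lam + n)) / ((-2 * l0) / (-2 * l0 + n))
        assert pseudo_r2_vz(fit) == pytest.approx(min(expected, 1.0),
                                                  abs=1e-12)
    # null-equivalent model and the saturated limit
    fit.llf = fit.llf_null
    assert pseudo_r2_vz(fit) == 0.0
    fit.llf = fit.llf_null + 1e9
    assert pseudo_r2_vz(fit) == 1.0
    fit.llf = fit.llf_null - 1.0
    with pytest.raises(ValueError):
        pseudo_r2_vz(fit)


# ---------------------------------------------------------------------------
# Moran correlogram
# ---------------------------------------------------------------------------


def _haversine_oracle(a, b):
    lon1, lat1, lon2, lat2 = map(np.radians, [a[0], a[1], b[0], b[1]])
    s = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * 6371.0 * np.arcsin(np.sqrt(s))


def test_morans_i_matches_hand_formula_on_toy():
    cent = np.array([[0.0, 45.0], [1.0, 45.0], [2.0, 45.0], [0.5, 46.0],
                     [1.5, 46.5]])
    resid = np.array([1.2, -0.3, 0.8, -1.1, 0.4])
    cor = nm.moran_correlogram(resid, cent, band_km=150, max_km=300,
                               n_perm=99, seed=0)
    # independent textbook double-sum within each band
    n = len(resid)
    z = resid - resid.mean()
    for b, (lo, hi) in enumerate([(0, 150), (150, 300)]):
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d = _haversine_oracle(cent[i], cent[j])
                    if (lo < d <= hi) or (b == 0 and d <= hi):
                        w[i, j] = 1.0
        s0 = w.sum()
        expected = n / s0 * (z @ w @ z) / (z ** 2).sum()
        assert cor.morans[b] == pytest.approx(expected, abs=1e-12)


def test_permutation_test_type_i_error_under_null():
    """With i.i.d. residuals the per-band rejection rate at alpha = 0.05
    must sit in [0.02, 0.09] over 200 replicates."""
    rng = np.random.default_rng(6)
    cent = np.column_stack([rng.uniform(0, 18, 30),
                            rng.uniform(38, 55, 30)])
    rejections = np.zeros(5)
    n_valid = np.zeros(5)
    for rep in range(200):
        resid = rng.standard_normal(30)
        cor = nm.moran_correlogram(resid, cent, n_perm=199, seed=rep)
        ok = np.isfinite(cor.pvalues)
        rejections[ok] += cor.pvalues[ok] <= 0.05
        n_valid += ok
    rates = rejections[n_valid > 0] / n_valid[n_valid > 0]
    assert np.all(rates >= 0.02) and np.all(rates <= 0.09)


def test_engineered_clusters_detected():
    rng = np.random.default_rng(7)
    cent = np.vstack([
        np.column_stack([rng.uniform(0, 1.5, 5), rng.uniform(44, 45.5, 5)]),
        np.column_stack([rng.uniform(20, 21.5, 5),
                         rng.uniform(44, 45.5, 5)]),
    ])
    resid = np.concatenate([1.0 + 0.05 * rng.standard_normal(5),
                            -1.0 + 0.05 * rng.standard_normal(5)])
    cor = nm.moran_correlogram(resid, cent, n_perm=999, seed=1)
    assert cor.morans[0] > 0
    assert cor.pvalues[0] <= 0.05


def test_zero_variance_residuals_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        nm.moran_correlogram(np.ones(6),
                             np.column_stack([np.arange(6),
                                              np.full(6, 45.0)]))


# ---------------------------------------------------------------------------
# Moran eigenvector maps and filter selection
# ---------------------------------------------------------------------------


def test_mem_matches_dense_eigensolver_on_chain():
    """Three collinear equidistant points with the chain graph: compare to
    an explicitly built centered weight matrix decomposed in the test."""
    cent = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    mem = nm.build_mem(cent)
    w = np.array([[0.0, 1.0, 0.0], [0.5, 0.0, 0.5], [0.0, 1.0, 0.0]])
    w_sym = (w + w.T) / 2
    h = np.eye(3) - np.ones((3, 3)) / 3
    evals, evecs = np.linalg.eigh(h @ w_sym @ h)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = np.abs(evals) > 1e-10
    np.testing.assert_allclose(mem.eigenvalues, evals[keep], atol=1e-12)
    for j in range(mem.eigenvectors.shape[1]):
        dot = abs(mem.eigenvectors[:, j] @ evecs[:, keep][:, j])
        assert dot == pytest.approx(1.0, abs=1e-10)


def test_mem_vectors_centered_and_orthonormal():
    rng = np.random.default_rng(8)
    cent = np.column_stack([rng.uniform(0, 25, 20), rng.uniform(35, 60, 20)])
    mem = nm.build_mem(cent)
    np.testing.assert_allclose(mem.eigenvectors.mean(axis=0), 0, atol=1e-10)
    gram = mem.eigenvectors.T @ mem.eigenvectors
    np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


def test_forced_disconnected_threshold_warns():
    cent = np.array([[0.0, 0.0], [0.5, 0.0], [30.0, 0.0], [30.5, 0.0]])
    with pytest.warns(RuntimeWarning, match="disconnected"):
        nm.build_mem(cent, link_threshold_km=100.0)


def test_sac_free_counts_need_no_filters():
    rng = np.random.default_rng(9)
    eff = _effort_frame(rng.poisson(3, 40), rng=rng)
    mem = nm.build_mem(eff[["centroid_lon", "centroid_lat"]].to_numpy())
    fit, cor = nm.select_spatial_filters(eff, mem, family="poisson",
                                         n_perm=199, seed=2)
    assert fit.filter_ids == []
    assert cor.all_nonsignificant()


def test_injected_mem_noise_is_filtered_out():
    """Counts with log-mean contaminated along the leading eigenvector:
    selection must include >= 1 filter and end with all band p >= 0.05."""
    rng = np.random.default_rng(10)
    n = 40
    eff = _effort_frame(np.zeros(n, dtype=int), rng=rng)
    mem = nm.build_mem(eff[["centroid_lon", "centroid_lat"]].to_numpy())
    eta = 1.0 + 1.2 * mem.eigenvectors[:, mem.positive[0]] * np.sqrt(n)
    eff["count"] = rng.poisson(np.exp(eta))
    fit, cor = nm.select_spatial_filters(eff, mem, family="poisson",
                                         n_perm=199, seed=3)
    assert len(fit.filter_ids) >= 1
    assert cor.all_nonsignificant()


def test_augmentation_never_decreases_likelihood():
    rng = np.random.default_rng(11)
    eff = _effort_frame(rng.poisson(3, 30), rng=rng)
    mem = nm.build_mem(eff[["centroid_lon", "centroid_lat"]].to_numpy())
    llfs = []
    for k in range(4):
        cols = mem.positive[:k]
        extra = (pd.DataFrame(mem.eigenvectors[:, cols],
                              columns=[f"mem_{c + 1}" for c in cols])
                 if k else None)
        fit = fit_count_glm(eff, family="poisson", extra_terms=extra)
        llfs.append(fit.llf)
    assert all(b >= a - 1e-8 for a, b in zip(llfs, llfs[1:]))


def test_effort_table_joins_and_zero_fills():
    cov = pd.DataFrame({"country_id": ["A", "B"], "area_km2": [1.0, 2.0],
                        "gdp_pc": [3.0, 4.0]})
    tally = pd.DataFrame({"country_id": ["A"], "count": [5]})
    out = effort_table(tally, cov)
    assert out.set_index("country_id")["count"].to_dict() == {"A": 5, "B": 0}


def test_haversine_matches_known_distance():
    # Paris (2.35E, 48.86N) to Berlin (13.40E, 52.52N) is ~878 km
    d = haversine_matrix(np.array([[2.35, 48.86], [13.40, 52.52]]))[0, 1]
    assert d == pytest.approx(878, rel=0.01)
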