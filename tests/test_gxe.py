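"""Interaction scans, genomic inflation, candidate FDR and sensitivity refits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pgsgxe.gxe import (candidate_fdr, confounder_sensitivity, genomic_lambda,
                        gxe_gwas, interaction_scan, marginal_scan,
                        prune_by_distance)
from pgsgxe.models import DegenerateDesignError, ModelSpec, fit_volume_model, \
    standardize
from pgsgxe.study import Cohort

from conftest import make_cohort, make_pheno, make_variants


# ---------------------------------------------------------------------------
# genomic lambda
# ---------------------------------------------------------------------------


def test_lambda_reference_point_and_monotonicity(rng):
    assert genomic_lambda(np.full(99, 0.5)) == pytest.approx(1.0, abs=1e-12)
    p = rng.uniform(size=10_000)
    lam = genomic_lambda(p)
    assert 0.95 < lam < 1.05
    assert genomic_lambda(p / 2) > lam  # smaller p => more inflation
    with pytest.raises(ValueError):
        genomic_lambda(np.array([]))
    with pytest.raises(ValueError):
        genomic_lambda(np.array([0.0, 0.5]))


# ---------------------------------------------------------------------------
# candidate FDR
# ---------------------------------------------------------------------------


def _rows(pmap):
    return pd.DataFrame({"snp_id": list(pmap), "p_int": list(pmap.values())})


def test_candidate_fdr_single_and_hand_oracle():
    flags = candidate_fdr(_rows({"rs1": 0.03}), {"hippocampus": ["rs1"]})
    assert flags.iloc[0]["q"] == pytest.approx(0.03)
    assert bool(flags.iloc[0]["significant"])

    # hand BH: p = {0.01, 0.02, 0.04}, m = 3 -> q = {0.03, 0.03, 0.04}
    flags = candidate_fdr(_rows({"a": 0.01, "b": 0.02, "c": 0.04}),
                          {"amygdala": ["a", "b", "c"]})
    np.testing.assert_allclose(sorted(flags["q"]), [0.03, 0.03, 0.04], atol=1e-12)
    assert flags["significant"].all()


def test_candidate_fdr_null_untested_and_bh_bound(rng):
    pmap = {f"rs{i}": p for i, p in enumerate(rng.uniform(0.5, 1.0, 10))}
    flags = candidate_fdr(_rows(pmap), {"r": list(pmap)})
    assert not flags["significant"].any()

    flags2 = candidate_fdr(_rows({"rs1": 0.5}), {"r": ["rs1", "rs_missing"]})
    assert bool(flags2[flags2.snp_id == "rs_missing"]["untested"].iloc[0])

    # BH can never call a raw p > alpha significant at level alpha
    pmap3 = {f"s{i}": p for i, p in enumerate(rng.uniform(0.051, 1.0, 20))}
    flags3 = candidate_fdr(_rows(pmap3), {"r": list(pmap3)})
    assert not flags3["significant"].any()


# ---------------------------------------------------------------------------
# vectorised scans vs full OLS
# ---------------------------------------------------------------------------


def test_interaction_scan_matches_statsmodels(rng):
    n, m = 250, 6
    C = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    e = rng.integers(0, 2, n).astype(float)
    Cfull = np.column_stack([C, e])
    G = rng.integers(0, 3, size=(n, m)).astype(float)
    y = rng.normal(size=n)
    b, se = interaction_scan(y, G, e, Cfull)
    for j in range(m):
        X = np.column_stack([Cfull, G[:, j], G[:, j] * e])
        res = sm.OLS(y, X).fit()
        assert b[j] == pytest.approx(res.params[-1], abs=1e-10)
        assert se[j] == pytest.approx(res.bse[-1], abs=1e-10)


def test_marginal_scan_matches_statsmodels_with_clusters(rng):
    n, m = 200, 4
    C = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    X = rng.normal(size=(n, m))
    y = rng.normal(size=n)
    groups = np.repeat(np.arange(n // 2), 2)
    b, se = marginal_scan(y, X, C, groups=groups)
    for j in range(m):
        res = sm.OLS(y, np.column_stack([C, X[:, j]])).fit(
            cov_type="cluster", cov_kwds={"groups": groups})
        assert b[j] == pytest.approx(res.params[-1], abs=1e-10)
        assert se[j] == pytest.approx(res.bse[-1], rel=1e-8)


def test_monomorphic_snp_yields_nan(rng):
    n = 100
    C = np.ones((n, 1))
    e = rng.integers(0, 2, n).astype(float)
    G = np.column_stack([np.full(n, 2.0), rng.integers(0, 3, n).astype(float)])
    b, se = interaction_scan(rng.normal(size=n), G,
                             e, np.column_stack([C, e]))
    assert np.isnan(b[0]) and np.isfinite(b[1])


# ---------------------------------------------------------------------------
# gxe_gwas filters
# ---------------------------------------------------------------------------


def _mini_cohort(rng, cid, n, variants, drop_snps=()):
    m = len(variants)
    d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    geno = make_cohort(d, variants.copy(), cohort_id=cid,
                       subjects=[f"{cid}_{i}" for i in range(n)])
    if drop_snps:
        keep = ~geno.variants["snp_id"].isin(drop_snps).to_numpy()
        geno = geno.subset_variants(keep)
    pheno = make_pheno(n, rng, cohort_id=cid, n_pcs=4)
    pheno["subject_id"] = geno.subjects
    return Cohort(cohort_id=cid, pheno=pheno, geno=geno, n_pcs=4)


def test_gxe_gwas_missingness_boundary(rng):
    """A SNP absent from exactly two cohorts stays; absent from three goes."""
    v = make_variants(4, spacing=400_000)
    cohorts = []
    for i in range(5):
        drop = []
        if i < 2:
            drop.append("rs2")   # rs2 missing in 2 cohorts -> kept
        if i < 3:
            drop.append("rs3")   # rs3 missing in 3 cohorts -> excluded
        cohorts.append(_mini_cohort(rng, f"C{i}", 120, v, drop))
    scan = gxe_gwas(cohorts, "ptsd", structure="hippocampus", seed=1)
    ids = set(scan.rows["snp_id"])
    assert "rs2" in ids
    assert "rs3" not in ids
    assert scan.rows.set_index("snp_id").loc["rs2", "k_cohorts"] == 3


def test_gxe_gwas_maf_filter_any_cohort(rng):
    v = make_variants(3, spacing=400_000)
    cohorts = [_mini_cohort(rng, f"C{i}", 150, v) for i in range(3)]
    # make rs1 rare in one cohort only
    g0 = cohorts[0].geno
    g0.dosage[:, 0] = 0.0
    g0.dosage[:3, 0] = 1.0  # maf 0.01 < 0.05
    g0.maf, g0.missing_rate = g0.compute_maf_missing()
    scan = gxe_gwas(cohorts, "ptsd", seed=1)
    assert "rs1" not in set(scan.rows["snp_id"])


def test_prune_by_distance(rng):
    rows = pd.DataFrame({
        "snp_id": ["a", "b", "c", "d"],
        "chrom": ["1", "1", "1", "2"],
        "pos": [1_000_000, 1_100_000, 2_000_000, 1_000_000],
        "p_int": [1e-6, 1e-3, 1e-4, 1e-5],
    })
    out = prune_by_distance(rows, window_kb=250)
    assert list(out["snp_id"]) == ["a", "d", "c"] or \
        set(out["snp_id"]) == {"a", "c", "d"}  # b absorbed by a (within 250 kb)
    assert "b" not in set(out["snp_id"])


# ---------------------------------------------------------------------------
# confounder sensitivity
# ---------------------------------------------------------------------------


def test_confounder_sensitivity_noop_and_independent_extras(rng):
    n = 3000
    df = make_pheno(n, rng, n_pcs=4)
    pgs = rng.normal(size=n)
    df["vol_mean_hippocampus"] = (4200 + 40 * pgs - 35 * pgs * df["ptsd"]
                                  + rng.normal(0, 300, n))
    spec = ModelSpec(n_pcs=4, interaction_with="ptsd")
    base = fit_volume_model(df, pgs, spec)["PGSxPTSD"]

    empty = confounder_sensitivity(df, pgs, spec, [])
    assert empty["beta_adjusted"].iloc[0] == pytest.approx(base.beta, abs=1e-12)

    table = confounder_sensitivity(df, pgs, spec,
                                   ["GxAGE", "GxSEX", "ExAGE", "ExPC1"])
    # independent confounders barely move the interaction estimate
    assert table["abs_change"].iloc[0] < 0.1 * table["se_base"].iloc[0]
    assert table["n_extra_terms"].iloc[0] == 4


def test_confounder_sensitivity_collinear_term_dropped(rng):
    df = make_pheno(200, rng, n_pcs=4)
    pgs = rng.normal(size=200)
    spec = ModelSpec(n_pcs=4, interaction_with="ptsd")
    # ExSEX duplicates nothing, but a second copy of it is collinear
    table = confounder_sensitivity(df, pgs, spec, ["ExSEX", "ExSEX"])
    assert table["dropped_terms"].iloc[0] == "ExSEX"
    assert table["n_extra_terms"].iloc[0] == 1


def test_constant_exposure_raises(rng):
    from pgsgxe.gxe import pgs_interaction_stage
    from pgsgxe.pgs import PgsMatrix, ThresholdGrid

    df = make_pheno(50, rng)
    df["ptsd"] = 0  # constant exposure in every cohort
    grid = ThresholdGrid(np.array([0.5]))
    pgsm = PgsMatrix("TEST", "hippocampus", "beta", list(df["subject_id"]),
                     grid, rng.normal(size=(50, 1)), np.array([1]))
    with pytest.raises(DegenerateDesignError):
        pgs_interaction_stage([(Cohort("TEST", df), pgsm)], "ptsd", [0.5])
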