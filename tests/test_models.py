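"""Per-cohort model fits against independent linear-algebra and
likelihood oracles, plus the family/twin handling rules."""

import numpy as np
import pandas as pd
import pytest

from pgsgxe.models import (AssocEstimate, DegenerateDesignError, ModelSpec,
                           family_adjust, fit_ptsd_model, fit_volume_model,
                           standardize)

from conftest import make_pheno


def test_standardize_closed_form():
    np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1], atol=1e-12)
    x = np.array([4.0, np.nan, 9.0, 1.0, 7.0])
    z = standardize(x)
    assert np.isnan(z[1])
    ok = ~np.isnan(z)
    assert z[ok].mean() == pytest.approx(0, abs=1e-12)
    assert z[ok].std(ddof=1) == pytest.approx(1, abs=1e-12)
    with pytest.raises(DegenerateDesignError, match="icv"):
        standardize([5, 5, 5], name="icv")


def test_joint_vs_separate_standardization_differ():
    a = np.array([1.0, 2.0, 3.0])
    b = a + 10.0
    joint = standardize(np.r_[a, b])
    separate = np.r_[standardize(a), standardize(b)]
    assert not np.allclose(joint, separate)


def _ols_oracle(y, X):
    """Explicit normal-equations solve with classical covariance."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se


def test_volume_model_matches_normal_equations(rng):
    df = make_pheno(12, rng, n_pcs=4)
    pgs = rng.normal(size=12)
    spec = ModelSpec(n_pcs=4)
    fits = fit_volume_model(df, pgs, spec)
    est = fits["PGS"]

    y = standardize(df["vol_mean_hippocampus"])
    age_c = df["age"] - df["age"].mean()
    X = np.column_stack([
        np.ones(12), standardize(pgs), standardize(df["icv"]),
        df["sex"], age_c, age_c**2,
        df[["pc1", "pc2", "pc3", "pc4"]].to_numpy(),
    ])
    beta, se = _ols_oracle(y, X)
    assert est.beta == pytest.approx(beta[1], abs=1e-8)
    assert est.se == pytest.approx(se[1], abs=1e-8)


def test_interaction_model_matches_oracle(rng):
    df = make_pheno(40, rng, n_pcs=4)
    pgs = rng.normal(size=40)
    spec = ModelSpec(n_pcs=4, interaction_with="ptsd")
    est = fit_volume_model(df, pgs, spec)["PGSxPTSD"]

    y = standardize(df["vol_mean_hippocampus"])
    age_c = df["age"] - df["age"].mean()
    g = standardize(pgs)
    e = df["ptsd"].to_numpy(float)
    X = np.column_stack([np.ones(40), g, standardize(df["icv"]), df["sex"],
                         age_c, age_c**2,
                         df[["pc1", "pc2", "pc3", "pc4"]].to_numpy(), e, g * e])
    beta, se = _ols_oracle(y, X)
    assert est.beta == pytest.approx(beta[-1], abs=1e-8)
    assert est.se == pytest.approx(se[-1], abs=1e-8)


def test_volume_model_beta_invariant_to_pgs_scaling(rng):
    df = make_pheno(60, rng, n_pcs=4)
    pgs = rng.normal(size=60)
    spec = ModelSpec(n_pcs=4)
    b1 = fit_volume_model(df, pgs, spec)["PGS"].beta
    b2 = fit_volume_model(df, 37.0 * pgs, spec)["PGS"].beta
    assert b1 == pytest.approx(b2, abs=1e-10)


def test_rank_deficient_design_names_columns(rng):
    df = make_pheno(30, rng, n_pcs=4)
    df["pc2"] = df["pc1"]  # force collinearity
    with pytest.raises(DegenerateDesignError, match="pc"):
        fit_volume_model(df, rng.normal(size=30), ModelSpec(n_pcs=4))


def test_sex_omitted_in_single_sex_cohort(rng):
    df = make_pheno(30, rng, n_pcs=4, all_male=True)
    fits = fit_volume_model(df, rng.normal(size=30), ModelSpec(n_pcs=4))
    assert "PGS" in fits  # no constant-column failure


def test_logistic_matches_contingency_table(rng):
    """With a binary predictor and no covariates varying, the logistic slope
    is the log cross-product odds ratio."""
    n = 400
    g = rng.integers(0, 2, n)
    p = np.where(g == 1, 0.55, 0.35)
    y = (rng.random(n) < p).astype(int)
    df = make_pheno(n, rng)
    df["ptsd"] = y
    df["age"] = 50.0  # constant covariates are auto-omitted
    df["sex"] = 0.0
    est = fit_ptsd_model(df, g.astype(float), ModelSpec(outcome="ptsd"))
    a = np.sum((g == 1) & (y == 1)); b = np.sum((g == 1) & (y == 0))
    c = np.sum((g == 0) & (y == 1)); d = np.sum((g == 0) & (y == 0))
    log_or = np.log(a * d / (b * c))
    # est.beta is per SD of g; rescale to per-unit
    per_unit = est.beta / g.std(ddof=1)
    assert per_unit == pytest.approx(log_or, abs=1e-4)


def test_logistic_matches_likelihood_grid(rng):
    """1-predictor logistic MLE agrees with a brute-force likelihood grid."""
    import statsmodels.api as sm
    from scipy.special import expit

    n = 300
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(-0.5 + 0.6 * x)).astype(int)

    def nll(a, b):
        lp = a + b * x
        return -(y * np.log(expit(lp)) + (1 - y) * np.log(expit(-lp))).sum()

    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
    grid_a = np.linspace(fit.params[0] - 0.01, fit.params[0] + 0.01, 41)
    grid_b = np.linspace(fit.params[1] - 0.01, fit.params[1] + 0.01, 41)
    vals = np.array([[nll(a, b) for b in grid_b] for a in grid_a])
    ia, ib = np.unravel_index(vals.argmin(), vals.shape)
    assert grid_a[ia] == pytest.approx(fit.params[0], abs=1e-3)
    assert grid_b[ib] == pytest.approx(fit.params[1], abs=1e-3)


def test_separation_is_flagged(rng):
    df = make_pheno(40, rng)
    pgs = rng.normal(size=40)
    df["ptsd"] = (pgs > 0).astype(int)  # perfectly separable
    est = fit_ptsd_model(df, pgs, ModelSpec(outcome="ptsd"))
    assert est.flag == "separation"
    assert np.isnan(est.beta)


def test_cluster_robust_duplication_inflates_se(rng):
    """Duplicating every subject as a fake twin leaves beta unchanged and
    inflates the clustered SE by ~sqrt(2) over the naive SE."""
    n = 1500
    df = make_pheno(n, rng, n_pcs=4)
    pgs = rng.normal(size=n)
    df["vol_mean_hippocampus"] = 4200 + 40 * pgs + rng.normal(0, 400, n)

    dup = pd.concat([df, df], ignore_index=True)
    dup["family_id"] = [f"fam{i}" for i in range(n)] * 2
    dup["subject_id"] = [f"s{i}" for i in range(2 * n)]
    pgs2 = np.r_[pgs, pgs]

    naive = fit_volume_model(dup, pgs2, ModelSpec(n_pcs=4))["PGS"]
    clust = fit_volume_model(dup, pgs2,
                             ModelSpec(n_pcs=4, family_mode="cluster_robust"))["PGS"]
    assert clust.beta == pytest.approx(naive.beta, abs=1e-10)
    assert clust.se / naive.se == pytest.approx(np.sqrt(2), rel=0.05)


def test_cluster_robust_equals_hc_for_singletons(rng):
    import statsmodels.api as sm

    n = 120
    df = make_pheno(n, rng, n_pcs=4)
    df["family_id"] = None  # all singleton families
    pgs = rng.normal(size=n)
    clust = fit_volume_model(df, pgs,
                             ModelSpec(n_pcs=4, family_mode="cluster_robust"))["PGS"]
    plain = fit_volume_model(df, pgs, ModelSpec(n_pcs=4))["PGS"]
    assert clust.beta == pytest.approx(plain.beta, abs=1e-12)
    # degenerate clusters reduce to heteroskedasticity-robust (HC1) SEs
    y = standardize(df["vol_mean_hippocampus"])
    age_c = df["age"] - df["age"].mean()
    X = sm.add_constant(np.column_stack([
        standardize(pgs), standardize(df["icv"]), df["sex"], age_c, age_c**2,
        df[[f"pc{i}" for i in range(1, 5)]].to_numpy()]))
    hc1 = sm.OLS(y, X).fit(cov_type="HC1").bse[1]
    assert clust.se == pytest.approx(hc1, rel=1e-6)


def test_family_adjust_case_priority_and_determinism(rng):
    df = make_pheno(6, rng)
    df["family_id"] = ["f1", "f1", "f2", "f2", "f3", "f3"]
    df["ptsd"] = [1, 0, 0, 0, 1, 1]
    out = family_adjust(df, "drop_one_per_family", seed=7)
    assert len(out) == 3
    # family with exactly one case keeps the case
    assert out[out["family_id"] == "f1"]["ptsd"].iloc[0] == 1
    # two-case family keeps a case
    assert out[out["family_id"] == "f3"]["ptsd"].iloc[0] == 1
    out2 = family_adjust(df, "drop_one_per_family", seed=7)
    pd.testing.assert_frame_equal(out, out2)
    out3 = family_adjust(df, "cluster_robust")
    assert len(out3) == 6  # no-op for the sandwich mode


def test_interaction_type_one_error_quick(rng):
    """Null interaction p-values are roughly uniform (coarse, 60 reps)."""
    hits = 0
    reps = 60
    for k in range(reps):
        r = np.random.default_rng(1000 + k)
        df = make_pheno(300, r, n_pcs=4)
        pgs = r.normal(size=300)
        df["vol_mean_hippocampus"] = 4200 + 35 * pgs + r.normal(0, 400, 300)
        p = fit_volume_model(df, pgs,
                             ModelSpec(n_pcs=4, interaction_with="ptsd"))["PGSxPTSD"].pval
        hits += p < 0.05
    assert 0 <= hits / reps < 0.15
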