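"""Gene-by-environment stages: PGS x E interaction pooling, the per-SNP GxE
GWAS, genomic inflation, candidate-SNP FDR and confounder-sensitivity refits.

The per-SNP scan fits, within each cohort,

    volume ~ SNP + E + SNP x E + ICV + sex + age + age^2 + PCs (+ sites)

and pools the interaction term across cohorts with DerSimonian-Laird
random-effects meta-analysis.  The scan is computed by residualising the SNP
and SNP x E columns against the shared covariate block (Frisch-Waugh), which
reproduces the full OLS fit exactly while scanning thousands of SNPs at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import pc_columns
from .meta import MetaEstimate, bonferroni_alpha, dl_meta, meta_arrays
from .models import (DegenerateDesignError, ModelSpec, _check_rank,
                     _design_covariates, _volume_design, family_adjust,
                     fit_volume_model, standardize, wald_p)
from .study import Cohort

logger = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution, carried at full precision
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


@dataclass
class GxeScanResult:
    """Per-SNP interaction scan output for one structure and one exposure."""

    env: str
    structure: str
    rows: pd.DataFrame  # snp_id chrom pos beta_int se_int p_int k_cohorts ...
    lambda_gc: float
    candidate_flags: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# vectorised scans (Frisch-Waugh residualisation)
# ---------------------------------------------------------------------------


def _qr_basis(C: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(C)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def residualize(V: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return V - Q @ (Q.T @ V)


def marginal_scan(y: np.ndarray, X: np.ndarray, C: np.ndarray,
                  groups: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column slope and SE of ``y ~ x + C`` for every column of ``X``.

    Equivalent to refitting the full OLS per column.  With ``groups`` the SE
    is the family-clustered sandwich (matching statsmodels' small-sample
    correction G/(G-1) * (n-1)/(n-k)); otherwise the classical OLS SE.
    """
    n = len(y)
    Q = _qr_basis(C)
    k_cov = Q.shape[1]
    yr = residualize(y[:, None], Q)[:, 0]
    Xr = residualize(X, Q)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
    dof = n - k_cov - 1
    if groups is None:
        rss = yr @ yr - beta * sxy
        sigma2 = rss / dof
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(sigma2 / sxx)
    else:
        # u_ij = x_ij * e_ij with full-model residuals e_ij = yr_i - b_j x_ij
        U = Xr * yr[:, None] - Xr**2 * beta[None, :]
        order = np.argsort(groups, kind="mergesort")
        gs = groups[order]
        cuts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
        sums = np.add.reduceat(U[order], cuts, axis=0)
        meat = (sums**2).sum(axis=0)
        n_g = len(cuts)
        corr = n_g / (n_g - 1) * (n - 1) / dof
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(corr * meat) / sxx
    bad = sxx <= 1e-12
    beta[bad] = np.nan
    se[bad] = np.nan
    return beta, se


def interaction_scan(y: np.ndarray, G: np.ndarray, e: np.ndarray,
                     C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP interaction slope/SE of ``y ~ g + g*e + C`` (E main in C).

    Returns the coefficient on g*e and its classical OLS standard error,
    exactly as a full per-SNP OLS would.
    """
    n = len(y)
    Q = _qr_basis(C)
    k_cov = Q.shape[1]
    yr = residualize(y[:, None], Q)[:, 0]
    Gr = residualize(G, Q)
    GEr = residualize(G * e[:, None], Q)
    s11 = np.einsum("ij,ij->j", Gr, Gr)
    s22 = np.einsum("ij,ij->j", GEr, GEr)
    s12 = np.einsum("ij,ij->j", Gr, GEr)
    c1 = Gr.T @ yr
    c2 = GEr.T @ yr
    det = s11 * s22 - s12**2
    with np.errstate(invalid="ignore", divide="ignore"):
        b_g = (s22 * c1 - s12 * c2) / det
        b_int = (s11 * c2 - s12 * c1) / det
        rss = yr @ yr - (b_g * c1 + b_int * c2)
        dof = n - k_cov - 2
        sigma2 = rss / dof
        se_int = np.sqrt(sigma2 * s11 / det)
    scale = np.maximum(s11 * s22, 1e-30)
    bad = ~np.isfinite(det) | (det <= 1e-10 * scale) | (s11 <= 1e-12)
    b_int[bad] = np.nan
    se_int[bad] = np.nan
    return b_int, se_int


# ---------------------------------------------------------------------------
# stage 3: PGS x E across peak thresholds
# ---------------------------------------------------------------------------


def pgs_interaction_stage(items: list[tuple[Cohort, object]], env: str,
                          peaks: list[float], structure: str = "hippocampus",
                          alpha_family: float = 0.05) -> pd.DataFrame:
    """Pool the PGS x E interaction at each peak threshold across cohorts.

    ``items`` pairs each cohort with its :class:`~pgsgxe.pgs.PgsMatrix`.
    Cohorts lacking the exposure (all-missing or constant) are dropped from
    the pooling with a log line; if none remain a
    :class:`DegenerateDesignError` is raised.  Returns one row per peak with
    the pooled estimate and a Bonferroni pass flag over ``len(peaks)`` tests.
    """
    alpha = bonferroni_alpha(len(peaks), alpha_family)
    out = []
    metas: list[MetaEstimate] = []
    for peak in peaks:
        ests = []
        for cohort, pgsm in items:
            e = cohort.pheno[env]
            if e.notna().sum() == 0 or e.dropna().nunique() < 2:
                logger.info("pgs_interaction_stage: cohort %s lacks %s variation, dropped",
                            cohort.cohort_id, env)
                continue
            spec = ModelSpec(structure=structure, interaction_with=env,
                             n_pcs=cohort.n_pcs, include_site_dummies=cohort.multi_site,
                             family_mode="cluster_robust" if cohort.twin else "independent")
            fits = fit_volume_model(
                cohort.pheno,
                pgsm.column_aligned(peak, cohort.pheno["subject_id"]), spec)
            term = [t for t in fits if t.startswith("PGSx")][0]
            ests.append(fits[term])
        if not ests:
            raise DegenerateDesignError(
                f"exposure {env!r} is missing or constant in every cohort")
        m = dl_meta(ests)
        metas.append(m)
        out.append({"threshold": peak, "term": m.term, "beta": m.beta_pooled,
                    "se": m.se_pooled, "pval": m.pval, "tau2": m.tau2,
                    "k": m.k, "passes_bonferroni": m.pval < alpha})
    df = pd.DataFrame(out)
    df.attrs["meta_estimates"] = metas
    df.attrs["bonferroni_alpha"] = alpha
    return df


# ---------------------------------------------------------------------------
# stage 4: per-SNP GxE GWAS
# ---------------------------------------------------------------------------


def gxe_gwas(cohorts: list[Cohort], env: str, structure: str = "hippocampus",
             maf_min: float = 0.05, max_missing_cohorts: int = 2,
             prune_kb: int = 250, seed: int = 0,
             candidates_by_region: dict[str, list[str]] | None = None
             ) -> GxeScanResult:
    """Genome-wide SNP x E interaction scan pooled across cohorts.

    Per cohort, twin families are reduced to one member each (cases
    prioritised, seeded RNG); the interaction model uses the Stage-1
    covariate set plus the E main effect.  SNPs with MAF below ``maf_min`` in
    any contributing cohort, or absent from more than ``max_missing_cohorts``
    cohorts, are excluded from the meta-analysis.  Genomic inflation lambda
    is computed on the pooled p-values.
    """
    panel: dict[str, tuple] = {}
    per_cohort: list[dict] = []
    k_total = len(cohorts)
    for cohort in cohorts:
        geno = cohort.geno
        if geno is None:
            raise ValueError(f"cohort {cohort.cohort_id} has no genotypes")
        df = cohort.pheno
        if cohort.twin:
            df = family_adjust(df, "drop_one_per_family", seed=seed)
        df = df[df[env].notna() & df[f"vol_mean_{structure}"].notna()]
        need = ["icv", "age", "sex"] + pc_columns(df, cohort.n_pcs)
        df = df.dropna(subset=need)
        if df[env].nunique() < 2:
            logger.info("gxe_gwas: cohort %s has constant %s, dropped",
                        cohort.cohort_id, env)
            continue
        spec = ModelSpec(structure=structure, n_pcs=cohort.n_pcs,
                         include_site_dummies=cohort.multi_site)
        y = standardize(df[f"vol_mean_{structure}"], "volume")
        cov = _design_covariates(df, spec)
        e = df[env].to_numpy(dtype=float)
        cov[env] = e
        C = np.column_stack([np.ones(len(df)), cov.to_numpy(dtype=float)])

        sub = geno.subset_subjects(list(df["subject_id"]))
        D = sub.dosage
        eaf = np.nanmean(D, axis=0) / 2.0
        G = np.where(np.isnan(D), 2.0 * np.nan_to_num(eaf)[None, :], D)
        b_int, se_int = interaction_scan(y, G, e, C)
        maf_here = np.minimum(eaf, 1 - np.nan_to_num(eaf, nan=0.0))
        ids = geno.variants["snp_id"].to_numpy()
        for j, s in enumerate(ids):
            if s not in panel:
                row = geno.variants.iloc[j]
                panel[s] = (str(row.chrom), int(row.pos), row.effect_allele,
                            row.other_allele)
        per_cohort.append({"ids": ids, "beta": b_int, "se": se_int,
                           "maf": maf_here, "cohort_id": cohort.cohort_id})

    snp_ids = sorted(panel, key=lambda s: (panel[s][0], panel[s][1]))
    pos_of = {s: i for i, s in enumerate(snp_ids)}
    m = len(snp_ids)
    k = len(per_cohort)
    B = np.full((k, m), np.nan)
    SE = np.full((k, m), np.nan)
    present = np.zeros((k_total, m), dtype=bool)
    maf_ok = np.ones(m, dtype=bool)
    for i, pc in enumerate(per_cohort):
        idx = np.array([pos_of[s] for s in pc["ids"]])
        B[i, idx] = pc["beta"]
        SE[i, idx] = pc["se"]
        present[i, idx] = True
        low = pc["maf"] < maf_min
        maf_ok[idx[low]] = False

    n_missing = k_total - present[:k].sum(axis=0)
    keep = maf_ok & (n_missing <= max_missing_cohorts)
    logger.info("gxe_gwas[%s x %s]: %d/%d SNPs pass MAF/presence filters",
                structure, env, int(keep.sum()), m)

    res = meta_arrays(B[:, keep], SE[:, keep])
    rows = pd.DataFrame(
        {
            "snp_id": np.array(snp_ids)[keep],
            "chrom": [panel[s][0] for s in np.array(snp_ids)[keep]],
            "pos": [panel[s][1] for s in np.array(snp_ids)[keep]],
            "effect_allele": [panel[s][2] for s in np.array(snp_ids)[keep]],
            "other_allele": [panel[s][3] for s in np.array(snp_ids)[keep]],
            "beta_int": res["beta"],
            "se_int": res["se"],
            "p_int": res["pval"],
            "k_cohorts": res["k"],
        }
    )
    rows = rows[np.isfinite(rows["p_int"])].reset_index(drop=True)
    lam = genomic_lambda(rows["p_int"].to_numpy())
    flags = None
    if candidates_by_region is not None:
        flags = candidate_fdr(rows, candidates_by_region)
    return GxeScanResult(env=env, structure=structure, rows=rows,
                         lambda_gc=lam, candidate_flags=flags)


def prune_by_distance(rows: pd.DataFrame, window_kb: int = 250,
                      n_top: int | None = None) -> pd.DataFrame:
    """Greedy distance pruning of a scan table: keep the best-p SNP, drop
    neighbours within ``window_kb`` on the same chromosome, repeat."""
    df = rows.sort_values(["p_int", "chrom", "pos"], kind="mergesort")
    kept = []
    taken: dict[str, list[int]] = {}
    win = window_kb * 1000
    for r in df.itertuples():
        near = taken.get(r.chrom, [])
        if any(abs(p - r.pos) <= win for p in near):
            continue
        kept.append(r.Index)
        taken.setdefault(r.chrom, []).append(r.pos)
        if n_top is not None and len(kept) >= n_top:
            break
    return rows.loc[kept].reset_index(drop=True)


def genomic_lambda(pvalues: np.ndarray) -> float:
    """Genomic-control inflation factor: median observed 1-df chi-square
    over the null median (0.4549...)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("genomic_lambda requires at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


def candidate_fdr(rows: pd.DataFrame,
                  candidates_by_region: dict[str, list[str]],
                  q_threshold: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg within each region's candidate set.

    Candidates absent from the scan are flagged ``untested``.  A candidate is
    significant when its BH-adjusted q is at or below ``q_threshold``.
    """
    pmap = dict(zip(rows["snp_id"], rows["p_int"]))
    out = []
    for region, snps in candidates_by_region.items():
        tested = [s for s in snps if s in pmap]
        untested = [s for s in snps if s not in pmap]
        if tested:
            pvals = np.array([pmap[s] for s in tested])
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            for s, p, q in zip(tested, pvals, qvals):
                out.append({"region": region, "snp_id": s, "p": p, "q": q,
                            "significant": bool(q <= q_threshold), "untested": False})
        for s in untested:
            out.append({"region": region, "snp_id": s, "p": np.nan, "q": np.nan,
                        "significant": False, "untested": True})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# confounder sensitivity
# ---------------------------------------------------------------------------


def confounder_sensitivity(df: pd.DataFrame, pgs: np.ndarray | str,
                           spec: ModelSpec,
                           extra_terms: list[str]) -> pd.DataFrame:
    """Refit the interaction model with extra G x covariate / E x covariate
    interaction terms and report the shift in the G x E estimate.

    ``extra_terms`` uses tokens like ``"GxAGE"``, ``"ExSEX"``, ``"GxPC1"``.
    Terms that make the design rank-deficient are dropped and reported.
    Returns a one-row comparison table (base vs adjusted beta/SE plus the
    absolute and relative change and any dropped terms).
    """
    if spec.interaction_with == "none":
        raise ValueError("confounder_sensitivity requires an interaction model")
    y, X, work, term_int = _volume_design(df, pgs, spec)
    _check_rank(X)
    base = sm.OLS(y, X).fit()
    b0, s0 = float(base.params[term_int]), float(base.bse[term_int])

    env_label = "PTSD" if spec.interaction_with == "ptsd" else "CT"
    sources = {"G": X["PGS"].to_numpy(), "E": X[env_label].to_numpy()}
    covs = {"AGE": X["age"].to_numpy(),
            "SEX": X["sex"].to_numpy() if "sex" in X.columns else None}
    for c in X.columns:
        if c.startswith("pc"):
            covs[c.upper()] = X[c].to_numpy()

    X_aug = X.copy()
    dropped = []
    base_rank = np.linalg.matrix_rank(X_aug.to_numpy(dtype=float))
    for tok in extra_terms:
        side, cov = tok.split("x", 1)
        if covs.get(cov.upper()) is None:
            dropped.append(tok)
            continue
        cand = X_aug.copy()
        cand[tok] = sources[side] * covs[cov.upper()]
        if np.linalg.matrix_rank(cand.to_numpy(dtype=float)) <= base_rank:
            logger.warning("confounder_sensitivity: term %s is collinear, dropped", tok)
            dropped.append(tok)
            continue
        X_aug = cand
        base_rank += 1
    adj = sm.OLS(y, X_aug).fit()
    b1, s1 = float(adj.params[term_int]), float(adj.bse[term_int])
    return pd.DataFrame([{
        "term": term_int, "beta_base": b0, "se_base": s0,
        "p_base": wald_p(b0, s0), "beta_adjusted": b1, "se_adjusted": s1,
        "p_adjusted": wald_p(b1, s1), "abs_change": abs(b1 - b0),
        "rel_change": abs(b1 - b0) / abs(b0) if b0 != 0 else np.inf,
        "n_extra_terms": len(extra_terms) - len(dropped),
        "dropped_terms": ",".join(dropped),
    }])
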