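"""End-to-end orchestration of the four analysis stages.

Stage 1 scans the 1,001-point threshold grid per structure (per-cohort linear
models pooled by random-effects meta-analysis) and selects the maximizing
threshold.  Stage 2 tests the maximizing PGS against PTSD with per-cohort
logistic models.  Stage 3 tests PGS x PTSD and PGS x childhood-trauma
interactions at the top local-peak thresholds.  Stage 4 runs the per-SNP
GxE GWAS with genomic-control and candidate-FDR bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gxe import GxeScanResult, gxe_gwas, marginal_scan, pgs_interaction_stage, \
    prune_by_distance
from .io import pc_columns
from .meta import GridScan, bonferroni_alpha, dl_meta, forest_data, grid_scan
from .models import (AssocEstimate, ModelSpec, _design_covariates,
                     fit_ptsd_model, standardize, wald_p)
from .pgs import (PgsMatrix, ThresholdGrid, align_alleles, build_threshold_grid,
                  compute_pgs, filter_subsample_n, hard_call_cohort, ld_clump,
                  snp_qc)
from .study import Cohort, Study

logger = logging.getLogger(__name__)


@dataclass
class ScoreParams:
    certainty: float = 0.8
    maf_min: float = 0.05
    miss_max: float = 0.05
    subsample_frac: float = 0.8
    clump_r2: float = 0.1
    clump_kb: int = 250


@dataclass
class PipelineResult:
    grid: ThresholdGrid
    pgs: dict[str, dict[str, PgsMatrix]]  # structure -> cohort -> matrix
    scans: dict[str, GridScan] = field(default_factory=dict)
    stage1_table: pd.DataFrame | None = None
    stage2_table: pd.DataFrame | None = None
    stage3_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    stage4: dict[tuple[str, str], GxeScanResult] = field(default_factory=dict)


def score_all(study: Study, grid: ThresholdGrid | None = None,
              params: ScoreParams | None = None) -> dict[str, dict[str, PgsMatrix]]:
    """Hard-call, QC, harmonise, clump and score every cohort x structure."""
    grid = grid or build_threshold_grid()
    params = params or ScoreParams()
    out: dict[str, dict[str, PgsMatrix]] = {}
    prepared: dict[str, object] = {}
    for cohort in study.cohorts:
        g = hard_call_cohort(cohort.geno, certainty=params.certainty)
        prepared[cohort.cohort_id] = snp_qc(g, params.maf_min, params.miss_max)
    for structure, ss in study.sumstats.items():
        ss_f = filter_subsample_n(ss, params.subsample_frac)
        out[structure] = {}
        for cohort in study.cohorts:
            geno = prepared[cohort.cohort_id]
            ss_h, geno_h = align_alleles(ss_f, geno)
            clump = ld_clump(ss_h, geno_h, params.clump_r2, params.clump_kb)
            out[structure][cohort.cohort_id] = compute_pgs(
                geno_h, ss_h, clump, grid, structure=structure)
    return out


def _grid_assoc(cohort: Cohort, pgsm: PgsMatrix, structure: str
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-threshold standardized-PGS slope and SE for one cohort.

    Equivalent to calling :func:`~pgsgxe.models.fit_volume_model` at every
    threshold; computed in one pass by residualising against the shared
    covariate block.  Constant score columns (zero SNPs) yield NaN.
    """
    df = cohort.pheno
    spec = ModelSpec(structure=structure, n_pcs=cohort.n_pcs,
                     include_site_dummies=cohort.multi_site)
    need = [f"vol_mean_{structure}", "icv", "age", "sex"] + pc_columns(df, cohort.n_pcs)
    work = df.dropna(subset=need)
    idx = {s: i for i, s in enumerate(pgsm.subjects)}
    rows = np.array([idx[s] for s in work["subject_id"] if s in idx])
    work = work[work["subject_id"].isin(idx)].copy()
    S = pgsm.scores[rows]
    y = standardize(work[f"vol_mean_{structure}"], f"vol_mean_{structure}")
    C = np.column_stack([np.ones(len(work)),
                         _design_covariates(work, spec).to_numpy(dtype=float)])
    mean = S.mean(axis=0)
    sd = S.std(axis=0, ddof=1)
    valid = sd > 0
    Z = np.zeros_like(S)
    Z[:, valid] = (S[:, valid] - mean[valid]) / sd[valid]
    groups = None
    if cohort.twin:
        groups = work["family_id"].fillna(work["subject_id"]).to_numpy()
    beta, se = marginal_scan(y, Z, C, groups=groups)
    beta[~valid] = np.nan
    se[~valid] = np.nan
    return beta, se, len(work)


def run_stage1(study: Study, pgs_all: dict[str, dict[str, PgsMatrix]],
               grid: ThresholdGrid) -> tuple[dict[str, GridScan], pd.DataFrame]:
    """Grid scan per structure; returns scans and a report of per-cohort and
    pooled estimates at each structure's maximizing threshold."""
    scans: dict[str, GridScan] = {}
    rows = []
    for structure, by_cohort in pgs_all.items():
        per_cohort: dict[str, tuple] = {}
        for cohort in study.cohorts:
            per_cohort[cohort.cohort_id] = _grid_assoc(
                cohort, by_cohort[cohort.cohort_id], structure)
        ests_by_thr = []
        for j in range(len(grid)):
            ests = [AssocEstimate(cid, "PGS", b[j], s[j],
                                  wald_p(b[j], s[j]) if np.isfinite(b[j] / s[j]) else np.nan,
                                  n)
                    for cid, (b, s, n) in per_cohort.items()]
            ests_by_thr.append(ests)
        scan = grid_scan(grid, ests_by_thr, structure=structure,
                         weight_kind=next(iter(by_cohort.values())).weight_kind,
                         allow_empty=True)
        scans[structure] = scan
        best = scan.best()
        alpha = bonferroni_alpha(len(grid), 0.05)
        for e in best.per_cohort:
            rows.append({"structure": structure, "cohort": e.cohort_id,
                         "threshold": scan.best_threshold, "beta": e.beta,
                         "se": e.se, "pval": e.pval, "n": e.n})
        rows.append({"structure": structure, "cohort": "Meta",
                     "threshold": scan.best_threshold, "beta": best.beta_pooled,
                     "se": best.se_pooled, "pval": best.pval,
                     "n": sum(e.n for e in best.per_cohort),
                     "passes_bonferroni": bool(best.pval < alpha)})
    return scans, pd.DataFrame(rows)


def run_stage2(study: Study, pgs_all: dict[str, dict[str, PgsMatrix]],
               scans: dict[str, GridScan]) -> pd.DataFrame:
    """PGS -> PTSD logistic models at each structure's maximizing threshold."""
    rows = []
    for structure, scan in scans.items():
        ests = []
        for cohort in study.cohorts:
            pgsm = pgs_all[structure][cohort.cohort_id]
            vals = pgsm.column_aligned(scan.best_threshold,
                                       cohort.pheno["subject_id"])
            spec = ModelSpec(outcome="ptsd", structure=structure,
                             family_mode="cluster_robust" if cohort.twin else "independent")
            est = fit_ptsd_model(cohort.pheno, vals, spec)
            if est.flag is None:
                ests.append(est)
            rows.append({"structure": structure, "cohort": cohort.cohort_id,
                         "threshold": scan.best_threshold, "beta": est.beta,
                         "or": est.or_, "se": est.se, "pval": est.pval,
                         "n": est.n, "flag": est.flag})
        meta = dl_meta(ests, term="PGS->PTSD")
        rows.append({"structure": structure, "cohort": "Meta",
                     "threshold": scan.best_threshold, "beta": meta.beta_pooled,
                     "or": float(np.exp(meta.beta_pooled)), "se": meta.se_pooled,
                     "pval": meta.pval, "n": sum(e.n for e in ests), "flag": None})
    return pd.DataFrame(rows)


def run_stage3(study: Study, pgs_all: dict[str, dict[str, PgsMatrix]],
               scans: dict[str, GridScan],
               envs: tuple[str, ...] = ("ptsd", "child_trauma"),
               structures: tuple[str, ...] | None = None,
               n_peaks: int = 5) -> dict[str, pd.DataFrame]:
    """PGS x E interaction meta-analysis at the top local-peak thresholds."""
    structures = structures or tuple(scans)
    out: dict[str, pd.DataFrame] = {}
    for structure in structures:
        scan = scans[structure]
        peaks = scan.top_peaks(n_peaks)
        items = [(c, pgs_all[structure][c.cohort_id]) for c in study.cohorts]
        for env in envs:
            table = pgs_interaction_stage(items, env, peaks, structure=structure)
            out[f"{structure}:{env}"] = table
    return out


def run_stage4(study: Study, envs: tuple[str, ...] = ("ptsd", "child_trauma"),
               structures: tuple[str, ...] = ("hippocampus", "amygdala"),
               seed: int = 0,
               candidates_by_region: dict[str, list[str]] | None = None
               ) -> dict[tuple[str, str], GxeScanResult]:
    """Per-SNP GxE GWAS for each structure x exposure pair."""
    out = {}
    for structure in structures:
        cands = None
        if candidates_by_region is not None:
            cands = {structure: candidates_by_region.get(structure, [])}
        for env in envs:
            out[(structure, env)] = gxe_gwas(
                study.cohorts, env, structure=structure, seed=seed,
                candidates_by_region=cands)
    return out


def run_all(study: Study, outdir: str | Path | None = None, seed: int = 0,
            params: ScoreParams | None = None,
            gwas_structures: tuple[str, ...] = ("hippocampus", "amygdala"),
            candidates_by_region: dict[str, list[str]] | None = None
            ) -> PipelineResult:
    """Execute Stages 1-4 and optionally write TSV reports + provenance."""
    grid = build_threshold_grid()
    pgs_all = score_all(study, grid, params)
    scans, t1 = run_stage1(study, pgs_all, grid)
    t2 = run_stage2(study, pgs_all, scans)
    gwas_structures = tuple(s for s in gwas_structures if s in scans)
    t3 = run_stage3(study, pgs_all, scans, structures=gwas_structures)
    s4 = run_stage4(study, structures=gwas_structures, seed=seed,
                    candidates_by_region=candidates_by_region)
    result = PipelineResult(grid=grid, pgs=pgs_all, scans=scans,
                            stage1_table=t1, stage2_table=t2,
                            stage3_tables=t3, stage4=s4)
    if outdir is not None:
        _write_reports(result, Path(outdir), seed)
    return result


def _write_reports(result: PipelineResult, outdir: Path, seed: int) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.6g")
    result.stage1_table.to_csv(outdir / "stage1_pgs_associations.tsv", **fmt)
    result.stage2_table.to_csv(outdir / "stage2_pgs_ptsd.tsv", **fmt)
    for key, table in result.stage3_tables.items():
        structure, env = key.split(":")
        table.to_csv(outdir / f"stage3_interaction_{structure}_{env}.tsv", **fmt)
        metas = table.attrs.get("meta_estimates", [])
        if metas:
            best = min(metas, key=lambda m: m.pval)
            forest_data(best).to_csv(
                outdir / f"forest_{structure}_{env}.tsv", **fmt)
    for (structure, env), scan in result.stage4.items():
        scan.rows.to_csv(outdir / f"stage4_gxe_gwas_{structure}_{env}.tsv", **fmt)
        prune_by_distance(scan.rows, n_top=20).to_csv(
            outdir / f"stage4_top_{structure}_{env}.tsv", **fmt)
        if scan.candidate_flags is not None:
            scan.candidate_flags.to_csv(
                outdir / f"stage4_candidates_{structure}_{env}.tsv", **fmt)
    lam = {f"{s}:{e}": scan.lambda_gc for (s, e), scan in result.stage4.items()}
    best_thr = {s: scan.best_threshold for s, scan in result.scans.items()}
    prov = {
        "seed": seed,
        "best_thresholds": best_thr,
        "lambda": lam,
        "versions": _versions(),
        "config_hash": hashlib.sha256(
            json.dumps({"seed": seed, "thresholds": len(result.grid)},
                       sort_keys=True).encode()).hexdigest(),
    }
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1))


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, statsmodels

    return {"pgsgxe": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__}
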