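"""Synthetic multi-cohort study generator with known ground truth.

Emulates the study design the pipeline targets: a large normative discovery
GWAS of subcortical volumes, five heterogeneous target cohorts (one all-male
twin cohort, one very large control-heavy population cohort, one
mega-analysed multi-site cohort), LD-blocked genotypes with imputation
probabilities, a positive PGS -> volume effect in controls attenuated in
PTSD cases (the headline GxE), and an amygdala-score -> PTSD log-odds
effect.  Everything is a pure function of (config, seed).

Genotypes use a latent-Gaussian block model: within a block of
``block_size`` SNPs the two haplotype latents share an exchangeable
correlation ``within_block_rho`` and are thresholded at each SNP's allele
frequency, giving Hardy-Weinberg genotypes with block LD.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .io import (STRUCTURES, GenotypeCohort, SummaryStats, write_phenotypes,
                 write_summary_stats, write_vcf)
from .study import Cohort, Study

# mm^3 location/scale used to put standardized volumes on a realistic scale
VOLUME_SCALE = {
    "accumbens": (600.0, 80.0),
    "amygdala": (1700.0, 180.0),
    "caudate": (3600.0, 380.0),
    "hippocampus": (4200.0, 400.0),
    "pallidum": (1800.0, 190.0),
    "putamen": (5100.0, 500.0),
    "thalamus": (7500.0, 700.0),
}

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class CohortSpec:
    cohort_id: str
    n: int
    ptsd_prevalence: float
    ct_prevalence: float | None  # None: childhood trauma not collected
    n_pcs: int = 4
    n_sites: int = 1
    twin: bool = False
    all_male: bool = False
    male_frac: float = 0.8
    age_mean: float = 40.0
    age_sd: float = 10.0


def default_cohorts() -> list[CohortSpec]:
    """The five analysis cohorts (Ns 377/143/169/6570/321, total 7580):
    a mega-analysed multi-site cohort, two mid-size veteran cohorts, a very
    large control-heavy population cohort (10 PCs), and an all-male twin
    cohort."""
    return [
        CohortSpec("PGC-PTSD", 377, 0.459, 0.508, n_sites=5,
                   male_frac=0.785, age_mean=35.3, age_sd=11.3),
        CohortSpec("MIRE", 143, 0.266, 0.448,
                   male_frac=0.895, age_mean=37.6, age_sd=9.9),
        CohortSpec("TRAC", 169, 0.561, 0.226,
                   male_frac=0.935, age_mean=31.2, age_sd=8.2),
        CohortSpec("UKBB", 6570, 160 / 6570, 0.258, n_pcs=10,
                   male_frac=0.465, age_mean=55.1, age_sd=7.4),
        CohortSpec("VETS", 321, 0.106, 0.611, twin=True, all_male=True,
                   age_mean=62.0, age_sd=2.6),
    ]


@dataclass
class SimConfig:
    seed: int = 17
    n_snps: int = 2000
    block_size: int = 20
    within_block_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 100
    h2_pgs: float = 0.008  # target-sample variance explained (control slope ~0.09)
    discovery_h2: float = 0.05  # score-volume R^2 in the discovery sample
    discovery_n: int = 33536
    cohort_specs: list[CohortSpec] = field(default_factory=default_cohorts)
    delta_gxe: float = -1.0  # multiplicative slope attenuation in cases; -1 => 0
    amygdala_logOR: float = math.log(1.15)
    missing_rate: float = 0.01
    imputation_certainty_noise: float = 0.05
    low_n_frac: float = 0.1  # fraction of discovery SNPs run on a subsample
    twin_residual_rho: float = 0.5
    ct_ptsd_logodds: float = 0.0  # optional CT-PTSD coupling
    spike_snp: str | None = None  # plant a single SNP x PTSD effect...
    spike_gxe_beta: float = 0.0   # ...of this size (SD volume per allele)
    structures: tuple[str, ...] = ("hippocampus", "amygdala")

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.block_size > self.n_snps:
            raise ValueError("block_size cannot exceed n_snps")
        for cs in self.cohort_specs:
            if not (0 < cs.ptsd_prevalence < 1):
                raise ValueError(f"{cs.cohort_id}: prevalence must lie in (0, 1)")
        unknown = set(self.structures) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown structures {sorted(unknown)}")

    @property
    def total_n(self) -> int:
        return sum(cs.n for cs in self.cohort_specs)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    causal_snps: dict[str, np.ndarray]
    true_weights: dict[str, np.ndarray]  # length n_snps, zero off the causal set
    true_scores: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    realized_slopes: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# panel, truth, genotypes
# ---------------------------------------------------------------------------


def make_panel(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant panel: blocks spaced 2 Mb apart, SNPs 10 kb apart in-block."""
    n = config.n_snps
    n_blocks = int(np.ceil(n / config.block_size))
    rows = []
    for j in range(n):
        b = j // config.block_size
        chrom = str(b % 22 + 1)
        block_on_chrom = b // 22
        pos = 1_000_000 + block_on_chrom * 2_000_000 + (j % config.block_size) * 10_000
        a1, a2 = _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        rows.append((f"rs{j + 1}", chrom, pos, a1, a2, b))
    panel = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos",
                                        "effect_allele", "other_allele", "block"])
    panel["maf"] = rng.uniform(*config.maf_range, size=n)
    return panel


def simulate_truth(config: SimConfig, panel: pd.DataFrame,
                   rng: np.random.Generator) -> GroundTruth:
    causal, weights = {}, {}
    for s in config.structures:
        idx = np.sort(rng.choice(config.n_snps, size=config.n_causal, replace=False))
        w = np.zeros(config.n_snps)
        w[idx] = rng.normal(size=config.n_causal)
        causal[s] = idx
        weights[s] = w
    return GroundTruth(causal_snps=causal, true_weights=weights)


def _draw_dosages(n: int, panel: pd.DataFrame, rho: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg dosages with exchangeable within-block latent LD."""
    m = len(panel)
    cut = _norm_ppf(panel["maf"].to_numpy())
    dosage = np.empty((n, m), dtype=np.int8)
    blocks = panel["block"].to_numpy()
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        k = len(cols)
        for hap in range(2):
            shared = rng.normal(size=(n, 1))
            eps = rng.normal(size=(n, k))
            latent = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps
            allele = (latent < cut[cols][None, :]).astype(np.int8)
            if hap == 0:
                dosage[:, cols] = allele
            else:
                dosage[:, cols] += allele
    return dosage


def _norm_ppf(q: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(q)


def simulate_genotypes(config: SimConfig, panel: pd.DataFrame | None = None,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, dict[str, GenotypeCohort]]:
    """Per-cohort genotype matrices over a shared panel.

    Twin cohorts draw one genotype per pair and duplicate it (monozygotic
    twins).  Imputation probability triples concentrate ``1 - d`` mass on the
    true class with an exponential certainty deficit ``d`` (scale
    ``imputation_certainty_noise``), so a small fraction of genotypes falls
    below the 80% hard-call bar; dosages are the GP-expected counts.
    Additional genotypes go missing completely at random at ``missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = make_panel(config, rng)
    cohorts: dict[str, GenotypeCohort] = {}
    for cs in config.cohort_specs:
        if cs.twin:
            n_unique = (cs.n + 1) // 2
            uniq = _draw_dosages(n_unique, panel, config.within_block_rho, rng)
            reps = np.repeat(np.arange(n_unique), 2)[: cs.n]
            true_d = uniq[reps]
        else:
            true_d = _draw_dosages(cs.n, panel, config.within_block_rho, rng)
        gp = _genotype_probs(true_d, config.imputation_certainty_noise, rng)
        dosage = gp[..., 1] + 2.0 * gp[..., 2]
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan
        gp[miss] = np.nan
        subjects = [f"{cs.cohort_id}_{i + 1:05d}" for i in range(cs.n)]
        cohorts[cs.cohort_id] = GenotypeCohort(
            cohort_id=cs.cohort_id, subjects=subjects,
            variants=panel[["snp_id", "chrom", "pos", "effect_allele",
                            "other_allele"]].copy(),
            dosage=dosage, genotype_prob=gp)
    return panel, cohorts


def _genotype_probs(true_d: np.ndarray, noise: float,
                    rng: np.random.Generator) -> np.ndarray:
    n, m = true_d.shape
    deficit = np.minimum(rng.exponential(noise, size=(n, m)), 0.7)
    split = rng.random((n, m))
    gp = np.zeros((n, m, 3))
    others = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    for g in (0, 1, 2):
        mask = true_d == g
        gp[mask, g] = 1.0 - deficit[mask]
        o1, o2 = others[g]
        gp[mask, o1] = deficit[mask] * split[mask]
        gp[mask, o2] = deficit[mask] * (1.0 - split[mask])
    return gp


# ---------------------------------------------------------------------------
# discovery summary statistics
# ---------------------------------------------------------------------------


def simulate_discovery_sumstats(config: SimConfig, panel: pd.DataFrame,
                                truth: GroundTruth, rng: np.random.Generator,
                                structure: str = "hippocampus",
                                weight_kind: str = "beta",
                                n_ref: int = 4000) -> SummaryStats:
    """Marginal discovery GWAS of one structure's volume.

    The marginal (LD-leaked) effect of each SNP is the reference-sample
    regression of the true standardized score on the SNP, scaled by the
    discovery-sample score-volume correlation sqrt(discovery_h2); sampling
    noise is added at the Wald standard error 1 / (sd(g) sqrt(N)).  A
    ``low_n_frac`` share of SNPs is marked as analysed on 50-80% of the
    maximum sample to exercise the per-SNP N filter.
    """
    G_ref = _draw_dosages(n_ref, panel, config.within_block_rho, rng).astype(float)
    w = truth.true_weights[structure]
    S = G_ref @ w
    S = (S - S.mean()) / S.std(ddof=1)
    sd_g = G_ref.std(axis=0, ddof=1)
    sd_g = np.where(sd_g < 1e-6, 1e-6, sd_g)
    cov_gs = (G_ref - G_ref.mean(axis=0)).T @ S / (n_ref - 1)
    beta_true = math.sqrt(config.discovery_h2) * cov_gs / sd_g**2

    m = len(panel)
    n_eff = np.round(config.discovery_n * rng.uniform(0.97, 1.0, size=m)).astype(int)
    low = rng.random(m) < config.low_n_frac
    n_eff[low] = np.round(config.discovery_n * rng.uniform(0.5, 0.8, size=low.sum())).astype(int)
    n_eff[np.argmax(n_eff)] = config.discovery_n  # pin the maximum

    se = 1.0 / (sd_g * np.sqrt(n_eff))
    beta_hat = beta_true + rng.normal(size=m) * se
    z = beta_hat / se
    from scipy.stats import norm

    pval = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "snp_id": panel["snp_id"],
            "chrom": panel["chrom"],
            "pos": panel["pos"],
            "effect_allele": panel["effect_allele"],
            "other_allele": panel["other_allele"],
            "weight": z if weight_kind == "zscore" else beta_hat,
            "se": se,
            "pval": pval,
            "n_eff": n_eff,
        }
    )
    return SummaryStats(table=table, weight_kind=weight_kind)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _solve_intercept(target_prev: float, lp: np.ndarray) -> float:
    f = lambda a: expit(a + lp).mean() - target_prev
    try:
        return optimize.brentq(f, -30.0, 30.0)
    except ValueError as err:
        raise ValueError(f"prevalence {target_prev} unattainable for the given "
                         f"liability effects") from err


def _phenotypes_from_scores(cs: CohortSpec, scores: dict[str, np.ndarray],
                            config: SimConfig, rng: np.random.Generator,
                            family_id: np.ndarray | None,
                            subjects: list[str],
                            spike_dosage: np.ndarray | None = None) -> pd.DataFrame:
    n = cs.n
    age = np.clip(rng.normal(cs.age_mean, cs.age_sd, size=n), 18.0, 90.0)
    sex = np.zeros(n) if cs.all_male else (rng.random(n) >= cs.male_frac).astype(float)
    icv = rng.normal(1.5e6, 1.5e5, size=n)
    icv_z = (icv - icv.mean()) / icv.std(ddof=1)
    pcs = rng.normal(size=(n, 10))
    site = (np.array([f"site{rng.integers(cs.n_sites) + 1}" for _ in range(n)])
            if cs.n_sites > 1 else np.array([None] * n, dtype=object))

    s_amy = scores.get("amygdala", np.zeros(n))
    s_amy_z = (s_amy - s_amy.mean()) / (s_amy.std(ddof=1) if s_amy.std() > 0 else 1.0)
    alpha = _solve_intercept(cs.ptsd_prevalence, config.amygdala_logOR * s_amy_z)
    ptsd = (rng.random(n) < expit(alpha + config.amygdala_logOR * s_amy_z)).astype(int)

    if cs.ct_prevalence is None:
        ct = np.full(n, np.nan)
    elif config.ct_ptsd_logodds != 0.0:
        a_ct = _solve_intercept(cs.ct_prevalence, config.ct_ptsd_logodds * ptsd.astype(float))
        ct = (rng.random(n) < expit(a_ct + config.ct_ptsd_logodds * ptsd)).astype(float)
    else:
        ct = (rng.random(n) < cs.ct_prevalence).astype(float)

    data = {
        "subject_id": subjects,
        "family_id": family_id if family_id is not None else [None] * n,
        "cohort_id": cs.cohort_id,
        "site_id": site,
        "icv": icv,
        "age": age,
        "sex": sex,
        "ptsd": ptsd,
        "child_trauma": ct,
    }
    for i in range(10):
        data[f"pc{i + 1}"] = pcs[:, i]
    df = pd.DataFrame(data)

    b_g = math.sqrt(config.h2_pgs)
    age_c = age - 50.0
    site_eff = np.zeros(n)
    if cs.n_sites > 1:
        eff = {f"site{k + 1}": rng.normal(0, 0.1) for k in range(cs.n_sites)}
        site_eff = np.array([eff[s] for s in site])
    for s in config.structures:
        S = scores[s]
        Sz = (S - S.mean()) / (S.std(ddof=1) if S.std() > 0 else 1.0)
        slope = b_g * (1.0 + config.delta_gxe * ptsd) if s == "hippocampus" else b_g
        lp = (slope * Sz + 0.3 * icv_z - 0.15 * sex - 0.015 * age_c
              - 0.0002 * age_c**2 + 0.05 * pcs[:, 0] + 0.05 * pcs[:, 1] + site_eff)
        if s == "hippocampus" and spike_dosage is not None:
            lp = lp + config.spike_gxe_beta * spike_dosage * ptsd
        resid_var = max(0.2, 1.0 - float(np.var(lp)))
        eps = _residuals(n, family_id, config.twin_residual_rho if cs.twin else 0.0, rng)
        v_std = lp + math.sqrt(resid_var) * eps
        mu, sd = VOLUME_SCALE[s]
        raw = mu + sd * v_std
        d = rng.normal(0, 0.05 * sd, size=n)
        df[f"vol_left_{s}"] = raw + d
        df[f"vol_right_{s}"] = raw - d
        df[f"vol_mean_{s}"] = raw
    return df


def _residuals(n: int, family_id, rho: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.normal(size=n)
    if rho <= 0 or family_id is None:
        return z
    fam = pd.Series(family_id)
    shared = {f: rng.normal() for f in fam.dropna().unique()}
    zf = np.array([shared.get(f, rng.normal()) for f in fam])
    return math.sqrt(rho) * zf + math.sqrt(1.0 - rho) * z


def simulate_cohorts(config: SimConfig, geno: dict[str, GenotypeCohort],
                     truth: GroundTruth, rng: np.random.Generator
                     ) -> dict[str, pd.DataFrame]:
    """Phenotype tables for every cohort, driven by the true genetic scores.

    Standardized volume follows sqrt(h2_pgs) * S * (1 + delta_gxe * PTSD)
    plus ICV/sex/age/PC/site effects and residual noise scaled to unit total
    variance; PTSD is assigned by a logistic liability on the standardized
    true amygdala score.  Realized case/control score slopes are recorded in
    the ground truth.
    """
    phenos: dict[str, pd.DataFrame] = {}
    for cs in config.cohort_specs:
        g = geno[cs.cohort_id]
        true_full = np.where(np.isnan(g.dosage), 0.0, g.dosage)
        scores = {}
        for s in config.structures:
            S = true_full @ truth.true_weights[s]
            scores[s] = S
        family_id = None
        if cs.twin:
            family_id = np.array([f"{cs.cohort_id}_fam{(i // 2) + 1:04d}"
                                  for i in range(cs.n)], dtype=object)
        spike = None
        if config.spike_snp is not None:
            j = int(np.flatnonzero(g.variants["snp_id"] == config.spike_snp)[0])
            col = g.dosage[:, j]
            spike = np.where(np.isnan(col), np.nanmean(col), col)
        df = _phenotypes_from_scores(cs, scores, config, rng, family_id,
                                     list(g.subjects), spike_dosage=spike)
        truth.true_scores[cs.cohort_id] = scores
        truth.realized_slopes[cs.cohort_id] = _slopes(df, scores, config)
        phenos[cs.cohort_id] = df
    return phenos


def _slopes(df: pd.DataFrame, scores: dict[str, np.ndarray],
            config: SimConfig) -> dict[str, float]:
    if "hippocampus" not in scores:
        return {}
    v = df["vol_mean_hippocampus"].to_numpy()
    v = (v - v.mean()) / v.std(ddof=1)
    S = scores["hippocampus"]
    Sz = (S - S.mean()) / (S.std(ddof=1) if S.std() > 0 else 1.0)
    out = {}
    for label, mask in (("controls", df["ptsd"] == 0), ("cases", df["ptsd"] == 1)):
        if mask.sum() > 2 and Sz[mask].std() > 0:
            out[label] = float(np.polyfit(Sz[mask.to_numpy()], v[mask.to_numpy()], 1)[0])
        else:
            out[label] = float("nan")
    return out


# ---------------------------------------------------------------------------
# phenotype-level studies (no genotypes) for power/calibration work
# ---------------------------------------------------------------------------


def simulate_association_study(config: SimConfig, seed: int | None = None
                               ) -> list[Cohort]:
    """Draw cohorts with true scores sampled directly (no genotype layer).

    The phenotype model is identical to :func:`simulate_cohorts`; the true
    standardized scores appear as ``pgs_<structure>`` columns.  Twin pairs
    share their genetic scores and have residual correlation
    ``twin_residual_rho``.  Suited to calibration and parameter-recovery
    studies of the modelling and meta-analysis stages.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohorts = []
    for cs in config.cohort_specs:
        family_id = None
        if cs.twin:
            n_unique = (cs.n + 1) // 2
            reps = np.repeat(np.arange(n_unique), 2)[: cs.n]
            family_id = np.array([f"{cs.cohort_id}_fam{r + 1:04d}" for r in reps],
                                 dtype=object)
            scores = {s: rng.normal(size=n_unique)[reps] for s in config.structures}
        else:
            scores = {s: rng.normal(size=cs.n) for s in config.structures}
        subjects = [f"{cs.cohort_id}_{i + 1:05d}" for i in range(cs.n)]
        df = _phenotypes_from_scores(cs, scores, config, rng, family_id, subjects)
        for s in config.structures:
            df[f"pgs_{s}"] = scores[s]
        cohorts.append(Cohort(cohort_id=cs.cohort_id, pheno=df, n_pcs=cs.n_pcs,
                              twin=cs.twin, multi_site=cs.n_sites > 1))
    return cohorts


# ---------------------------------------------------------------------------
# one-call study assembly and fixture bundles
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig) -> tuple[Study, GroundTruth]:
    """Full pipeline input: panel, discovery sumstats, genotypes, phenotypes."""
    rng = np.random.default_rng(config.seed)
    panel = make_panel(config, rng)
    truth = simulate_truth(config, panel, rng)
    _, geno = simulate_genotypes(config, panel, rng)
    sumstats = {s: simulate_discovery_sumstats(config, panel, truth, rng, structure=s)
                for s in config.structures}
    phenos = simulate_cohorts(config, geno, truth, rng)
    cohorts = [Cohort(cohort_id=cs.cohort_id, pheno=phenos[cs.cohort_id],
                      geno=geno[cs.cohort_id], n_pcs=cs.n_pcs, twin=cs.twin,
                      multi_site=cs.n_sites > 1)
               for cs in config.cohort_specs]
    return Study(sumstats=sumstats, cohorts=cohorts), truth


def write_fixture_bundle(config: SimConfig, outdir: str | Path,
                         force: bool = False) -> dict[str, Path]:
    """Write a complete on-disk study: sumstats TSV, per-cohort VCF and
    phenotype TSV, ground-truth JSON and a cohort summary table."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is non-empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    study, truth = simulate_study(config)
    paths: dict[str, Path] = {}
    for s, ss in study.sumstats.items():
        p = outdir / f"sumstats_{s}.tsv"
        write_summary_stats(ss, p)
        paths[f"sumstats_{s}"] = p
    summary_rows = []
    for cohort in study.cohorts:
        pv = outdir / f"{cohort.cohort_id}.vcf"
        write_vcf(cohort.geno, pv)
        paths[f"vcf_{cohort.cohort_id}"] = pv
        pp = outdir / f"{cohort.cohort_id}_pheno.tsv"
        out = cohort.pheno.copy()
        out["sex"] = out["sex"].map({0: "M", 1: "F", 0.0: "M", 1.0: "F"})
        write_phenotypes(out, pp)
        paths[f"pheno_{cohort.cohort_id}"] = pp
        df = cohort.pheno
        summary_rows.append({
            "cohort": cohort.cohort_id, "n": len(df),
            "n_male": int((df["sex"] == 0).sum()),
            "mean_age": round(float(df["age"].mean()), 2),
            "n_ptsd": int(df["ptsd"].sum()),
            "n_child_trauma": int(df["child_trauma"].sum(skipna=True))
            if df["child_trauma"].notna().any() else None,
        })
    summary_rows.append({
        "cohort": "Total", "n": sum(r["n"] for r in summary_rows),
        "n_male": sum(r["n_male"] for r in summary_rows), "mean_age": np.nan,
        "n_ptsd": sum(r["n_ptsd"] for r in summary_rows),
        "n_child_trauma": np.nan})
    summary = pd.DataFrame(summary_rows)
    ps = outdir / "cohort_summary.tsv"
    summary.to_csv(ps, sep="\t", index=False)
    paths["cohort_summary"] = ps

    tj = outdir / "truth.json"
    tj.write_text(json.dumps({
        "config": _config_dict(config),
        "causal_snps": {s: truth.causal_snps[s].tolist() for s in truth.causal_snps},
        "true_weights": {s: truth.true_weights[s].tolist() for s in truth.true_weights},
        "realized_slopes": truth.realized_slopes,
    }, indent=1))
    paths["truth"] = tj
    return paths


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["structures"] = list(d["structures"])
    d["maf_range"] = list(d["maf_range"])
    return d
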