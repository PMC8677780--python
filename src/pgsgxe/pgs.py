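"""Clumping + thresholding polygenic score construction.

The score for subject *i* at threshold *t* is the weighted sum of
effect-allele dosages over LD-clumped index SNPs whose discovery p-value is
at or below *t*:

    PGS_i(t) = sum_{j : p_j <= t} w_j * d_ij

with ``w`` either discovery betas or Z scores.  Missing dosages are imputed
as twice the cohort effect-allele frequency, the behaviour of standard
scoring tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeCohort, SummaryStats, Variant

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class ThresholdGrid:
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if not (np.all(np.diff(t) > 0) and t[0] > 0 and t[-1] <= 1):
            raise ValueError("thresholds must be strictly increasing within (0, 1]")
        self.thresholds = t

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass
class ClumpResult:
    index_snps: list[Variant]
    removed: dict[str, str]  # snp_id -> absorbing index snp_id
    r2_threshold: float
    window_kb: int

    @property
    def index_ids(self) -> list[str]:
        return [v.snp_id for v in self.index_snps]


@dataclass
class PgsMatrix:
    """Subjects x thresholds score matrix for one structure/weighting."""

    cohort_id: str
    structure: str
    weight_kind: str
    subjects: list[str]
    grid: ThresholdGrid
    scores: np.ndarray
    n_snps_used: np.ndarray = field(default=None)  # type: ignore[assignment]

    def column(self, threshold: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.grid.thresholds - threshold)))
        if abs(self.grid.thresholds[j] - threshold) > 1e-9:
            raise KeyError(f"threshold {threshold} not on the grid")
        return self.scores[:, j]

    def column_aligned(self, threshold: float, subject_ids) -> np.ndarray:
        """Scores at one threshold reordered to ``subject_ids`` (NaN absent)."""
        col = self.column(threshold)
        idx = {s: i for i, s in enumerate(self.subjects)}
        return np.array([col[idx[s]] if s in idx else np.nan for s in subject_ids])


def hard_call(genotype_prob: np.ndarray, certainty: float = 0.8) -> np.ndarray:
    """Convert (p0, p1, p2) triples to 0/1/2 calls, NaN below ``certainty``.

    The default 0.8 keeps a genotype only when the most likely class carries
    at least 80% posterior probability.
    """
    gp = np.asarray(genotype_prob, dtype=float)
    if gp.shape[-1] != 3:
        raise ValueError("genotype_prob must have a trailing dimension of 3")
    if np.nanmin(gp) < 0:
        raise ValueError("negative genotype probability")
    sums = gp.sum(axis=-1)
    ok_sum = np.isclose(sums, 1.0, atol=1e-6) | np.isnan(sums)
    if not ok_sum.all():
        raise ValueError("genotype probabilities must sum to 1 within 1e-6")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        best = np.nanmax(gp, axis=-1)
    call = np.argmax(np.nan_to_num(gp, nan=-1.0), axis=-1).astype(float)
    call[~(best >= certainty)] = np.nan
    call[np.isnan(sums)] = np.nan
    return call


def snp_qc(cohort: GenotypeCohort, maf_min: float = 0.05,
           miss_max: float = 0.05) -> GenotypeCohort:
    """Drop SNPs with MAF < ``maf_min`` or missingness > ``miss_max``.

    Boundary values are retained: the exclusions are strict, mirroring a
    "greater than 5% missing / less than 5% MAF" rule.
    """
    keep = (cohort.maf >= maf_min) & (cohort.missing_rate <= miss_max)
    n_kept = int(keep.sum())
    logger.info("snp_qc[%s]: retained %d/%d SNPs (maf>=%.3g, miss<=%.3g)",
                cohort.cohort_id, n_kept, cohort.n_variants, maf_min, miss_max)
    if n_kept == 0:
        logger.warning("snp_qc[%s]: no SNPs survive QC", cohort.cohort_id)
    return cohort.subset_variants(keep)


def filter_subsample_n(ss: SummaryStats, frac: float = 0.8) -> SummaryStats:
    """Drop variants whose GWAS N falls below ``frac`` of the maximum N.

    Mirrors the exclusion of SNPs analysed in less than 80% of the maximum
    discovery sample; the boundary (exactly 80%) is retained.
    """
    n_max = ss.n_max
    keep = ss.table["n_eff"] >= frac * n_max
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_subsample_n: dropped %d/%d variants below %.0f%% of N=%d",
                    dropped, len(keep), 100 * frac, n_max)
    return SummaryStats(table=ss.table[keep], weight_kind=ss.weight_kind,
                        n_dropped=ss.n_dropped + dropped)


def align_alleles(ss: SummaryStats, cohort: GenotypeCohort
                  ) -> tuple[SummaryStats, GenotypeCohort]:
    """Harmonise summary statistics and cohort genotypes on allele identity.

    Matching is on snp_id.  Swapped alleles flip the weight sign (one fixed
    convention); strand flips are complemented then re-matched; palindromic
    (A/T, C/G) SNPs and irreconcilable allele pairs are dropped.  Returns the
    harmonised pair restricted to the shared variants, cohort-ordered.
    """
    st = ss.table.set_index("snp_id")
    cv = cohort.variants
    keep_idx: list[int] = []
    weights_sign: list[float] = []
    rows: list[str] = []
    n_pal = n_mismatch = n_absent = 0
    for j, r in enumerate(cv.itertuples()):
        if r.snp_id not in st.index:
            n_absent += 1
            continue
        s = st.loc[r.snp_id]
        a1, a2 = s["effect_allele"], s["other_allele"]
        if (a1, a2) in _PALINDROMIC:
            n_pal += 1
            continue
        ca1, ca2 = r.effect_allele, r.other_allele
        if (ca1, ca2) in _PALINDROMIC:
            n_pal += 1
            continue
        sign = _match_alleles(a1, a2, ca1, ca2)
        if sign == 0:
            n_mismatch += 1
            continue
        keep_idx.append(j)
        weights_sign.append(sign)
        rows.append(r.snp_id)
    logger.info("align_alleles[%s]: matched %d; dropped %d palindromic, %d mismatched, "
                "%d absent from sumstats", cohort.cohort_id, len(rows), n_pal,
                n_mismatch, n_absent)
    sub = cohort.subset_variants(np.array(keep_idx, dtype=int))
    st2 = st.loc[rows].reset_index()
    sign_arr = np.array(weights_sign)
    # adopt the cohort's allele orientation: flip weight sign where swapped
    st2["weight"] = st2["weight"].to_numpy() * sign_arr
    flip = sign_arr < 0
    ea = st2["effect_allele"].to_numpy().copy()
    oa = st2["other_allele"].to_numpy().copy()
    st2.loc[flip, "effect_allele"] = oa[flip]
    st2.loc[flip, "other_allele"] = ea[flip]
    # after strand complementation the stored alleles follow the cohort
    st2["effect_allele"] = sub.variants["effect_allele"].to_numpy()
    st2["other_allele"] = sub.variants["other_allele"].to_numpy()
    out = SummaryStats(table=st2[ss.table.columns], weight_kind=ss.weight_kind,
                       n_dropped=ss.n_dropped + n_pal + n_mismatch)
    return out, sub


def _match_alleles(a1: str, a2: str, ca1: str, ca2: str) -> float:
    """Return +1 (same orientation), -1 (swapped) or 0 (irreconcilable)."""
    if (a1, a2) == (ca1, ca2):
        return 1.0
    if (a1, a2) == (ca2, ca1):
        return -1.0
    f1, f2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
    if (f1, f2) == (ca1, ca2):
        return 1.0
    if (f1, f2) == (ca2, ca1):
        return -1.0
    return 0.0


def ld_clump(ss: SummaryStats, cohort: GenotypeCohort, r2_threshold: float = 0.1,
             window_kb: int = 250) -> ClumpResult:
    """Greedy LD clumping on genotype-estimated r².

    SNPs are visited in ascending discovery p-value (ties by chrom, pos);
    each becomes an index unless it sits within ``window_kb`` of an existing
    index on the same chromosome with pairwise-complete dosage r² at or above
    ``r2_threshold``, in which case it is absorbed by the most correlated
    such index.
    """
    st = ss.table
    cohort_ids = {s: j for j, s in enumerate(cohort.variants["snp_id"])}
    order = st.sort_values(["pval", "chrom", "pos"], kind="mergesort").index
    window = window_kb * 1000

    index_snps: list[Variant] = []
    index_by_chrom: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(pos, col)]
    index_variants_rows: list[pd.Series] = []
    removed: dict[str, str] = {}
    D = cohort.dosage
    for i in order:
        r = st.loc[i]
        if r["snp_id"] not in cohort_ids:
            logger.info("ld_clump: %s absent from cohort %s, skipped",
                        r["snp_id"], cohort.cohort_id)
            continue
        col = cohort_ids[r["snp_id"]]
        chrom, pos = str(r["chrom"]), int(r["pos"])
        absorbed_by, best_r2 = None, -1.0
        for ipos, icol, iid in index_by_chrom.get(chrom, []):
            if abs(ipos - pos) <= window:
                r2 = _pairwise_r2(D[:, col], D[:, icol])
                if r2 >= r2_threshold and r2 > best_r2:
                    absorbed_by, best_r2 = iid, r2
        if absorbed_by is None:
            index_snps.append(Variant(r["snp_id"], chrom, pos,
                                      r["effect_allele"], r["other_allele"]))
            index_by_chrom.setdefault(chrom, []).append((pos, col, r["snp_id"]))
        else:
            removed[r["snp_id"]] = absorbed_by
    return ClumpResult(index_snps=index_snps, removed=removed,
                       r2_threshold=r2_threshold, window_kb=window_kb)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1] ** 2)


def build_threshold_grid() -> ThresholdGrid:
    """The 1,001-point p-value threshold grid: 0.0001 step 0.001, plus 1.0."""
    t = 0.0001 + 0.001 * np.arange(1000)
    return ThresholdGrid(np.append(t, 1.0))


def compute_pgs(cohort: GenotypeCohort, ss: SummaryStats, clump: ClumpResult,
                grid: ThresholdGrid, structure: str = "hippocampus") -> PgsMatrix:
    """Score the cohort at every grid threshold over the clumped index SNPs.

    Threshold inclusion is ``pval <= t``.  Missing dosages are imputed as
    2 x effect-allele frequency among non-missing genotypes.
    """
    st = ss.table.set_index("snp_id")
    ids = [v.snp_id for v in clump.index_snps if v.snp_id in st.index]
    cohort_ids = {s: j for j, s in enumerate(cohort.variants["snp_id"])}
    ids = [s for s in ids if s in cohort_ids]
    if not ids:
        logger.warning("compute_pgs[%s]: no index SNPs available; scores are 0",
                       cohort.cohort_id)
        z = np.zeros((cohort.n_subjects, len(grid)))
        return PgsMatrix(cohort.cohort_id, structure, ss.weight_kind,
                         list(cohort.subjects), grid, z, np.zeros(len(grid), int))
    cols = np.array([cohort_ids[s] for s in ids])
    w = st.loc[ids, "weight"].to_numpy(dtype=float)
    p = st.loc[ids, "pval"].to_numpy(dtype=float)

    D = cohort.dosage[:, cols]
    eaf = np.nanmean(D, axis=0) / 2.0
    eaf = np.nan_to_num(eaf, nan=0.0)
    fill = np.where(np.isnan(D), 2.0 * eaf[None, :], D)

    order = np.argsort(p, kind="mergesort")
    contrib = fill[:, order] * w[order][None, :]
    cum = np.cumsum(contrib, axis=1)
    p_sorted = p[order]
    counts = np.searchsorted(p_sorted, grid.thresholds, side="right")
    scores = np.zeros((cohort.n_subjects, len(grid)))
    nz = counts > 0
    scores[:, nz] = cum[:, counts[nz] - 1]
    if not nz.all():
        logger.warning("compute_pgs[%s]: zero SNPs pass the smallest threshold(s)",
                       cohort.cohort_id)
    return PgsMatrix(cohort.cohort_id, structure, ss.weight_kind,
                     list(cohort.subjects), grid, scores, counts.astype(int))


def hard_call_cohort(cohort: GenotypeCohort, certainty: float = 0.8) -> GenotypeCohort:
    """Apply :func:`hard_call` to a cohort carrying genotype probabilities."""
    if cohort.genotype_prob is None:
        return cohort
    calls = hard_call(cohort.genotype_prob, certainty=certainty)
    return GenotypeCohort(cohort_id=cohort.cohort_id, subjects=list(cohort.subjects),
                          variants=cohort.variants.copy(), dosage=calls,
                          genotype_prob=cohort.genotype_prob)
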