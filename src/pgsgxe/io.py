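"""Readers, writers and the canonical in-memory data model.

All coordinates are 1-based (VCF convention); chromosomes are strings.
Genotypes live in a subjects x variants dosage matrix (additive count of the
effect allele, ``NaN`` = missing).  Phenotype/covariate tables are plain
pandas DataFrames with a documented column schema (see :data:`PHENO_COLUMNS`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the seven bilateral subcortical structures modelled throughout
STRUCTURES = (
    "accumbens",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)

VALID_ALLELES = frozenset("ACGT")

#: per-subject phenotype/covariate schema; vol_* columns repeat per structure,
#: principal components are ``pc1..pcK``.
PHENO_COLUMNS = (
    "subject_id",
    "family_id",
    "cohort_id",
    "site_id",
    "icv",
    "age",
    "sex",  # 0 = male, 1 = female (internal convention)
    "ptsd",
    "child_trauma",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP keyed by rs-id with an explicit effect allele."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")


VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]


@dataclass
class SummaryStats:
    """Discovery GWAS rows that seed PGS construction.

    ``table`` columns: snp_id, chrom, pos, effect_allele, other_allele,
    weight, se, pval, n_eff.  ``weight`` is a per-allele beta on the
    SD-volume scale, or a Z score (``weight_kind``).
    """

    table: pd.DataFrame
    weight_kind: str  # "beta" | "zscore"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.weight_kind not in ("beta", "zscore"):
            raise ValueError(f"unknown weight_kind {self.weight_kind!r}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_max(self) -> int:
        return int(self.table["n_eff"].max())

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def variants(self) -> list[Variant]:
        return [
            Variant(r.snp_id, str(r.chrom), int(r.pos), r.effect_allele, r.other_allele)
            for r in self.table.itertuples()
        ]


@dataclass
class GenotypeCohort:
    """Subjects x SNPs dosage matrix plus variant metadata for one cohort.

    ``dosage[i, j]`` is the count of ``variants.effect_allele[j]`` carried by
    subject ``i`` (0-2, possibly fractional for imputed dosages, NaN missing).
    ``genotype_prob`` holds (p0, p1, p2) triples when imputation probabilities
    are available.  ``maf``/``missing_rate`` are per-variant and always match
    what a recomputation from ``dosage`` yields.
    """

    cohort_id: str
    subjects: list[str]
    variants: pd.DataFrame  # VARIANT_COLUMNS
    dosage: np.ndarray
    genotype_prob: np.ndarray | None = None
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    missing_rate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError("dosage shape does not match subjects x variants")
        with np.errstate(invalid="ignore"):
            bad = np.nan_to_num(self.dosage, nan=1.0)
            if (bad < 0).any() or (bad > 2).any():
                raise ValueError("dosages must lie in [0, 2] or be missing")
        if self.maf is None or self.missing_rate is None:
            self.maf, self.missing_rate = self.compute_maf_missing()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency among non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def compute_maf_missing(self) -> tuple[np.ndarray, np.ndarray]:
        eaf = self.effect_allele_freq()
        maf = np.minimum(eaf, 1.0 - eaf)
        missing = np.isnan(self.dosage).mean(axis=0)
        return maf, missing

    def subset_variants(self, mask: np.ndarray) -> "GenotypeCohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeCohort(
            cohort_id=self.cohort_id,
            subjects=list(self.subjects),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            genotype_prob=None if self.genotype_prob is None else self.genotype_prob[:, idx, :],
            maf=self.maf[idx],
            missing_rate=self.missing_rate[idx],
        )

    def subset_subjects(self, keep: Sequence[str]) -> "GenotypeCohort":
        index = {s: i for i, s in enumerate(self.subjects)}
        idx = np.array([index[s] for s in keep], dtype=int)
        return GenotypeCohort(
            cohort_id=self.cohort_id,
            subjects=list(keep),
            variants=self.variants.copy(),
            dosage=self.dosage[idx],
            genotype_prob=None if self.genotype_prob is None else self.genotype_prob[idx],
        )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_SUMSTAT_REQUIRED = {"SNP", "CHR", "BP", "A1", "A2", "P", "N"}


def read_summary_stats(path: str | Path, weight_kind: str) -> SummaryStats:
    """Read whitespace/tab-delimited GWAS summary statistics.

    Expected header: SNP CHR BP A1 A2 BETA|Z SE P N (SE optional for
    Z-score weights).  Rows with non-ACGT alleles or p-values outside (0, 1]
    are dropped and counted in ``n_dropped``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    weight_col = "BETA" if weight_kind == "beta" else "Z"
    required = _SUMSTAT_REQUIRED | {weight_col}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")

    n0 = len(df)
    a1 = df["A1"].astype(str).str.upper()
    a2 = df["A2"].astype(str).str.upper()
    ok = (
        a1.isin(VALID_ALLELES)
        & a2.isin(VALID_ALLELES)
        & (a1 != a2)
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & np.isfinite(df[weight_col])
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.info("read_summary_stats: dropped %d/%d invalid rows from %s", dropped, n0, path)
    df = df[ok]

    table = pd.DataFrame(
        {
            "snp_id": df["SNP"].astype(str),
            "chrom": df["CHR"].astype(str),
            "pos": df["BP"].astype(int),
            "effect_allele": a1[ok],
            "other_allele": a2[ok],
            "weight": df[weight_col].astype(float),
            "se": df["SE"].astype(float) if "SE" in df.columns else np.nan,
            "pval": df["P"].astype(float),
            "n_eff": df["N"].astype(int),
        }
    )
    return SummaryStats(table=table, weight_kind=weight_kind, n_dropped=dropped)


def write_summary_stats(ss: SummaryStats, path: str | Path) -> None:
    t = ss.table
    out = pd.DataFrame(
        {
            "SNP": t["snp_id"],
            "CHR": t["chrom"],
            "BP": t["pos"],
            "A1": t["effect_allele"],
            "A2": t["other_allele"],
            ("BETA" if ss.weight_kind == "beta" else "Z"): t["weight"],
            "SE": t["se"],
            "P": t["pval"],
            "N": t["n_eff"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str, cohort_id: str | None = None) -> GenotypeCohort:
    """Load a genotype cohort from VCF (GT/GP/DS) or PLINK ``.traw`` text.

    For VCF the ALT allele is the effect allele.  Per record the dosage
    source is, in order of preference, DS, GP (expected count p1 + 2 p2),
    then GT.  Multi-allelic records are dropped with a log line.
    """
    path = Path(path)
    if cohort_id is None:
        cohort_id = path.stem.split(".")[0]
    if format == "vcf":
        return _read_vcf(path, cohort_id)
    if format == "plink_traw":
        return _read_traw(path, cohort_id)
    raise FormatError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, cohort_id: str) -> GenotypeCohort:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, dosages, probs = [], [], []
    any_gp = False
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        ds = _vcf_field(rec, "DS")
        gp = _vcf_field(rec, "GP")
        if ds is not None:
            d = ds.astype(float).reshape(-1)
        elif gp is not None:
            g = gp.astype(float)
            d = g[:, 1] + 2.0 * g[:, 2]
        else:
            gts = rec.genotype.array()
            if gts is None:
                raise FormatError(f"{path}: record {rec.ID} has no GT, DS or GP")
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            d = alleles.sum(axis=1)
        if gp is not None:
            any_gp = True
            probs.append(gp.astype(float))
        else:
            probs.append(np.full((len(subjects), 3), np.nan))
        dosages.append(d)
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", str(rec.CHROM), int(rec.POS), alt, ref))
    if n_multi:
        logger.info("read_genotypes: dropped %d multi-allelic records from %s", n_multi, path)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.vstack(dosages).T if dosages else np.empty((len(subjects), 0))
    gp_arr = np.stack(probs, axis=1) if (probs and any_gp) else None
    return GenotypeCohort(cohort_id=cohort_id, subjects=subjects, variants=variants,
                          dosage=dosage, genotype_prob=gp_arr)


def _vcf_field(rec, key: str):
    try:
        val = rec.format(key)
    except KeyError:
        return None
    return val


def _read_traw(path: Path, cohort_id: str) -> GenotypeCohort:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing traw column(s) {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    variants = pd.DataFrame(
        {
            "snp_id": df["SNP"].astype(str),
            "chrom": df["CHR"].astype(str),
            "pos": df["POS"].astype(int),
            "effect_allele": df["COUNTED"].astype(str),
            "other_allele": df["ALT"].astype(str),
        }
    )
    dosage = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeCohort(cohort_id=cohort_id, subjects=sample_cols, variants=variants,
                          dosage=dosage)


def write_traw(cohort: GenotypeCohort, path: str | Path) -> None:
    v = cohort.variants
    out = pd.DataFrame(
        {
            "CHR": v["chrom"],
            "SNP": v["snp_id"],
            "(C)M": 0,
            "POS": v["pos"],
            "COUNTED": v["effect_allele"],
            "ALT": v["other_allele"],
        }
    )
    for i, s in enumerate(cohort.subjects):
        out[s] = cohort.dosage[i]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def write_vcf(cohort: GenotypeCohort, path: str | Path) -> None:
    """Write an uncompressed VCF 4.2 with DS (and GP when available).

    The effect allele is emitted as ALT so a round-trip through
    :func:`read_genotypes` preserves the dosage orientation.
    """
    v = cohort.variants
    has_gp = cohort.genotype_prob is not None
    fmt = "GT:DS:GP" if has_gp else "GT:DS"
    order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT">\n')
        if has_gp:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">\n')
        for chrom in pd.unique(v["chrom"].to_numpy()[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.subjects) + "\n")
        for j in order:
            row = v.iloc[j]
            fields = [str(row.chrom), str(row.pos), row.snp_id, row.other_allele,
                      row.effect_allele, ".", "PASS", ".", fmt]
            for i in range(cohort.n_subjects):
                d = cohort.dosage[i, j]
                if np.isnan(d):
                    gt, ds = "./.", "."
                else:
                    k = int(round(d)) if abs(d - round(d)) < 1e-9 else None
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(k, "./.")
                    ds = f"{d:.6g}"
                cell = f"{gt}:{ds}"
                if has_gp:
                    p = cohort.genotype_prob[i, j]
                    cell += ":" + ",".join("." if np.isnan(x) else f"{x:.6g}" for x in p)
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path, sex_map: dict | None = None) -> pd.DataFrame:
    """Read a delimited phenotype/covariate table into the canonical schema.

    ``sex_map`` maps file-level sex codes to the internal convention
    (0 = male, 1 = female); defaults to ``{"M": 0, "F": 1, 1: 0, 2: 1}``.
    Missing ``child_trauma`` and per-structure volumes are allowed.
    """
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate subject_id {dup!r}")
    if sex_map is None:
        sex_map = {"M": 0, "F": 1, 0: 0, 1: 1, "0": 0, "1": 1}
    df["sex"] = df["sex"].map(lambda x: sex_map.get(x, sex_map.get(str(x))))
    if df["sex"].isna().any():
        raise FormatError(f"{path}: sex codes not covered by the configured map")
    df["subject_id"] = df["subject_id"].astype(str)
    return average_bilateral(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.drop(columns=[c for c in df.columns if c.startswith("vol_flag_")],
                  errors="ignore")
    sep = "," if str(path).endswith(".csv") else "\t"
    out.to_csv(path, sep=sep, index=False, float_format="%.10g")


def average_bilateral(df: pd.DataFrame, structures: Iterable[str] = STRUCTURES) -> pd.DataFrame:
    """Fill ``vol_mean_<s>`` with the left/right average per structure.

    One-sided records get the available side and a flag; records missing both
    sides get a null mean and a flag.  Flags live in ``vol_flag_<s>`` with
    values both / left_only / right_only / missing.
    """
    df = df.copy()
    for s in structures:
        lcol, rcol = f"vol_left_{s}", f"vol_right_{s}"
        if lcol not in df.columns and rcol not in df.columns:
            continue
        left = df.get(lcol, pd.Series(np.nan, index=df.index)).astype(float)
        right = df.get(rcol, pd.Series(np.nan, index=df.index)).astype(float)
        mean = (left + right) / 2.0
        mean = mean.where(~(left.isna() & ~right.isna()), right)
        mean = mean.where(~(right.isna() & ~left.isna()), left)
        df[f"vol_mean_{s}"] = mean
        flag = pd.Series("both", index=df.index)
        flag[left.isna() & ~right.isna()] = "right_only"
        flag[right.isna() & ~left.isna()] = "left_only"
        flag[left.isna() & right.isna()] = "missing"
        df[f"vol_flag_{s}"] = flag
    return df


def pc_columns(df: pd.DataFrame, n_pcs: int) -> list[str]:
    cols = [f"pc{i}" for i in range(1, n_pcs + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table lacks principal components {missing}")
    return cols
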