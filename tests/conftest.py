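import numpy as np
import pandas as pd
import pytest

from pgsgxe.io import GenotypeCohort, SummaryStats, VARIANT_COLUMNS


def make_variants(n, chrom="1", spacing=10_000, start=1_000_000):
    rows = [(f"rs{i + 1}", chrom, start + i * spacing, "A", "G") for i in range(n)]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def make_cohort(dosage, variants=None, cohort_id="TEST", subjects=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if variants is None:
        variants = make_variants(m)
    if subjects is None:
        subjects = [f"s{i + 1}" for i in range(n)]
    return GenotypeCohort(cohort_id=cohort_id, subjects=subjects,
                          variants=variants, dosage=dosage)


def make_sumstats(variants, weight=None, pval=None, n_eff=None,
                  weight_kind="beta"):
    m = len(variants)
    table = variants.copy()
    table["weight"] = np.ones(m) if weight is None else np.asarray(weight, float)
    table["se"] = 0.1
    table["pval"] = np.full(m, 0.5) if pval is None else np.asarray(pval, float)
    table["n_eff"] = np.full(m, 1000) if n_eff is None else np.asarray(n_eff, int)
    return SummaryStats(table=table, weight_kind=weight_kind)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_pheno(n, rng, cohort_id="TEST", structure="hippocampus",
               n_pcs=10, prev=0.4, family_pairs=False, all_male=False):
    """Random but well-conditioned phenotype table for model tests."""
    df = pd.DataFrame({
        "subject_id": [f"s{i + 1}" for i in range(n)],
        "family_id": ([f"fam{i // 2 + 1}" for i in range(n)] if family_pairs
                      else [None] * n),
        "cohort_id": cohort_id,
        "site_id": None,
        "icv": rng.normal(1.5e6, 1.5e5, n),
        "age": rng.uniform(20, 70, n),
        "sex": np.zeros(n) if all_male else rng.integers(0, 2, n).astype(float),
        "ptsd": (rng.random(n) < prev).astype(int),
        "child_trauma": (rng.random(n) < 0.3).astype(float),
    })
    for i in range(n_pcs):
        df[f"pc{i + 1}"] = rng.normal(size=n)
    df[f"vol_mean_{structure}"] = rng.normal(4200, 400, n)
    return df
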