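"""Per-cohort association models.

Stage-1-style linear models of standardized subcortical volume on
standardized PGS (covariates: ICV, sex, age, age^2, ancestry PCs, optional
site dummies), Stage-2 logistic models of PTSD on PGS, and Stage-3
interaction models adding an environment main effect and its product with
the PGS.  Twin/family structure is handled either by family-clustered
sandwich standard errors (point estimates unchanged) or by dropping one twin
per family, prioritising PTSD cases.

All p-values are two-sided Wald (normal) so that per-cohort estimates feed
directly into the inverse-variance meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import pc_columns

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """Raised when the design matrix is rank deficient or an input constant."""


@dataclass
class ModelSpec:
    outcome: str = "volume"  # "volume" | "ptsd"
    structure: str = "hippocampus"
    predictor: str = "pgs"  # "pgs" | "snp"
    interaction_with: str = "none"  # "none" | "ptsd" | "child_trauma"
    n_pcs: int = 4
    include_site_dummies: bool = False
    family_mode: str = "independent"  # independent | drop_one_per_family | cluster_robust

    def __post_init__(self) -> None:
        if self.interaction_with == "ptsd" and self.outcome != "volume":
            raise ValueError("a PGSxPTSD interaction requires a volume outcome")


@dataclass
class AssocEstimate:
    cohort_id: str
    term: str
    beta: float
    se: float
    pval: float
    n: int
    or_: float | None = None
    flag: str | None = None

    @property
    def z(self) -> float:
        return self.beta / self.se


def wald_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def standardize(values, name: str = "value", index=None) -> np.ndarray:
    """Center/scale to mean 0, sample SD 1 (ddof=1); NaN passes through."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2 or np.nanstd(x[ok], ddof=1) == 0:
        raise DegenerateDesignError(f"cannot standardize constant column {name!r}")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / x[ok].std(ddof=1)
    return out


def _design_covariates(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Stage-1 covariate block: ICV, sex, centered age, age^2, PCs, sites."""
    X = pd.DataFrame(index=df.index)
    X["icv"] = standardize(df["icv"], "icv")
    if df["sex"].nunique() > 1:
        X["sex"] = df["sex"].astype(float)
    else:
        logger.info("sex covariate omitted (single-valued cohort)")
    age_c = df["age"].astype(float) - df["age"].astype(float).mean()
    X["age"] = age_c
    X["age2"] = age_c**2
    for c in pc_columns(df, spec.n_pcs):
        X[c] = df[c].astype(float)
    if spec.include_site_dummies and "site_id" in df.columns and df["site_id"].nunique() > 1:
        dummies = pd.get_dummies(df["site_id"].astype(str), prefix="site",
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for c in X.columns:
            sub = X.drop(columns=[c]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(c)
        raise DegenerateDesignError(f"rank-deficient design; collinear columns: {bad}")


def _volume_design(df: pd.DataFrame, pgs: np.ndarray | str, spec: ModelSpec
                   ) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame, str | None]:
    """Assemble (y, X, work, interaction_term) for a Stage-1/3 volume model."""
    g = df[pgs].to_numpy(dtype=float) if isinstance(pgs, str) else np.asarray(pgs, float)
    y_raw = df[f"vol_mean_{spec.structure}"].astype(float)

    work = df.copy()
    work["_pgs_raw"] = g
    work["_y_raw"] = y_raw
    env_col = None
    if spec.interaction_with != "none":
        env_col = spec.interaction_with
        work = work[work[env_col].notna()]
    needed = ["_pgs_raw", "_y_raw", "icv", "age", "sex"] + pc_columns(df, spec.n_pcs)
    work = work.dropna(subset=needed)

    y = standardize(work["_y_raw"], f"vol_mean_{spec.structure}")
    X = _design_covariates(work, spec)
    X.insert(0, "PGS", standardize(work["_pgs_raw"], "pgs"))
    term_int = None
    if env_col is not None:
        e = work[env_col].to_numpy(dtype=float)
        if np.unique(e).size < 2:
            raise DegenerateDesignError(f"environment {env_col!r} is constant")
        label = "PTSD" if env_col == "ptsd" else "CT"
        term_int = f"PGSx{label}"
        X[label] = e
        X[term_int] = X["PGS"].to_numpy() * e
    X = sm.add_constant(X)
    return y, X, work, term_int


def fit_volume_model(df: pd.DataFrame, pgs: np.ndarray | str,
                     spec: ModelSpec) -> dict[str, AssocEstimate]:
    """OLS of standardized volume on standardized PGS plus covariates.

    With ``spec.interaction_with`` set, the environment main effect (0/1) and
    the PGS x E product enter the model and the interaction estimate is
    returned under the term ``"PGSxPTSD"`` / ``"PGSxCT"``.
    Returns a dict keyed by term ("PGS" always present).
    """
    cohort_id = str(df["cohort_id"].iloc[0]) if "cohort_id" in df.columns else ""
    y, X, work, term_int = _volume_design(df, pgs, spec)
    n = len(work)
    _check_rank(X)

    model = sm.OLS(y, X)
    if spec.family_mode == "cluster_robust":
        groups = work["family_id"].fillna(work["subject_id"]).to_numpy()
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        res = model.fit()

    out: dict[str, AssocEstimate] = {}
    for term in ["PGS"] + ([term_int] if term_int else []):
        b, s = float(res.params[term]), float(res.bse[term])
        out[term] = AssocEstimate(cohort_id, term, b, s, wald_p(b, s), n)
    return out


def fit_ptsd_model(df: pd.DataFrame, pgs: np.ndarray | str,
                   spec: ModelSpec) -> AssocEstimate:
    """Logistic regression of PTSD diagnosis on standardized PGS + age, sex.

    Returns the PGS estimate on the log-odds scale with ``or_ = exp(beta)``.
    Complete separation is flagged and the estimate withheld (NaN fields).
    """
    cohort_id = str(df["cohort_id"].iloc[0]) if "cohort_id" in df.columns else ""
    g = df[pgs].to_numpy(dtype=float) if isinstance(pgs, str) else np.asarray(pgs, float)
    work = df.copy()
    work["_pgs_raw"] = g
    work = work.dropna(subset=["_pgs_raw", "ptsd", "age", "sex"])
    n = len(work)

    X = pd.DataFrame(index=work.index)
    X["PGS"] = standardize(work["_pgs_raw"], "pgs")
    if work["age"].nunique() > 1:  # constant covariates are auto-omitted
        X["age"] = work["age"].astype(float) - work["age"].astype(float).mean()
    if work["sex"].nunique() > 1:
        X["sex"] = work["sex"].astype(float)
    X = sm.add_constant(X)
    y = work["ptsd"].astype(float)
    try:
        model = sm.Logit(y, X)
        if spec.family_mode == "cluster_robust":
            groups = work["family_id"].fillna(work["subject_id"]).to_numpy()
            res = model.fit(disp=False, maxiter=100, cov_type="cluster",
                            cov_kwds={"groups": groups})
        else:
            res = model.fit(disp=False, maxiter=100)
        separated = (not res.mle_retvals.get("converged", True)) or \
            np.abs(res.params["PGS"]) > 20
    except Exception:  # statsmodels raises PerfectSeparationError and kin
        separated = True
        res = None
    if separated:
        logger.warning("fit_ptsd_model[%s]: separation detected, estimate withheld",
                       cohort_id)
        return AssocEstimate(cohort_id, "PGS->PTSD", np.nan, np.nan, np.nan, n,
                             or_=np.nan, flag="separation")
    b, s = float(res.params["PGS"]), float(res.bse["PGS"])
    return AssocEstimate(cohort_id, "PGS->PTSD", b, s, wald_p(b, s), n,
                         or_=float(np.exp(b)))


def family_adjust(df: pd.DataFrame, mode: str, seed: int | None = None) -> pd.DataFrame:
    """Prepare a cohort table for family/twin structure.

    ``cluster_robust`` is a no-op here (the fitters handle the sandwich);
    ``drop_one_per_family`` keeps one member per family: the PTSD case when
    exactly one is present, otherwise a seeded uniform pick (among cases when
    several, among all members when none).
    """
    if mode in ("independent", "cluster_robust"):
        return df
    if mode != "drop_one_per_family":
        raise ValueError(f"unknown family_mode {mode!r}")
    rng = np.random.default_rng(seed)
    keep_idx: list = []
    fam = df["family_id"].fillna(df["subject_id"])
    for _, grp in df.groupby(fam, sort=True):
        if len(grp) == 1:
            keep_idx.append(grp.index[0])
            continue
        cases = grp[grp["ptsd"] == 1]
        pool = cases if len(cases) >= 1 else grp
        if len(pool) == 1:
            keep_idx.append(pool.index[0])
        else:
            keep_idx.append(pool.index[rng.integers(len(pool))])
    out = df.loc[sorted(keep_idx)]
    logger.info("drop_one_per_family: kept %d of %d subjects", len(out), len(df))
    return out


def make_spec_for_cohort(cohort_id: str, n_pcs: int = 4, twin: bool = False,
                         multi_site: bool = False, **kw) -> ModelSpec:
    """Convenience constructor applying the per-cohort modelling conventions."""
    return ModelSpec(n_pcs=n_pcs, include_site_dummies=multi_site,
                     family_mode="cluster_robust" if twin else "independent", **kw)
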