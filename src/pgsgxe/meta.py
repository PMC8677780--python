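"""Random-effects meta-analysis and threshold-grid bookkeeping.

Pooling uses the DerSimonian-Laird moment estimator of the between-cohort
variance tau^2: with fixed-effect weights w_i = 1/se_i^2 and Cochran's

    Q = sum_i w_i (b_i - b_FE)^2,
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),

the pooled effect is the tau^2-inflated inverse-variance average with
w*_i = 1/(se_i^2 + tau^2), se_pooled = (sum w*)^(-1/2), and a two-sided
normal (Wald) p-value.  I^2 = max(0, (Q - (k-1))/Q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import AssocEstimate
from .pgs import ThresholdGrid

logger = logging.getLogger(__name__)


@dataclass
class MetaEstimate:
    term: str
    beta_pooled: float
    se_pooled: float
    pval: float
    tau2: float
    q_stat: float
    i2: float
    k: int
    per_cohort: list[AssocEstimate] = field(default_factory=list)

    @property
    def z(self) -> float:
        return self.beta_pooled / self.se_pooled


@dataclass
class GridScan:
    structure: str
    weight_kind: str
    grid: ThresholdGrid
    per_threshold: list[MetaEstimate]
    best_threshold: float
    local_peaks: list[float]

    def best(self) -> MetaEstimate:
        j = int(np.argmin(np.abs(self.grid.thresholds - self.best_threshold)))
        return self.per_threshold[j]

    def top_peaks(self, n: int = 5) -> list[float]:
        """The ``n`` most significant local-peak thresholds, ascending order."""
        z = {t: abs(self.per_threshold[j].z)
             for j, t in enumerate(self.grid.thresholds) if t in self.local_peaks}
        best = sorted(self.local_peaks, key=lambda t: -z[t])[:n]
        return sorted(best)


def dl_meta(estimates: list[AssocEstimate], term: str | None = None) -> MetaEstimate:
    """DerSimonian-Laird random-effects pooling of per-cohort estimates."""
    est = [e for e in estimates if np.isfinite(e.beta) and np.isfinite(e.se)]
    if not est:
        raise ValueError("dl_meta requires at least one finite estimate")
    b = np.array([e.beta for e in est])
    se = np.array([e.se for e in est])
    res = _dl_arrays(b[:, None], se[:, None])
    if term is None:
        term = est[0].term
    return MetaEstimate(term=term, beta_pooled=float(res["beta"][0]),
                        se_pooled=float(res["se"][0]), pval=float(res["pval"][0]),
                        tau2=float(res["tau2"][0]), q_stat=float(res["q"][0]),
                        i2=float(res["i2"][0]), k=len(est), per_cohort=list(est))


def _dl_arrays(B: np.ndarray, SE: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised DL pooling over columns; NaN entries drop out per column.

    ``B``/``SE`` are (k, m) arrays of per-cohort estimates for m quantities.
    """
    ok = np.isfinite(B) & np.isfinite(SE) & (SE > 0)
    w = np.where(ok, 1.0 / np.where(ok, SE, 1.0) ** 2, 0.0)
    k = ok.sum(axis=0)
    sw = w.sum(axis=0)
    b_fe = np.where(sw > 0, (w * np.where(ok, B, 0.0)).sum(axis=0) / np.where(sw > 0, sw, 1), np.nan)
    q = (w * (np.where(ok, B, 0.0) - b_fe[None, :]) ** 2 * ok).sum(axis=0)
    denom = sw - (w**2).sum(axis=0) / np.where(sw > 0, sw, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(denom > 0, np.maximum(0.0, (q - (k - 1)) / denom), 0.0)
        ws = np.where(ok, 1.0 / (np.where(ok, SE, 1.0) ** 2 + tau2[None, :]), 0.0)
        sws = ws.sum(axis=0)
        beta = (ws * np.where(ok, B, 0.0)).sum(axis=0) / sws
        se = 1.0 / np.sqrt(sws)
        zval = beta / se
        pval = 2.0 * stats.norm.sf(np.abs(zval))
        i2 = np.where(q > 0, np.maximum(0.0, (q - (k - 1)) / np.where(q > 0, q, 1)), 0.0)
    empty = k == 0
    for arr in (beta, se, pval, tau2, q, i2):
        arr[empty] = np.nan
    return {"beta": beta, "se": se, "pval": pval, "tau2": tau2, "q": q,
            "i2": i2, "z": beta / se, "k": k}


def meta_arrays(B: np.ndarray, SE: np.ndarray) -> dict[str, np.ndarray]:
    """Public vectorised DL pooling (used by the per-SNP GxE scan)."""
    return _dl_arrays(np.asarray(B, float), np.asarray(SE, float))


def grid_scan(grid: ThresholdGrid,
              estimates_by_threshold: list[list[AssocEstimate]],
              structure: str = "hippocampus",
              weight_kind: str = "beta",
              allow_empty: bool = False) -> GridScan:
    """Pool per-cohort estimates at every threshold and locate the optimum.

    ``best_threshold`` attains the smallest meta p-value (ties broken by the
    smaller threshold; comparisons use |z| so sub-double-precision p-values
    stay ordered).  Local peaks are thresholds whose p-value is at least as
    significant as both neighbours'; on a plateau only its smallest threshold
    counts.
    """
    if len(estimates_by_threshold) != len(grid):
        raise ValueError("estimates_by_threshold length must match the grid")
    metas = []
    for ests in estimates_by_threshold:
        finite = [e for e in ests if np.isfinite(e.beta) and np.isfinite(e.se)]
        if not finite and allow_empty:
            metas.append(MetaEstimate(term="PGS", beta_pooled=np.nan,
                                      se_pooled=np.nan, pval=np.nan, tau2=0.0,
                                      q_stat=0.0, i2=0.0, k=0))
        else:
            metas.append(dl_meta(ests))
    absz = np.array([abs(m.z) if np.isfinite(m.z) else -np.inf for m in metas])
    best_j = int(np.argmax(absz))  # argmax takes the first (smallest threshold) on ties
    peaks = [float(grid.thresholds[j]) for j in _local_peaks(absz)]
    return GridScan(structure=structure, weight_kind=weight_kind, grid=grid,
                    per_threshold=metas, best_threshold=float(grid.thresholds[best_j]),
                    local_peaks=peaks)


def _local_peaks(absz: np.ndarray) -> list[int]:
    """Indices where |z| >= both neighbours; plateaus yield their first index."""
    n = len(absz)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absz[j + 1] == absz[i]:
            j += 1
        left_ok = i == 0 or absz[i - 1] <= absz[i]
        right_ok = j == n - 1 or absz[j + 1] <= absz[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def bonferroni_alpha(n_tests: int, alpha_family: float = 0.05) -> float:
    """Per-test significance bound controlling the family-wise error rate."""
    if n_tests < 1 or not (0 < alpha_family < 1):
        raise ValueError("need n_tests >= 1 and alpha_family in (0, 1)")
    return alpha_family / n_tests


def forest_data(meta: MetaEstimate) -> pd.DataFrame:
    """Plot-ready forest table: one row per cohort plus the pooled row.

    Columns: label, beta, ci_low, ci_high (beta +/- 1.96 se), weight (the
    normalised random-effects weight; 1.0 for the pooled row).
    """
    ws = np.array([1.0 / (e.se**2 + meta.tau2) for e in meta.per_cohort])
    ws = ws / ws.sum()
    rows = [
        {"label": e.cohort_id, "beta": e.beta, "ci_low": e.beta - 1.96 * e.se,
         "ci_high": e.beta + 1.96 * e.se, "weight": w}
        for e, w in zip(meta.per_cohort, ws)
    ]
    rows.append({"label": "Meta", "beta": meta.beta_pooled,
                 "ci_low": meta.beta_pooled - 1.96 * meta.se_pooled,
                 "ci_high": meta.beta_pooled + 1.96 * meta.se_pooled,
                 "weight": 1.0})
    return pd.DataFrame(rows)
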