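"""Light-weight bundles tying genotypes, phenotypes and modelling config."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GenotypeCohort, SummaryStats


@dataclass
class Cohort:
    """One target cohort: genotypes, phenotype table, modelling conventions.

    ``n_pcs`` is the number of ancestry principal components entered as
    covariates (10 for the very large population cohort, 4 elsewhere);
    ``twin`` selects family-aware estimation; ``multi_site`` adds site
    indicator covariates for mega-analysed multi-site cohorts.
    """

    cohort_id: str
    pheno: pd.DataFrame
    geno: GenotypeCohort | None = None
    n_pcs: int = 4
    twin: bool = False
    multi_site: bool = False


@dataclass
class Study:
    """A full analysis input: discovery sumstats per structure plus cohorts."""

    sumstats: dict[str, SummaryStats]  # structure -> discovery summary stats
    cohorts: list[Cohort] = field(default_factory=list)

    def cohort(self, cohort_id: str) -> Cohort:
        for c in self.cohorts:
            if c.cohort_id == cohort_id:
                return c
        raise KeyError(cohort_id)
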