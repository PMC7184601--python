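"""Cell-line drug-sensitivity classification from dose-response AUC values.

Given a panel of cell lines with a genotype at a biallelic site (``WT/WT``,
``WT/SNP``, ``SNP/SNP``) and the area under the dose-response curve (AUC)
for each (cell line, drug) pair, this module:

* standardises AUC to a Z-score within each (drug, dataset) stratum — AUC
  scales differ between source databases, so strata are never pooled;
* calls a line *sensitive* when its Z-score falls strictly below a cutoff
  (default −1.5; lower AUC means stronger response);
* compares genotype cohorts with an unpaired two-tailed t-test, pooling
  heterozygotes into the SNP cohort (a dominant-effect reading of the
  biomarker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENOTYPES",
    "SNP_COHORT",
    "CohortComparison",
    "DegenerateInputError",
    "zscore_auc",
    "classify_sensitivity",
    "annotate_panel",
    "compare_genotype_cohorts",
    "summarize_by_drug",
]

GENOTYPES = ("WT/WT", "WT/SNP", "SNP/SNP")
#: genotypes pooled into the SNP cohort (heterozygotes count as SNP carriers)
SNP_COHORT = ("WT/SNP", "SNP/SNP")

PANEL_COLUMNS = ["cell_line", "genotype", "drug", "auc", "dataset"]


class DegenerateInputError(ValueError):
    """Raised when a stratum is too small or has zero AUC variance."""


def zscore_auc(auc) -> np.ndarray:
    """Z-scores of the AUC values of one (drug, dataset) stratum.

    Uses the sample standard deviation (n−1 denominator).  Requires at least
    three records and non-zero spread.
    """
    auc = np.asarray(auc, dtype=float)
    if auc.size < 3:
        raise DegenerateInputError(
            f"need >= 3 AUC records to standardise, got {auc.size}"
        )
    sd = auc.std(ddof=1)
    if not sd > 0:
        raise DegenerateInputError("AUC values are constant; Z-score undefined")
    return (auc - auc.mean()) / sd


def classify_sensitivity(z, threshold: float = -1.5):
    """Sensitive iff ``z < threshold`` (strict; a line exactly at the cutoff
    is non-sensitive).  Accepts a scalar or an array."""
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("non-finite Z-score")
    out = z_arr < threshold
    if np.isscalar(z) or z_arr.ndim == 0:
        return bool(out)
    return out


def _check_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns {missing}")
    bad = set(panel["genotype"]) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotypes {sorted(bad)}; expected {GENOTYPES}")


def annotate_panel(panel: pd.DataFrame, threshold: float = -1.5) -> pd.DataFrame:
    """Return the panel with ``z`` and ``sensitive`` columns added.

    Z-scores are computed independently within each (dataset, drug) stratum.
    """
    _check_panel(panel)
    out = panel.copy()
    out["z"] = (
        out.groupby(["dataset", "drug"], sort=False)["auc"]
        .transform(lambda s: zscore_auc(s.to_numpy()))
    )
    out["sensitive"] = classify_sensitivity(out["z"].to_numpy(), threshold)
    return out


@dataclass(frozen=True)
class CohortComparison:
    """Two-group comparison of AUC by genotype cohort for one drug."""

    drug: str
    dataset: str
    n_wt: int
    n_snp: int
    mean_auc_wt: float
    mean_auc_snp: float
    t_statistic: float
    p_value: float
    sensitive_wt: int
    sensitive_snp: int
    threshold: float
    equal_var: bool


def compare_genotype_cohorts(
    records: pd.DataFrame,
    threshold: float = -1.5,
    equal_var: bool = False,
) -> CohortComparison:
    """Unpaired two-tailed t-test of AUC between the WT and SNP cohorts.

    ``records`` must hold one (dataset, drug) stratum.  Heterozygous lines
    join the SNP cohort.  Welch's test is the default; pass
    ``equal_var=True`` for the classic pooled-variance test.  Sensitive
    counts per cohort use the Z-score cutoff within this stratum.
    """
    _check_panel(records)
    strata = records[["dataset", "drug"]].drop_duplicates()
    if len(strata) != 1:
        raise ValueError(
            "records must belong to a single (dataset, drug) stratum; "
            f"got {len(strata)}"
        )
    dataset, drug = strata.iloc[0]

    is_snp = records["genotype"].isin(SNP_COHORT).to_numpy()
    auc = records["auc"].to_numpy(dtype=float)
    wt_auc, snp_auc = auc[~is_snp], auc[is_snp]
    if len(wt_auc) < 2 or len(snp_auc) < 2:
        raise DegenerateInputError(
            f"each cohort needs >= 2 records (WT: {len(wt_auc)}, SNP: {len(snp_auc)})"
        )
    if np.ptp(auc) == 0:
        # a constant AUC column: no effect and no defined Z-score
        t_stat, p = 0.0, 1.0
        sensitive = np.zeros(auc.size, dtype=bool)
    else:
        t_stat, p = stats.ttest_ind(snp_auc, wt_auc, equal_var=equal_var)
        sensitive = zscore_auc(auc) < threshold
    return CohortComparison(
        drug=str(drug),
        dataset=str(dataset),
        n_wt=int((~is_snp).sum()),
        n_snp=int(is_snp.sum()),
        mean_auc_wt=float(wt_auc.mean()),
        mean_auc_snp=float(snp_auc.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        sensitive_wt=int(sensitive[~is_snp].sum()),
        sensitive_snp=int(sensitive[is_snp].sum()),
        threshold=threshold,
        equal_var=equal_var,
    )


def summarize_by_drug(
    panel: pd.DataFrame, threshold: float = -1.5, equal_var: bool = False
) -> pd.DataFrame:
    """Per-(dataset, drug) cohort comparison table for a whole panel."""
    _check_panel(panel)
    rows = []
    for (dataset, drug), grp in panel.groupby(["dataset", "drug"], sort=False):
        cmp_ = compare_genotype_cohorts(grp, threshold=threshold, equal_var=equal_var)
        rows.append(
            {
                "dataset": dataset,
                "drug": drug,
                "n_wt": cmp_.n_wt,
                "n_snp": cmp_.n_snp,
                "mean_auc_wt": cmp_.mean_auc_wt,
                "mean_auc_snp": cmp_.mean_auc_snp,
                "t_statistic": cmp_.t_statistic,
                "p_value": cmp_.p_value,
                "sensitive_wt": cmp_.sensitive_wt,
                "sensitive_snp": cmp_.sensitive_snp,
            }
        )
    return pd.DataFrame(rows)
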