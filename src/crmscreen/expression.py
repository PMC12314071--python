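"""Expression definitions and bundle-sheath specificity filters.

Operates on summary tables from cell-separated RNA-seq: a genes x samples
TPM matrix with a sample design (cell type BS/M/V, developmental stage 1-7,
replicate), and per-contrast differential-expression statistics (log2 fold
change, adjusted p, FDR).  Differential statistics are consumed, never
computed: the upstream model fits come from dedicated count-model tools and
both an adjusted p and an FDR column are required because the screen applies
the two independently.

All comparisons are strict, exactly as the filter definitions read: TPM
must exceed 1 (TPM = 1.0 fails), log2FC(BS/M) must exceed 2 (2.0 fails).
Missing values fail filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("crmscreen")

__all__ = [
    "ExpressionTable",
    "expressed_genes",
    "bs_specific_filter",
    "coexpression_rank",
    "BS_FILTER_THRESHOLDS",
]

#: bundle-sheath specificity: conjunction of four strict conditions
BS_FILTER_THRESHOLDS = {
    "log2fc_bs_m_min": 2.0,  # log2FC(BS/M) > 2
    "padj_bs_m_max": 0.01,  # adjusted P (BS/M) < 0.01
    "fdr_bs_m_max": 0.01,  # FDR (BS/M) < 0.01
    "log2fc_bs_v_min": -0.5,  # log2FC(BS/V) > -0.5
}

DE_COLUMNS = ["gene_id", "log2fc_bs_m", "padj_bs_m", "fdr_bs_m", "log2fc_bs_v"]


@dataclass
class ExpressionTable:
    """TPM matrix (genes x samples) plus sample metadata.

    ``meta`` is indexed by sample name with columns ``cell_type`` (BS/M/V),
    ``stage`` (1-7) and ``replicate``; every TPM column must be covered.
    """

    tpm: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        missing = set(self.tpm.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("cell_type", "stage"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks column {col!r}")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("negative TPM values")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)


def expressed_genes(expr: ExpressionTable, tpm_min: float = 1.0, min_samples: int = 3) -> set[str]:
    """Genes with TPM strictly above ``tpm_min`` in >= ``min_samples`` samples
    of at least one developmental stage.

    Stages with fewer than ``min_samples`` samples can never qualify and are
    flagged with a warning.
    """
    out: set[str] = set()
    for stage, samples in expr.meta.groupby("stage").groups.items():
        samples = [s for s in samples if s in expr.tpm.columns]
        if len(samples) < min_samples:
            logger.warning("stage %s has %d samples (< %d); cannot qualify genes", stage, len(samples), min_samples)
            continue
        n_over = (expr.tpm[samples] > tpm_min).sum(axis=1)
        out |= set(expr.tpm.index[n_over >= min_samples])
    return out


def bs_specific_filter(de: pd.DataFrame, thresholds: dict = BS_FILTER_THRESHOLDS) -> set[str]:
    """Bundle-sheath-specific genes by the compound four-condition filter.

    log2FC(BS/M) > 2 AND adjusted P(BS/M) < 0.01 AND FDR(BS/M) < 0.01 AND
    log2FC(BS/V) > -0.5, all strict; genes with any missing statistic fail.
    """
    missing_cols = [c for c in DE_COLUMNS if c not in de.columns]
    if missing_cols:
        raise ValueError(f"DE table lacks columns: {missing_cols}")
    d = de.set_index("gene_id") if de.index.name != "gene_id" else de
    ok = (
        (d["log2fc_bs_m"] > thresholds["log2fc_bs_m_min"])
        & (d["padj_bs_m"] < thresholds["padj_bs_m_max"])
        & (d["fdr_bs_m"] < thresholds["fdr_bs_m_max"])
        & (d["log2fc_bs_v"] > thresholds["log2fc_bs_v_min"])
    )
    ok = ok.fillna(False)
    return set(d.index[ok])


def coexpression_rank(expr: ExpressionTable, target_gene: str) -> pd.Series:
    """Genes ranked by Pearson correlation with the target on log2(TPM+1).

    Returns a Series (gene -> correlation) in descending order, ties broken
    by gene id; the target itself ranks first with correlation 1.  A
    zero-variance target is an error; zero-variance other genes get NaN and
    sort last.
    """
    if target_gene not in expr.tpm.index:
        raise KeyError(f"target gene {target_gene!r} not in expression table")
    x = np.log2(expr.tpm + 1.0)
    target = x.loc[target_gene]
    if float(target.std(ddof=0)) == 0.0:
        raise ValueError(f"target gene {target_gene!r} has zero variance")
    with np.errstate(invalid="ignore"):  # zero-variance genes yield NaN, sorted last
        corr = x.T.corrwith(target)
    frame = corr.rename("correlation").to_frame()
    frame["gene_id"] = frame.index
    frame = frame.sort_values(["correlation", "gene_id"], ascending=[False, True], na_position="last")
    return frame["correlation"]
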