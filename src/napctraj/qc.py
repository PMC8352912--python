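"""Cell and sample quality control.

Three rules, applied exactly as stated in the study design:

* RNA QC — a cell passes iff it has **more than** ``min_genes_exclusive``
  unique genes detected and **less than** ``max_mito_frac_exclusive``
  mitochondrial UMI fraction (both strict).
* Hashing QC — a cell passes iff the most abundant hashtag carries more
  than ``hto_dominant_frac_exclusive`` of its hashtag UMI and the
  second-to-first hashtag ratio is below ``hto_second_ratio_exclusive``
  (both strict). Ties for the most abundant hashtag fail.
* Bulk common-gene QC — "common genes" are detected (value > 0) in at
  least ``detect_frac`` of samples; a sample passes iff it detects more
  than ``pass_frac`` of the common genes (strict).

All boundary cases therefore fail: exactly 500 genes, exactly 5% mito,
exactly 80% dominant hashtag, exactly 5% ratio, exactly 97% common genes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BulkExpressionTable, HashtagMatrix, UMICountMatrix

__all__ = [
    "QCThresholds",
    "cell_rna_qc",
    "hashtag_demux",
    "combine_qc",
    "bulk_common_gene_qc",
    "filter_cells",
]


@dataclass
class QCThresholds:
    min_genes_exclusive: int = 500
    max_mito_frac_exclusive: float = 0.05
    hto_dominant_frac_exclusive: float = 0.80
    hto_second_ratio_exclusive: float = 0.05
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        for name in ("max_mito_frac_exclusive", "hto_dominant_frac_exclusive",
                     "hto_second_ratio_exclusive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_genes_exclusive < 0:
            raise ValueError("min_genes_exclusive must be non-negative")


def mito_gene_mask(gene_ids: np.ndarray, prefix: str = "mt-") -> np.ndarray:
    """Case-insensitive prefix match identifying mitochondrial genes."""
    prefix = prefix.lower()
    return np.array([str(g).lower().startswith(prefix) for g in gene_ids])


def cell_rna_qc(
    counts: UMICountMatrix, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Per-cell RNA QC metrics and pass flags.

    Returns a DataFrame indexed by barcode with columns
    ``n_genes_detected``, ``total_umi``, ``mito_frac``, ``rna_pass``,
    ``rna_reason``. A cell with zero total UMI has an undefined
    mitochondrial fraction and fails with reason ``zero_umi``.
    """
    thresholds = thresholds or QCThresholds()
    csc = counts.counts.tocsc()
    n_detected = np.asarray((csc > 0).sum(axis=0)).ravel()
    total = np.asarray(csc.sum(axis=0)).ravel().astype(float)
    mito = mito_gene_mask(counts.gene_ids, thresholds.mito_prefix)
    mito_umi = np.asarray(csc[mito].sum(axis=0)).ravel().astype(float) if mito.any() \
        else np.zeros_like(total)

    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_umi / np.where(total > 0, total, 1), np.nan)

    pass_genes = n_detected > thresholds.min_genes_exclusive
    pass_mito = mito_frac < thresholds.max_mito_frac_exclusive  # NaN -> False
    rna_pass = pass_genes & pass_mito & (total > 0)

    reason = np.full(counts.n_cells, "", dtype=object)
    reason[total == 0] = "zero_umi"
    reason[(total > 0) & ~pass_genes] = "low_genes"
    reason[(total > 0) & pass_genes & ~pass_mito] = "high_mito"

    return pd.DataFrame(
        {
            "n_genes_detected": n_detected,
            "total_umi": total.astype(int),
            "mito_frac": mito_frac,
            "rna_pass": rna_pass,
            "rna_reason": reason,
        },
        index=pd.Index(counts.cell_barcodes, name="barcode"),
    )


def hashtag_demux(
    hto: HashtagMatrix, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Ratio-based hashtag demultiplexing QC.

    The assigned hashtag is the argmax of the cell's hashtag counts; a cell
    passes iff its dominant fraction exceeds the dominant threshold and the
    second/first ratio is below the ratio threshold (both strict). Ties for
    the top hashtag and zero-HTO cells fail with reason codes.
    """
    thresholds = thresholds or QCThresholds()
    counts = np.asarray(hto.counts, dtype=float)
    order = np.sort(counts, axis=0)
    top = order[-1]
    second = order[-2]
    total = counts.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        dominant_frac = np.where(total > 0, top / np.where(total > 0, total, 1), np.nan)
        second_ratio = np.where(top > 0, second / np.where(top > 0, top, 1), np.nan)

    tie = (top == second) & (total > 0)
    hash_pass = (
        (total > 0)
        & ~tie
        & (dominant_frac > thresholds.hto_dominant_frac_exclusive)
        & (second_ratio < thresholds.hto_second_ratio_exclusive)
    )

    assigned = hto.hashtag_ids[np.argmax(counts, axis=0)].astype(object)
    assigned[total == 0] = None
    assigned[tie] = None

    reason = np.full(counts.shape[1], "", dtype=object)
    reason[total == 0] = "zero_hto"
    reason[tie] = "tied_top_hashtags"
    low_dom = (total > 0) & ~tie & ~(dominant_frac > thresholds.hto_dominant_frac_exclusive)
    reason[low_dom] = "low_dominant_frac"
    high_ratio = (
        (total > 0) & ~tie
        & (dominant_frac > thresholds.hto_dominant_frac_exclusive)
        & ~(second_ratio < thresholds.hto_second_ratio_exclusive)
    )
    reason[high_ratio] = "high_second_ratio"

    return pd.DataFrame(
        {
            "hashtag": assigned,
            "dominant_frac": dominant_frac,
            "second_to_first_ratio": second_ratio,
            "hash_pass": hash_pass,
            "hash_reason": reason,
        },
        index=pd.Index(hto.cell_barcodes, name="barcode"),
    )


def combine_qc(rna_report: pd.DataFrame, hash_report: pd.DataFrame) -> pd.DataFrame:
    """Join the RNA and hashing reports; overall pass = both pass.

    The two rules are applied independently and intersected.
    """
    report = rna_report.join(hash_report, how="inner")
    if len(report) != len(rna_report) or len(report) != len(hash_report):
        raise ValueError("RNA and hashtag reports cover different barcodes")
    report["pass"] = report["rna_pass"] & report["hash_pass"]
    return report


def filter_cells(counts: UMICountMatrix, report: pd.DataFrame,
                 column: str = "pass") -> UMICountMatrix:
    """Subset a count matrix to cells flagged True in a QC report column."""
    keep = report.loc[pd.Index(counts.cell_barcodes), column].to_numpy(bool)
    return counts.subset_cells(keep)


def bulk_common_gene_qc(
    bulk: BulkExpressionTable,
    detect_frac: float = 0.90,
    pass_frac: float = 0.97,
) -> dict:
    """Common-gene QC for bulk expression tables.

    Common genes are those detected (> 0) in at least ``detect_frac`` of
    the samples; each sample's metric is the fraction of common genes it
    detects, and the sample passes iff that fraction strictly exceeds
    ``pass_frac``. With zero common genes every sample fails and a warning
    is recorded in the report.
    """
    if bulk.values.shape[1] < 2:
        raise ValueError("bulk common-gene QC requires at least 2 samples")
    detected = bulk.values.to_numpy() > 0
    common = detected.mean(axis=1) >= detect_frac
    common_genes = bulk.values.index[common]
    n_common = int(common.sum())
    if n_common == 0:
        metric = np.zeros(bulk.values.shape[1])
        warning = "no common genes at this detection threshold"
    else:
        metric = detected[common].mean(axis=0)
        warning = None
    samples = pd.DataFrame(
        {
            "frac_common_detected": metric,
            "pass": metric > pass_frac if n_common else np.zeros(len(metric), bool),
        },
        index=pd.Index(bulk.sample_ids, name="sample"),
    )
    return {
        "common_genes": common_genes,
        "n_common_genes": n_common,
        "samples": samples,
        "warning": warning,
    }
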