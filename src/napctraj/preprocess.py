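"""Normalization, variable-gene selection, scaling and PCA.

The processing chain mirrors the standard single-cell toolchain: log1p
counts-per-10k normalization, highly-variable-gene selection by
standardized log dispersion within mean bins, per-gene standardization,
then PCA on the scaled matrix. PCA uses a deterministic SVD with the sign
of each component fixed so that its largest-magnitude gene loading is
positive.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    BulkExpressionTable,
    EmbeddingResult,
    NormalizedMatrix,
    ScaledMatrix,
    UMICountMatrix,
)

__all__ = ["normalize_log", "select_hvg", "scale_center", "pca", "bulk_pca"]


def normalize_log(counts: UMICountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Log-normalize: value = log(1 + count * scale_factor / nUMI_cell).

    Requires QC to have removed zero-total cells first.
    """
    n_umi = counts.n_umi.astype(float)
    if np.any(n_umi == 0):
        raise ValueError(
            "cells with zero total UMI present; run QC filtering before normalization"
        )
    csc = counts.counts.tocsc().astype(float)
    csc = csc.multiply(scale_factor / n_umi).tocsr()
    csc.data = np.log1p(csc.data)
    return NormalizedMatrix(csc, counts.gene_ids, counts.cell_barcodes,
                            scheme=f"log1p_cp{scale_factor:g}")


def _gene_mean_var(values: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean and (population) variance of a sparse matrix."""
    n = values.shape[1]
    mean = np.asarray(values.mean(axis=1)).ravel()
    sq = values.multiply(values)
    mean_sq = np.asarray(sq.mean(axis=1)).ravel()
    var = mean_sq - mean**2
    return mean, np.maximum(var, 0.0)


def select_hvg(
    norm: NormalizedMatrix, n_top: int = 3581, n_mean_bins: int = 20
) -> np.ndarray:
    """Select highly variable genes by standardized log dispersion.

    Dispersion is variance/mean of ``expm1`` of the normalized values (i.e.
    on the counts-per-scale-factor scale). Log dispersions are z-scored
    within ``n_mean_bins`` equal-count bins of gene mean, and the top
    ``n_top`` genes by z-score are returned (ties broken by gene id).
    Constant (zero-dispersion) genes are never selected.
    """
    expm1 = norm.values.copy()
    expm1.data = np.expm1(expm1.data)
    mean, var = _gene_mean_var(expm1)

    usable = (mean > 0) & (var > 0)
    n_usable = int(usable.sum())
    if n_top > n_usable:
        raise ValueError(
            f"requested {n_top} variable genes but only {n_usable} genes are non-constant"
        )

    dispersion = np.full(len(mean), np.nan)
    dispersion[usable] = var[usable] / mean[usable]
    log_disp = np.log(dispersion[usable])
    usable_idx = np.flatnonzero(usable)

    # equal-count bins of mean expression among usable genes
    order = np.argsort(mean[usable], kind="stable")
    bins = np.empty(n_usable, dtype=int)
    bins[order] = np.minimum(
        (np.arange(n_usable) * n_mean_bins) // n_usable, n_mean_bins - 1
    )

    z = np.empty(n_usable)
    for b in range(n_mean_bins):
        in_bin = bins == b
        if not in_bin.any():
            continue
        vals = log_disp[in_bin]
        sd = vals.std()
        z[in_bin] = (vals - vals.mean()) / sd if sd > 0 else 0.0

    ids = norm.gene_ids[usable_idx]
    rank = pd.DataFrame({"z": z, "gene": ids}).sort_values(
        ["z", "gene"], ascending=[False, True], kind="stable"
    )
    return rank["gene"].to_numpy(object)[:n_top]


def scale_center(norm: NormalizedMatrix, genes, ddof: int = 1,
                 clip: float | None = None) -> ScaledMatrix:
    """Standardize selected genes to mean 0, variance 1 across cells.

    Constant genes are dropped with a warning; ``clip`` optionally clips
    standardized values at +/- clip (off by default).
    """
    genes = np.asarray(genes, dtype=object)
    idx = pd.Index(norm.gene_ids).get_indexer(genes)
    if (idx < 0).any():
        missing = genes[idx < 0]
        raise KeyError(f"genes not in matrix: {list(missing[:5])} ...")
    dense = np.asarray(norm.values[idx].todense(), dtype=float)
    mean = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    if constant.all():
        raise ValueError("all requested genes are constant; nothing to scale")
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s) before scaling",
            stacklevel=2,
        )
        keep = ~constant
        dense, mean, sd, genes = dense[keep], mean[keep], sd[keep], genes[keep]
    scaled = (dense - mean) / sd
    if clip is not None:
        scaled = np.clip(scaled, -clip, clip)
    return ScaledMatrix(scaled, genes, norm.cell_barcodes)


def _signed_svd(X: np.ndarray, n_comp: int):
    """SVD of observations x features X with deterministic component signs."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp]
    for k in range(n_comp):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    return U, S, Vt


def pca(scaled: ScaledMatrix, n_pcs: int = 50) -> EmbeddingResult:
    """PCA of cells in the scaled gene space (deterministic SVD).

    Explained-variance fractions are singular values squared over the total
    variance of the scaled matrix, so a rank-1 matrix gives PC1 fraction 1.
    """
    X = scaled.values.T  # cells x genes, already per-gene centered
    n_obs, n_feat = X.shape
    if n_pcs > min(n_obs, n_feat):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(cells, genes)={min(n_obs, n_feat)}"
        )
    U, S, Vt = _signed_svd(X, n_pcs)
    total_var = (X**2).sum()
    evr = S**2 / total_var if total_var > 0 else np.zeros(n_pcs)
    return EmbeddingResult(
        coords=U * S,
        explained_variance_ratio=evr,
        loadings=Vt,
        obs_ids=scaled.cell_barcodes,
        gene_ids=scaled.gene_ids,
    )


def bulk_pca(
    bulk: BulkExpressionTable, mean_percentile: float = 0.90, n_pcs: int = 10
) -> EmbeddingResult:
    """PCA of bulk samples on high-mean genes.

    Genes whose mean expression is at or above the ``mean_percentile``
    quantile of all gene means are kept (percentile 0 keeps every gene),
    log1p-transformed, standardized per gene across samples, and the
    samples are embedded by PCA.
    """
    if bulk.values.shape[1] < 2:
        raise ValueError("bulk PCA requires at least 2 samples")
    log_expr = np.log1p(bulk.values.to_numpy(float))
    means = log_expr.mean(axis=1)
    cutoff = np.quantile(means, mean_percentile)
    keep = means >= cutoff
    X = log_expr[keep]
    sd = X.std(axis=1, ddof=1, keepdims=True)
    nonconst = sd.ravel() > 0
    X = (X[nonconst] - X[nonconst].mean(axis=1, keepdims=True)) / sd[nonconst]
    genes = bulk.gene_ids[keep][nonconst]
    n_pcs = min(n_pcs, min(X.shape[1], X.shape[0]))
    U, S, Vt = _signed_svd(X.T, n_pcs)
    total_var = (X**2).sum()
    evr = S**2 / total_var if total_var > 0 else np.zeros(n_pcs)
    return EmbeddingResult(
        coords=U * S,
        explained_variance_ratio=evr,
        loadings=Vt,
        obs_ids=bulk.sample_ids,
        gene_ids=genes,
    )
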