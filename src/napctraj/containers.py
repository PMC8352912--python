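"""In-memory containers for the pipeline's matrices.

All single-cell matrices follow the 10x convention: genes are rows, cells
are columns. Counts are stored sparse (CSR); derived per-cell totals
(``n_umi``) are column sums of the count matrix, which is exactly what the
library-size offset of the pseudotime regression uses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "UMICountMatrix",
    "HashtagMatrix",
    "BulkExpressionTable",
    "NormalizedMatrix",
    "ScaledMatrix",
    "EmbeddingResult",
    "ClusterAssignment",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class UMICountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape (n_genes, n_cells).
    gene_ids, cell_barcodes
        Unique string identifiers for rows / columns.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_barcodes, "cell barcode")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("UMI counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_umi(self) -> np.ndarray:
        """Per-cell total UMI (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, mask_or_idx) -> "UMICountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return UMICountMatrix(
            self.counts[:, idx], self.gene_ids, self.cell_barcodes[idx]
        )

    def subset_genes(self, mask_or_idx) -> "UMICountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return UMICountMatrix(
            self.counts[idx, :], self.gene_ids[idx], self.cell_barcodes
        )


@dataclass
class HashtagMatrix:
    """Hashtag-oligo (HTO) counts, hashtags x cells, aligned to an RNA matrix."""

    counts: np.ndarray
    hashtag_ids: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.hashtag_ids = np.asarray(self.hashtag_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.counts.shape != (len(self.hashtag_ids), len(self.cell_barcodes)):
            raise ValueError("hashtag matrix shape does not match identifier lists")
        if len(self.hashtag_ids) < 2:
            raise ValueError("at least two hashtags are required for demultiplexing")
        _check_unique(self.hashtag_ids, "hashtag")
        _check_unique(self.cell_barcodes, "cell barcode")
        if np.any(self.counts < 0):
            raise ValueError("hashtag counts must be non-negative")


@dataclass
class BulkExpressionTable:
    """Bulk expression, genes x samples, in TPM units.

    When ``units == "TPM"`` every sample column must sum to 1e6 (relative
    tolerance 1e-3).
    """

    values: pd.DataFrame  # genes x samples
    units: str = "TPM"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a genes x samples DataFrame")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        _check_unique(self.values.index.to_numpy(), "gene")
        _check_unique(self.values.columns.to_numpy(), "sample")
        if self.units == "TPM":
            sums = self.values.sum(axis=0).to_numpy(dtype=float)
            if not np.allclose(sums, 1e6, rtol=1e-3):
                raise ValueError(
                    "TPM columns must sum to 1e6 (worst column sum "
                    f"{sums[np.argmax(np.abs(sums - 1e6))]:.1f}); "
                    "read with renormalize=True to rescale"
                )

    @property
    def gene_ids(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=object)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=object)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression (genes x cells, sparse) with a provenance tag."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_barcodes: np.ndarray
    scheme: str = "log1p_cp10k"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError("normalized matrix shape does not match identifiers")
        if self.values.data.size and np.any(self.values.data < 0):
            raise ValueError("log-normalized values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.gene_ids, columns=self.cell_barcodes
        )


@dataclass
class ScaledMatrix:
    """Dense selected-genes x cells matrix, per-gene mean 0 / variance 1."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError("scaled matrix shape does not match identifiers")


@dataclass
class EmbeddingResult:
    """PCA embedding: per-observation coordinates plus loadings.

    ``coords`` is observations x components (cells for single-cell PCA,
    samples for bulk PCA); ``loadings`` is components x genes with rows of
    unit norm; ``explained_variance_ratio`` is non-increasing.
    """

    coords: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray
    obs_ids: np.ndarray
    gene_ids: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class ClusterAssignment:
    """Per-cell integer cluster labels, contiguous from 0, ordered by size."""

    labels: np.ndarray
    cell_barcodes: np.ndarray
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if len(self.labels) != len(self.cell_barcodes):
            raise ValueError("one label per cell required")
        uniq = np.unique(self.labels)
        if len(self.labels) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster labels must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))
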