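"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices use Matrix Market coordinate triplets (1-based, standard)
with TSV sidecars for gene ids and cell barcodes, the layout emitted by
10x-style quantification. Tabular data is tab-separated with a header row.
Duplicate coordinate entries in an .mtx file are summed (the usual sparse
dialect). All round-trips are lossless for integer counts.
"""
from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import BulkExpressionTable, HashtagMatrix, UMICountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_hashtags",
    "write_hashtags",
    "read_bulk",
    "write_bulk",
    "write_table",
    "read_table",
]


def _read_sidecar(path) -> np.ndarray:
    """Read the first column of a headerless TSV sidecar (genes/barcodes)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty sidecar file: {path}")
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].to_numpy(object)
    return ids


def read_counts(mtx_path, genes_path, barcodes_path) -> UMICountMatrix:
    """Read a Matrix Market UMI matrix with gene/barcode sidecars.

    Duplicate (i, j) entries are summed. Raises on dimension mismatch
    between the header and the sidecars, and on negative or non-integer
    entries.
    """
    mtx_path = Path(mtx_path)
    if mtx_path.stat().st_size == 0:
        raise ValueError(f"empty matrix file: {mtx_path}")
    mat = scipy.io.mmread(mtx_path)
    genes = _read_sidecar(genes_path)
    barcodes = _read_sidecar(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix header declares {mat.shape} but sidecars list "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )
    csr = sp.csr_matrix(mat)  # sums duplicate coordinates
    if csr.data.size and (np.any(csr.data < 0) or np.any(csr.data != np.round(csr.data))):
        raise ValueError(f"negative or non-integer entries in {mtx_path}")
    csr = csr.astype(np.int64)
    return UMICountMatrix(csr, genes, barcodes)


def write_counts(matrix: UMICountMatrix, mtx_path, genes_path, barcodes_path) -> None:
    """Write a UMI matrix as .mtx plus TSV sidecars (lossless round-trip)."""
    scipy.io.mmwrite(str(mtx_path), matrix.counts.tocoo(), field="integer")
    pd.Series(matrix.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(matrix.cell_barcodes).to_csv(
        barcodes_path, sep="\t", header=False, index=False
    )


def read_hashtags(path) -> HashtagMatrix:
    """Read an HTO count table: hashtags x cells, TSV with a barcode header."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty hashtag file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"hashtag table has no cell columns: {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric entries in hashtag table: {path}")
    return HashtagMatrix(
        values.astype(np.int64),
        df.index.to_numpy(object),
        df.columns.to_numpy(object),
    )


def write_hashtags(hto: HashtagMatrix, path) -> None:
    pd.DataFrame(
        hto.counts, index=hto.hashtag_ids, columns=hto.cell_barcodes
    ).to_csv(path, sep="\t")


def read_bulk(path, units: str = "TPM", renormalize: bool = False) -> BulkExpressionTable:
    """Read a genes x samples bulk expression TSV.

    When ``units="TPM"`` and a column does not sum to 1e6 (relative
    tolerance 1e-3): with ``renormalize=True`` the column is rescaled with a
    warning, otherwise a validation error is raised.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty bulk expression file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    if df.shape[1] == 0:
        raise ValueError(f"bulk table has no sample columns: {path}")
    if units == "TPM":
        sums = df.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1e6, rtol=1e-3):
            if renormalize:
                warnings.warn(
                    "TPM columns do not sum to 1e6; renormalizing", stacklevel=2
                )
                df = df * (1e6 / df.sum(axis=0))
            # else fall through: container validation raises with detail
    return BulkExpressionTable(df, units=units)


def write_bulk(bulk: BulkExpressionTable, path) -> None:
    bulk.values.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write any tabular result as TSV (deterministic column order)."""
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty table: {path}")
    return pd.read_csv(path, sep="\t", index_col=index_col)
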