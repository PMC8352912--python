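"""Trajectory gene score and signed maturation score.

The trajectory gene score is the slope-weighted sum of expression over the
trajectory gene set: score_j = sum_i beta1_i * expr_ij. It is linear in
the expression layer, so it transfers unchanged to held-out single cells
(log-normalized layer) and to bulk samples (log1p TPM layer); the layer is
recorded in the returned Series' name.

The maturation score standardizes each gene of a curated signed gene set
across cells, multiplies by its +/-1 direction indicator, and sums over
genes and over the cells of each cluster.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BulkExpressionTable, ClusterAssignment, NormalizedMatrix
from .glm import TrajectoryGeneSet

__all__ = ["MaturationGeneSet", "trajectory_gene_score", "maturation_score"]


@dataclass
class MaturationGeneSet:
    """Curated maturation genes with +/-1 direction indicators."""

    genes: np.ndarray
    signs: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.signs = np.asarray(self.signs, dtype=int)
        if len(self.genes) != len(self.signs):
            raise ValueError("one sign per gene required")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in maturation set")
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("direction indicators must be +1 or -1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MaturationGeneSet":
        return cls(df.index.to_numpy(object), df.iloc[:, 0].to_numpy(int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sign": self.signs},
                            index=pd.Index(self.genes, name="gene"))


def _expression_frame(expr) -> tuple[pd.DataFrame, str]:
    """Extract a genes x observations log-scale DataFrame and a layer tag."""
    if isinstance(expr, NormalizedMatrix):
        return expr.to_frame(), expr.scheme
    if isinstance(expr, BulkExpressionTable):
        return np.log1p(expr.values), f"log1p_{expr.units}"
    if isinstance(expr, pd.DataFrame):
        return expr, "user_layer"
    raise TypeError(f"unsupported expression container: {type(expr).__name__}")


def trajectory_gene_score(expr, gene_set: TrajectoryGeneSet) -> pd.Series:
    """Slope-weighted trajectory score per cell or bulk sample.

    Genes of the set missing from the expression table are dropped with a
    warning; zero overlap is an error.
    """
    frame, layer = _expression_frame(expr)
    present = np.isin(gene_set.genes, frame.index.to_numpy(object))
    if not present.any():
        raise ValueError("no trajectory gene overlaps the expression table")
    n_missing = int((~present).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} of {len(gene_set)} trajectory genes missing from the "
            "expression table; scoring on the overlap",
            stacklevel=2,
        )
    genes = gene_set.genes[present]
    beta = gene_set.beta1[present]
    scores = beta @ frame.loc[genes].to_numpy(float)
    out = pd.Series(scores, index=frame.columns, name="trajectory_score")
    out.attrs["layer"] = layer
    out.attrs["n_genes_used"] = int(present.sum())
    return out


def maturation_score(
    norm: NormalizedMatrix,
    gene_set: MaturationGeneSet,
    clusters: ClusterAssignment,
) -> pd.Series:
    """Signed per-cluster maturation score.

    Per-gene standardized expression (mean 0, variance 1 across all cells)
    is multiplied by the gene's direction indicator and summed over the
    genes of the set and over the cells of each cluster. Constant genes
    are dropped with a warning; if no usable gene remains this is an
    error, not a silent zero.
    """
    if not np.array_equal(norm.cell_barcodes, clusters.cell_barcodes):
        raise ValueError("normalized matrix and clusters cover different cells")
    present = np.isin(gene_set.genes, norm.gene_ids)
    if not present.any():
        raise ValueError("no maturation gene present in the expression matrix")
    genes = gene_set.genes[present]
    signs = gene_set.signs[present]
    idx = pd.Index(norm.gene_ids).get_indexer(genes)
    dense = np.asarray(norm.values[idx].todense(), dtype=float)
    sd = dense.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all maturation genes are constant across cells")
    if (~usable).any():
        warnings.warn(
            f"dropping {int((~usable).sum())} constant maturation gene(s)",
            stacklevel=2,
        )
    dense, signs, sd = dense[usable], signs[usable], sd[usable]
    z = (dense - dense.mean(axis=1, keepdims=True)) / sd[:, None]
    per_cell = signs @ z
    out = pd.Series(
        [per_cell[clusters.labels == c].sum() for c in range(clusters.n_clusters)],
        index=pd.Index(range(clusters.n_clusters), name="cluster"),
        name="maturation_score",
    )
    return out
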