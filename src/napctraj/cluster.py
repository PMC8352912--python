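"""Neighbor graph construction, graph clustering, pseudo-bulk correlation
and AUC marker ranking."""
from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from .containers import (
    ClusterAssignment,
    EmbeddingResult,
    NormalizedMatrix,
    UMICountMatrix,
)

__all__ = [
    "harmonize",
    "knn_graph",
    "graph_cluster",
    "pseudobulk",
    "cluster_correlation",
    "marker_auc",
]


def harmonize(embedding: EmbeddingResult, batch=None, method: str = "identity"
              ) -> EmbeddingResult:
    """Pluggable batch correction of PC coordinates.

    The default (and only built-in) method is the identity: single-batch
    data needs no correction. Any replacement must return corrected
    coordinates with the same shape and observation ids.
    """
    if method != "identity":
        raise NotImplementedError(f"unknown harmonization method: {method}")
    return embedding


def knn_graph(embedding: EmbeddingResult, n_pcs_used: int = 15, k: int = 15
              ) -> nx.Graph:
    """Undirected, unweighted k-nearest-neighbor graph.

    Euclidean distance in the first ``n_pcs_used`` components; the directed
    kNN relation is symmetrized (an edge exists if either endpoint lists
    the other among its k nearest). Nodes are cell indices 0..n-1 with a
    ``barcode`` attribute.
    """
    n_cells = embedding.coords.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n_cells:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n_cells})")
    X = embedding.coords[:, : min(n_pcs_used, embedding.n_components)]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    g = nx.Graph()
    g.add_nodes_from(range(n_cells))
    for i in range(n_cells):
        for j in idx[i, 1:]:  # skip self
            g.add_edge(i, int(j))
    nx.set_node_attributes(
        g, {i: b for i, b in enumerate(embedding.obs_ids)}, "barcode"
    )
    return g


def graph_cluster(graph: nx.Graph, resolution: float = 1.0, seed: int = 0
                  ) -> ClusterAssignment:
    """Louvain modularity clustering of the cell kNN graph.

    Deterministic under a fixed seed; labels are renumbered by decreasing
    cluster size (ties broken by smallest member index).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = nx.algorithms.community.louvain_communities(
        graph, resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    n = graph.number_of_nodes()
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(communities):
        labels[list(members)] = lab
    barcodes = np.array(
        [graph.nodes[i].get("barcode", str(i)) for i in range(n)], dtype=object
    )
    return ClusterAssignment(labels, barcodes, resolution=resolution, seed=seed)


def pseudobulk(counts: UMICountMatrix, clusters: ClusterAssignment) -> pd.DataFrame:
    """Sum raw counts over cells within each cluster (genes x clusters)."""
    if not np.array_equal(counts.cell_barcodes, clusters.cell_barcodes):
        raise ValueError("count matrix and cluster assignment barcodes differ")
    n_clusters = clusters.n_clusters
    out = np.zeros((counts.n_genes, n_clusters))
    csc = counts.counts.tocsc()
    for c in range(n_clusters):
        cols = np.flatnonzero(clusters.labels == c)
        out[:, c] = np.asarray(csc[:, cols].sum(axis=1)).ravel()
    return pd.DataFrame(
        out, index=pd.Index(counts.gene_ids, name="gene"),
        columns=[f"cluster_{c}" for c in range(n_clusters)],
    )


def cluster_correlation(pb: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of log1p-CPM pseudo-bulk profiles.

    Returns a symmetric clusters x clusters matrix with unit diagonal.
    """
    if pb.shape[1] == 1:
        warnings.warn("single cluster: correlation matrix is 1x1", stacklevel=2)
    cpm = pb * (1e6 / pb.sum(axis=0))
    log_cpm = np.log1p(cpm)
    corr = log_cpm.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _auc_one_vs_rest(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Midrank AUC per gene (rows) of cluster cells vs the rest.

    AUC = U / (n1 * n2) with U the Mann-Whitney statistic computed from
    midranks, so ties contribute half a concordant pair.
    """
    n1 = int(in_group.sum())
    n2 = values.shape[1] - n1
    ranks = np.apply_along_axis(rankdata, 1, values)
    rank_sum = ranks[:, in_group].sum(axis=1)
    u = rank_sum - n1 * (n1 + 1) / 2
    return u / (n1 * n2)


def marker_auc(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment,
    top_n: int = 200,
    exclude_ribosomal: bool = True,
    ribosomal_prefixes: tuple[str, ...] = ("rps", "rpl"),
) -> pd.DataFrame:
    """Rank marker genes per cluster by one-vs-rest AUC.

    Returns a tidy table (cluster, gene, auc, rank) with the top ``top_n``
    genes per cluster, ribosomal-prefix genes excluded by default.
    """
    if clusters.n_clusters < 2:
        raise ValueError("marker ranking requires at least 2 clusters")
    gene_mask = np.ones(len(norm.gene_ids), dtype=bool)
    if exclude_ribosomal:
        lowered = np.array([str(g).lower() for g in norm.gene_ids])
        for p in ribosomal_prefixes:
            gene_mask &= ~np.char.startswith(lowered.astype(str), p)
    dense = np.asarray(norm.values[np.flatnonzero(gene_mask)].todense())
    genes = norm.gene_ids[gene_mask]

    rows = []
    for c in range(clusters.n_clusters):
        in_c = clusters.labels == c
        if in_c.sum() == 0 or (~in_c).sum() == 0:
            raise ValueError(f"cluster {c} is empty or covers all cells")
        auc = _auc_one_vs_rest(dense, in_c)
        order = np.lexsort((genes.astype(str), -auc))[:top_n]
        for r, gi in enumerate(order):
            rows.append((c, genes[gi], auc[gi], r + 1))
    return pd.DataFrame(rows, columns=["cluster", "gene", "auc", "rank"])
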