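"""Principal-graph pseudotime.

A simplified principal graph: the minimum spanning tree over cluster
centroids in the PC embedding. Cells are projected perpendicularly onto
the nearest tree edge (clamped to the segment) and ordered by geodesic
distance along the tree from a user-chosen root cluster. This preserves
the downstream contract of principal-graph trajectory tools — a scalar
ordering from a designated starting population — without their iterative
graph-embedding machinery.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .containers import ClusterAssignment, EmbeddingResult, NormalizedMatrix

__all__ = [
    "TrajectoryGraph",
    "PseudotimeAssignment",
    "learn_principal_graph",
    "order_cells",
    "bin_expression",
]


@dataclass
class TrajectoryGraph:
    """MST over cluster centroids; nodes are cluster labels."""

    centroids: np.ndarray  # n_clusters x n_dims
    tree: nx.Graph  # nodes = cluster labels, edge attr "weight" = distance
    n_dims_used: int

    def __post_init__(self) -> None:
        n = self.centroids.shape[0]
        if self.tree.number_of_nodes() != n:
            raise ValueError("tree nodes must match centroid rows")
        if self.tree.number_of_edges() != n - 1 or not nx.is_connected(self.tree):
            raise ValueError("principal graph must be a spanning tree")


@dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime P_j >= 0; NaN marks cells excluded from the trajectory."""

    values: np.ndarray
    cell_barcodes: np.ndarray
    root_cluster: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if len(self.values) != len(self.cell_barcodes):
            raise ValueError("one pseudotime per cell required")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or abs(finite.min()) > 1e-9):
            raise ValueError("pseudotime must be non-negative with minimum 0")

    @property
    def on_trajectory(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.cell_barcodes, name="pseudotime")


def learn_principal_graph(
    embedding: EmbeddingResult,
    clusters: ClusterAssignment,
    n_dims_used: int = 15,
) -> TrajectoryGraph:
    """Minimum spanning tree over cluster centroids in PC space."""
    if clusters.n_clusters < 2:
        raise ValueError("principal graph requires at least 2 clusters")
    if not np.array_equal(embedding.obs_ids, clusters.cell_barcodes):
        raise ValueError("embedding and cluster assignment cover different cells")
    dims = min(n_dims_used, embedding.n_components)
    X = embedding.coords[:, :dims]
    centroids = np.vstack(
        [X[clusters.labels == c].mean(axis=0) for c in range(clusters.n_clusters)]
    )
    dist = cdist(centroids, centroids)
    mst = minimum_spanning_tree(sp.csr_matrix(dist))
    tree = nx.Graph()
    tree.add_nodes_from(range(clusters.n_clusters))
    coo = mst.tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        tree.add_edge(int(i), int(j), weight=float(w))
    return TrajectoryGraph(centroids, tree, dims)


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Project points p onto segment [a, b]; return (t in [0,1], squared distance)."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(p))
    proj = a + t[:, None] * ab
    d2 = ((p - proj) ** 2).sum(axis=1)
    return t, d2


def order_cells(
    embedding: EmbeddingResult,
    graph: TrajectoryGraph,
    root_cluster: int,
    max_projection_quantile: float | None = None,
) -> PseudotimeAssignment:
    """Order cells along the principal tree from a root cluster.

    Each cell is projected onto its nearest tree edge; its pseudotime is
    the geodesic distance along the tree from the root centroid to the
    projection point, shifted so the earliest cell (at or behind the root
    centroid) sits at 0. ``max_projection_quantile`` excludes
    cells whose perpendicular distance to the tree exceeds that quantile —
    off-trajectory populations such as contaminating monocytes — marking
    them NaN.
    """
    if root_cluster not in graph.tree:
        raise ValueError(f"root cluster {root_cluster} is not a node of the trajectory")
    X = embedding.coords[:, : graph.n_dims_used]
    n_cells = X.shape[0]

    # geodesic distance from the root centroid to every node
    node_dist = nx.single_source_dijkstra_path_length(
        graph.tree, root_cluster, weight="weight"
    )

    edges = list(graph.tree.edges(data="weight"))
    best_d2 = np.full(n_cells, np.inf)
    best_p = np.zeros(n_cells)
    for u, v, w in edges:
        a, b = graph.centroids[u], graph.centroids[v]
        t, d2 = _project_to_segment(X, a, b)
        # geodesic position of the projection point measured from the root
        along = np.minimum(node_dist[u] + t * w, node_dist[v] + (1 - t) * w)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_p[better] = along[better]

    values = best_p.copy()
    if max_projection_quantile is not None:
        cutoff = np.quantile(np.sqrt(best_d2), max_projection_quantile)
        values[np.sqrt(best_d2) > cutoff] = np.nan

    # anchor: the earliest projection (a cell at/behind the root centroid)
    # defines pseudotime 0, so values are non-negative with minimum exactly 0
    finite = np.isfinite(values)
    if finite.any():
        values[finite] -= values[finite].min()
    return PseudotimeAssignment(values, embedding.obs_ids, root_cluster)


def bin_expression(
    norm: NormalizedMatrix,
    pseudotime: PseudotimeAssignment,
    genes,
    n_bins: int = 25,
    states: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned pseudotime expression profiles.

    Cells on the trajectory are split into ``n_bins`` equal-width bins over
    [min P, max P] (last bin right-inclusive). For each requested gene and
    bin the mean and SD of normalized expression are reported, together
    with the bin's cell count and, if per-cell state labels are given, the
    modal state. Empty bins report NaN means, not zero.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    genes = np.asarray(genes, dtype=object)
    gidx = pd.Index(norm.gene_ids).get_indexer(genes)
    if (gidx < 0).any():
        raise KeyError(f"genes not found: {list(genes[gidx < 0][:5])}")
    if not np.array_equal(norm.cell_barcodes, pseudotime.cell_barcodes):
        raise ValueError("normalized matrix and pseudotime cover different cells")

    on = pseudotime.on_trajectory
    p = pseudotime.values[on]
    lo, hi = p.min(), p.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_bins - 1)

    dense = np.asarray(norm.values[gidx][:, np.flatnonzero(on)].todense())
    states_on = np.asarray(states, dtype=object)[on] if states is not None else None

    rows = []
    for b in range(n_bins):
        in_bin = which == b
        n_in = int(in_bin.sum())
        center = 0.5 * (edges[b] + edges[b + 1])
        if states_on is not None and n_in:
            vals, cnts = np.unique(states_on[in_bin], return_counts=True)
            modal = vals[np.argmax(cnts)]
        else:
            modal = None
        for gi, gene in enumerate(genes):
            if n_in:
                x = dense[gi, in_bin]
                mean, sd = float(x.mean()), float(x.std(ddof=0))
            else:
                mean, sd = np.nan, np.nan
            rows.append((gene, b, center, n_in, mean, sd, modal))
    return pd.DataFrame(
        rows,
        columns=["gene", "bin", "bin_center", "n_cells", "mean", "sd", "modal_state"],
    )
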