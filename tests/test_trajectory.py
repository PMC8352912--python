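import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from napctraj import ClusterAssignment, EmbeddingResult, NormalizedMatrix
from napctraj.trajectory import (
    PseudotimeAssignment,
    bin_expression,
    learn_principal_graph,
    order_cells,
)


def _embedding(coords):
    coords = np.asarray(coords, dtype=float)
    return EmbeddingResult(
        coords, np.zeros(coords.shape[1]), np.zeros((coords.shape[1], 0)),
        np.array([f"c{i}" for i in range(coords.shape[0])], dtype=object),
        np.array([], dtype=object),
    )


def _clusters(labels):
    labels = np.asarray(labels)
    return ClusterAssignment(
        labels, np.array([f"c{i}" for i in range(len(labels))], dtype=object),
        resolution=1.0, seed=0,
    )


def _mst_weight_bruteforce(centroids):
    """Minimum spanning-tree weight by enumerating all labeled trees (Pruefer)."""
    n = len(centroids)
    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        tree = nx.from_prufer_sequence(list(seq))
        w = sum(dist[u, v] for u, v in tree.edges)
        best = min(best, w)
    return best


class TestLearnPrincipalGraph:
    def test_collinear_centroids_form_path(self):
        emb = _embedding([[0.0], [0.1], [5.0], [5.1], [10.0], [10.1]])
        graph = learn_principal_graph(emb, _clusters([0, 0, 1, 1, 2, 2]),
                                      n_dims_used=1)
        assert graph.tree.degree[1] == 2
        assert graph.tree.degree[0] == 1 and graph.tree.degree[2] == 1

    def test_tree_invariant(self):
        rng = np.random.default_rng(0)
        emb = _embedding(rng.normal(size=(40, 3)))
        graph = learn_principal_graph(emb, _clusters(np.repeat([0, 1, 2, 3], 10)))
        assert graph.tree.number_of_edges() == graph.tree.number_of_nodes() - 1
        assert nx.is_connected(graph.tree)

    def test_mst_weight_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        centroids = rng.normal(size=(5, 2))
        # one cell per cluster placed exactly at each centroid
        emb = _embedding(centroids)
        graph = learn_principal_graph(emb, _clusters([0, 1, 2, 3, 4]), n_dims_used=2)
        weight = sum(w for _, _, w in graph.tree.edges(data="weight"))
        assert weight == pytest.approx(_mst_weight_bruteforce(centroids), abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            learn_principal_graph(_embedding([[0.0], [1.0]]), _clusters([0, 0]))


class TestOrderCells:
    def test_root_centroid_cell_is_zero_and_chain_geodesic(self):
        # clusters at x = 0, 3, 5; cells sit exactly on the centroids
        emb = _embedding([[0.0], [0.0], [3.0], [3.0], [5.0], [5.0]])
        clusters = _clusters([0, 0, 1, 1, 2, 2])
        graph = learn_principal_graph(emb, clusters, n_dims_used=1)
        p = order_cells(emb, graph, root_cluster=0)
        assert p.values[0] == pytest.approx(0.0)
        assert p.values[2] == pytest.approx(3.0)
        # far centroid: sum of the two edge lengths
        assert p.values[4] == pytest.approx(5.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(50, 2))
        labels = (coords[:, 0] > 0).astype(int)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        emb1, emb2 = _embedding(coords), _embedding(coords @ R.T)
        g1 = learn_principal_graph(emb1, _clusters(labels), n_dims_used=2)
        g2 = learn_principal_graph(emb2, _clusters(labels), n_dims_used=2)
        p1 = order_cells(emb1, g1, 0)
        p2 = order_cells(emb2, g2, 0)
        assert np.allclose(p1.values, p2.values, atol=1e-10)

    def test_offtrajectory_cells_excluded_by_quantile(self):
        # tree learned on the backbone clusters; contaminants sit far off it
        backbone = np.column_stack([np.linspace(0, 10, 40), np.zeros(40)])
        contaminants = np.array([[5.0, 50.0]] * 4)
        labels = np.array([0] * 20 + [1] * 20)
        graph = learn_principal_graph(_embedding(backbone), _clusters(labels),
                                      n_dims_used=2)
        emb_all = _embedding(np.vstack([backbone, contaminants]))
        p = order_cells(emb_all, graph, 0, max_projection_quantile=40 / 44)
        assert np.isnan(p.values[-4:]).all()
        assert np.isfinite(p.values[:40]).all()

    def test_unknown_root_rejected(self):
        emb = _embedding([[0.0], [1.0]])
        graph = learn_principal_graph(emb, _clusters([0, 1]), n_dims_used=1)
        with pytest.raises(ValueError, match="root"):
            order_cells(emb, graph, root_cluster=9)

    def test_recovers_latent_order(self, default_sim):
        """Monotone recovery of true pseudotime on the default simulation."""
        from scipy.stats import spearmanr

        from napctraj.cluster import graph_cluster, knn_graph
        from napctraj.preprocess import normalize_log, pca, scale_center, select_hvg
        from napctraj.qc import cell_rna_qc, combine_qc, filter_cells, hashtag_demux

        _, counts, hto, truth = default_sim
        kept = filter_cells(counts, combine_qc(cell_rna_qc(counts),
                                               hashtag_demux(hto)))
        norm = normalize_log(kept)
        emb = pca(scale_center(norm, select_hvg(norm, n_top=300)), n_pcs=30)
        clusters = graph_cluster(knn_graph(emb), resolution=0.3, seed=0)
        graph = learn_principal_graph(emb, clusters)
        true_p = truth.cells.loc[kept.cell_barcodes, "true_pseudotime"].to_numpy()
        root = int(np.argmin([
            np.nanmean(true_p[clusters.labels == c])
            for c in range(clusters.n_clusters)
        ]))
        p = order_cells(emb, graph, root)
        rho = spearmanr(p.values, true_p).statistic
        assert rho >= 0.8


def _norm(values):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        sp.csr_matrix(values),
        np.array([f"g{i}" for i in range(values.shape[0])], dtype=object),
        np.array([f"c{i}" for i in range(values.shape[1])], dtype=object),
    )


def _ptime(values):
    values = np.asarray(values, dtype=float)
    return PseudotimeAssignment(
        values, np.array([f"c{i}" for i in range(len(values))], dtype=object),
        root_cluster=0,
    )


class TestBinExpression:
    def test_uniform_cells_fill_bins_evenly(self):
        p = _ptime(np.arange(100) / 99.0)
        profile = bin_expression(_norm(np.ones((1, 100))), p, ["g0"], n_bins=25)
        assert (profile["n_cells"] == 4).all()
        assert profile["n_cells"].sum() == 100

    def test_constant_gene_zero_sd(self):
        p = _ptime(np.linspace(0, 1, 50))
        profile = bin_expression(_norm(np.full((1, 50), 2.5)), p, ["g0"], n_bins=5)
        assert (profile["mean"] == 2.5).all()
        assert (profile["sd"] == 0.0).all()

    def test_two_bin_hand_computation(self):
        vals = np.array([[0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]])
        p = _ptime(np.arange(10) / 9.0)
        profile = bin_expression(_norm(vals), p, ["g0"], n_bins=2)
        # bins split at 0.5: cells 0-4 (p<0.5) and 5-9 (last bin right-inclusive)
        assert profile.loc[0, "mean"] == pytest.approx(np.mean([0, 1, 2, 3, 4]))
        assert profile.loc[1, "mean"] == pytest.approx(np.mean([5, 6, 7, 8, 9]))
        assert profile.loc[0, "sd"] == pytest.approx(np.std([0, 1, 2, 3, 4]))

    def test_empty_bin_reports_missing(self):
        p = _ptime([0.0, 0.01, 1.0])
        profile = bin_expression(_norm([[1.0, 2.0, 3.0]]), p, ["g0"], n_bins=4)
        assert profile["n_cells"].tolist() == [2, 0, 0, 1]
        assert np.isnan(profile.loc[1, "mean"]) and np.isnan(profile.loc[2, "mean"])

    def test_modal_state_per_bin(self):
        p = _ptime(np.linspace(0, 1, 8))
        states = np.array(["a", "a", "a", "b", "b", "b", "b", "b"], dtype=object)
        profile = bin_expression(_norm(np.ones((1, 8))), p, ["g0"], n_bins=2,
                                 states=states)
        assert profile.loc[0, "modal_state"] == "a"
        assert profile.loc[1, "modal_state"] == "b"

    def test_marker_trends_along_recovered_pseudotime(self, default_sim):
        """Down-marker falls and up-marker rises along the latent axis."""
        from napctraj.preprocess import normalize_log
        _, counts, _, truth = default_sim
        genes = truth.genes
        down = genes[genes.true_beta1 < 0].index[0]
        up = genes[genes.true_beta1 > 0].index[0]
        tp = truth.cells["true_pseudotime"].to_numpy()
        ok = np.isfinite(tp)
        sub = counts.subset_cells(ok)
        norm = normalize_log(sub)
        p = PseudotimeAssignment(tp[ok] - tp[ok].min(), sub.cell_barcodes, 0)
        profile = bin_expression(norm, p, [down, up], n_bins=25)
        for gene, sign in ((down, -1), (up, +1)):
            means = profile[profile.gene == gene].sort_values("bin")["mean"]
            slope = np.polyfit(np.arange(len(means)), means.to_numpy(), 1)[0]
            assert np.sign(slope) == sign
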