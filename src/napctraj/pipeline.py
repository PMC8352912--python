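"""End-to-end orchestration of the two analysis shapes.

``run_learn`` executes the full in vitro chain — QC, normalization,
variable genes, PCA, clustering, principal-graph pseudotime, per-gene
Poisson pseudotime regression, trajectory gene selection and scoring,
binned profiles — writing every intermediate as TSV plus a manifest of
parameter values, seeds and artifact hashes. ``run_transfer`` applies a
previously learned trajectory gene set to new single-cell or bulk data
(QC and normalization only; no refitting).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .cluster import graph_cluster, harmonize, knn_graph, marker_auc, pseudobulk
from .containers import BulkExpressionTable, HashtagMatrix, UMICountMatrix
from .glm import PoissonPseudotimeModel, TrajectoryGeneSet
from .preprocess import normalize_log, pca, scale_center, select_hvg
from .qc import QCThresholds, bulk_common_gene_qc, cell_rna_qc, combine_qc, \
    filter_cells, hashtag_demux
from .scores import trajectory_gene_score
from .simulate import SimulationConfig, simulate_trajectory_counts
from .trajectory import bin_expression, learn_principal_graph, order_cells

logger = logging.getLogger("napctraj")

__all__ = ["LearnConfig", "run_learn", "run_transfer"]


@dataclass
class LearnConfig:
    """Parameters of a trajectory-learning run.

    Input is either a simulation config or file paths to a count matrix
    and hashtag table. ``root_cluster="auto"`` picks the cluster whose
    cells have the smallest mean true pseudotime (requires simulation
    truth or a truth table path) — the synthetic analogue of designating
    the known starting population as the root.
    """

    simulation: SimulationConfig | None = None
    counts_mtx: str | None = None
    counts_genes: str | None = None
    counts_barcodes: str | None = None
    hto_path: str | None = None
    truth_cells_path: str | None = None

    qc: QCThresholds = field(default_factory=QCThresholds)
    scale_factor: float = 1e4
    n_top_hvg: int = 300
    n_mean_bins: int = 20
    n_pcs: int = 50
    n_pcs_used: int = 15
    k: int = 15
    resolution: float = 0.3  # coarse: resolves broad states, not sub-clusters
    cluster_seed: int = 0
    root_cluster: int | str = "auto"
    max_projection_quantile: float | None = None
    alpha: float = 5e-5
    n_bins: int = 25
    n_profile_genes: int = 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: LearnConfig):
    if config.simulation is not None:
        counts, hto, truth = simulate_trajectory_counts(config.simulation)
        return counts, hto, truth.cells
    for name in ("counts_mtx", "counts_genes", "counts_barcodes", "hto_path"):
        if getattr(config, name) is None:
            raise ValueError(f"either a simulation config or {name} is required")
    counts = nio.read_counts(
        config.counts_mtx, config.counts_genes, config.counts_barcodes
    )
    hto = nio.read_hashtags(config.hto_path)
    truth_cells = (
        nio.read_table(config.truth_cells_path)
        if config.truth_cells_path
        else None
    )
    return counts, hto, truth_cells


def _choose_root(clusters, truth_cells: pd.DataFrame, barcodes) -> int:
    """Root = cluster with the smallest mean true pseudotime of its cells."""
    p = truth_cells["true_pseudotime"].reindex(pd.Index(barcodes)).to_numpy(float)
    means = []
    for c in range(clusters.n_clusters):
        vals = p[clusters.labels == c]
        vals = vals[np.isfinite(vals)]
        means.append(vals.mean() if len(vals) else np.inf)
    return int(np.argmin(means))


def run_learn(config: LearnConfig, outdir: str | Path | None = None) -> dict:
    """Execute the trajectory-learning pipeline; returns the artifacts.

    When ``outdir`` is given every artifact is written as TSV and a
    ``manifest.json`` records the configuration, seeds and SHA-256 of each
    output, so two runs with the same config are byte-comparable.
    """
    t0 = time.time()
    counts, hto, truth_cells = _load_inputs(config)
    logger.info("loaded %d genes x %d cells", counts.n_genes, counts.n_cells)

    rna = cell_rna_qc(counts, config.qc)
    hashes = hashtag_demux(hto, config.qc)
    qc_report = combine_qc(rna, hashes)
    kept = filter_cells(counts, qc_report)
    logger.info("QC: %d of %d cells pass", kept.n_cells, counts.n_cells)
    if kept.n_cells == 0:
        raise RuntimeError("qc_filtering: no cells pass quality control")

    norm = normalize_log(kept, config.scale_factor)
    n_top = config.n_top_hvg
    hvg = select_hvg(norm, n_top=n_top, n_mean_bins=config.n_mean_bins)
    scaled = scale_center(norm, hvg)
    n_pcs = min(config.n_pcs, min(scaled.values.shape) - 1)
    embedding = harmonize(pca(scaled, n_pcs=n_pcs))
    graph = knn_graph(embedding, n_pcs_used=config.n_pcs_used, k=config.k)
    clusters = graph_cluster(graph, resolution=config.resolution,
                             seed=config.cluster_seed)
    logger.info("clustering: %d clusters", clusters.n_clusters)

    if config.root_cluster == "auto":
        if truth_cells is None:
            raise ValueError(
                "root_cluster='auto' requires simulation truth; pass an explicit root"
            )
        root = _choose_root(clusters, truth_cells, kept.cell_barcodes)
    else:
        root = int(config.root_cluster)

    tree = learn_principal_graph(embedding, clusters, n_dims_used=config.n_pcs_used)
    ptime = order_cells(
        embedding, tree, root,
        max_projection_quantile=config.max_projection_quantile,
    )

    model = PoissonPseudotimeModel(kept, ptime)
    results = model.fit()
    gene_set = results.select_genes(config.alpha)
    logger.info("trajectory genes: %d at alpha=%g", len(gene_set), config.alpha)

    scores = trajectory_gene_score(norm, gene_set) if len(gene_set) else pd.Series(
        dtype=float, name="trajectory_score"
    )

    profiles = None
    if len(gene_set) >= 1:
        order = np.argsort(-np.abs(gene_set.beta1))
        profile_genes = gene_set.genes[order[: config.n_profile_genes]]
        states = np.array(
            [f"cluster_{c}" for c in clusters.labels], dtype=object
        )
        profiles = bin_expression(norm, ptime, profile_genes,
                                  n_bins=config.n_bins, states=states)

    artifacts = {
        "qc_report": qc_report,
        "counts": kept,
        "normalized": norm,
        "hvg": hvg,
        "embedding": embedding,
        "clusters": clusters,
        "trajectory_graph": tree,
        "root_cluster": root,
        "pseudotime": ptime,
        "glm_results": results,
        "gene_set": gene_set,
        "scores": scores,
        "binned_profiles": profiles,
    }
    logger.info("learn run finished in %.1f s", time.time() - t0)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}

        def _write(name: str, df: pd.DataFrame):
            path = outdir / f"{name}.tsv"
            nio.write_table(df, path)
            files[name] = _sha256(path)

        _write("qc_report", qc_report)
        _write("clusters", pd.DataFrame(
            {"cluster": clusters.labels},
            index=pd.Index(clusters.cell_barcodes, name="barcode")))
        _write("pseudotime", ptime.to_series().to_frame())
        _write("glm_fits", results.table)
        _write("trajectory_genes", gene_set.to_frame())
        _write("scores", scores.to_frame())
        if profiles is not None:
            _write("binned_profiles", profiles)
        manifest = {
            "config": json.loads(json.dumps(config.to_dict(), default=str)),
            "root_cluster": root,
            "artifacts": files,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        artifacts["manifest"] = manifest
    return artifacts


def run_transfer(
    gene_set: TrajectoryGeneSet,
    counts: UMICountMatrix | None = None,
    hto: HashtagMatrix | None = None,
    bulk: BulkExpressionTable | None = None,
    qc_thresholds: QCThresholds | None = None,
    scale_factor: float = 1e4,
    min_overlap_frac: float = 0.5,
    outdir: str | Path | None = None,
) -> pd.Series:
    """Apply a learned trajectory gene set to held-out data (no refit).

    Single-cell input gets RNA QC (plus hashing QC when a hashtag matrix
    is provided) and log normalization before scoring; bulk input is
    scored on the log1p(TPM) layer after common-gene QC. Raises when the
    gene-set overlap with the data falls below ``min_overlap_frac``.
    """
    if (counts is None) == (bulk is None):
        raise ValueError("provide exactly one of counts= or bulk=")
    if counts is not None:
        report = cell_rna_qc(counts, qc_thresholds)
        if hto is not None:
            report = combine_qc(report, hashtag_demux(hto, qc_thresholds))
            col = "pass"
        else:
            col = "rna_pass"
        kept = filter_cells(counts, report, column=col)
        if kept.n_cells == 0:
            raise RuntimeError("no cells pass quality control")
        expr = normalize_log(kept, scale_factor)
        target_genes = expr.gene_ids
    else:
        bulk_common_gene_qc(bulk)
        expr = bulk
        target_genes = bulk.gene_ids

    overlap = np.isin(gene_set.genes, target_genes).mean()
    if overlap < min_overlap_frac:
        raise ValueError(
            f"gene-set overlap {overlap:.0%} below the floor {min_overlap_frac:.0%}"
        )
    scores = trajectory_gene_score(expr, gene_set)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_table(scores.to_frame(), outdir / "transfer_scores.tsv")
    return scores
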