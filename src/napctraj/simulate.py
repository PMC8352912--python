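"""Synthetic hashed single-cell data with a known differentiation trajectory.

The generator inverts the pipeline's own regression model: each gene has a
log base rate beta0 and a log-rate slope beta1 on a latent pseudotime P in
[0, pseudotime_max], and counts are Poisson with mean
``L_j * exp(beta0_i + beta1_i * P_j)`` where L_j is a log-normal per-cell
library scale. A configurable fraction of genes carries slope
``+/- beta1_effect``; the rest are trajectory-null. Discrete cell states
are deterministic functions of pseudotime via ordered breakpoints, and
each state elevates a small disjoint set of marker genes so clustering has
signal beyond the continuous trajectory. Mitochondrial genes are ordinary
null genes flagged by the "mt-" name prefix with a rate multiplier that
controls their UMI share. Hashtag counts are multinomial with a dominant
fraction on each cell's true hashtag; doublet barcodes sum the RNA and
hashtag counts of two latent cells, which is exactly the signal the
ratio-based hashing QC is designed to reject. An optional off-trajectory
contaminant population (a monocyte-like bystander) has no pseudotime and
its own markers.

The per-cell offset used downstream is the *realized* library size (column
sum), not the latent scale L_j, mirroring what any consumer of real data
can compute.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import BulkExpressionTable, HashtagMatrix, UMICountMatrix
from .immuno import CytotoxicityCounts

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_trajectory_counts",
    "simulate_bulk",
    "simulate_ctl_counts",
]


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters (defaults are the reference conditions)."""

    n_cells: int = 2000
    n_genes: int = 1000
    n_hashtags: int = 4
    frac_trajectory_genes: float = 0.10
    beta1_effect: float = 1.0
    pseudotime_max: float = 1.0
    libsize_log_mean: float = math.log(5000.0)
    libsize_log_sd: float = 0.25
    frac_mito_genes: float = 0.02
    mito_rate_multiplier: float = 1.5
    doublet_rate: float = 0.05
    hto_dominant_frac: float = 0.95
    hto_mean_umi: float = 200.0
    state_breakpoints: tuple[float, ...] = (0.5,)
    n_marker_genes_per_state: int = 15
    marker_log_fc: float = 1.5
    frac_contaminant: float = 0.0
    contaminant_n_markers: int = 20
    contaminant_log_fc: float = 2.0
    n_bulk_samples: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_trajectory_genes", "frac_mito_genes", "doublet_rate",
                     "frac_contaminant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.hto_dominant_frac <= 1.0:
            raise ValueError("hto_dominant_frac must be in (0, 1]")
        for name in ("n_cells", "n_genes", "n_hashtags", "n_bulk_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pseudotime_max <= 0:
            raise ValueError("pseudotime_max must be positive")
        bp = tuple(self.state_breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("state_breakpoints must be strictly increasing")
        if bp and (bp[0] <= 0 or bp[-1] >= self.pseudotime_max):
            raise ValueError("state_breakpoints must lie inside (0, pseudotime_max)")
        expected_total = math.exp(self.libsize_log_mean + 0.5 * self.libsize_log_sd**2)
        if expected_total < 1.0:
            raise ValueError(
                f"expected total counts per cell ({expected_total:.3g}) < 1: "
                "degenerate simulation"
            )

    @property
    def n_states(self) -> int:
        return len(self.state_breakpoints) + 1


@dataclass
class TruthTable:
    """Ground truth of a simulation: one row per cell and per gene.

    ``cells`` columns: true_pseudotime (NaN for contaminants), true_state,
    true_hashtag, is_doublet. ``genes`` columns: true_beta0, true_beta1,
    is_mito, marker_state.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame


def _state_of(p: np.ndarray, breakpoints: tuple[float, ...]) -> np.ndarray:
    idx = np.searchsorted(np.asarray(breakpoints), p, side="right")
    return np.array([f"state_{i}" for i in idx], dtype=object)


def simulate_trajectory_counts(
    config: SimulationConfig,
) -> tuple[UMICountMatrix, HashtagMatrix, TruthTable]:
    """Simulate a hashed UMI matrix with known trajectory ground truth.

    Identical config (including seed) gives bit-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- genes -----------------------------------------------------------
    n_mito = int(round(cfg.frac_mito_genes * cfg.n_genes))
    is_mito = np.zeros(cfg.n_genes, dtype=bool)
    mito_idx = rng.choice(cfg.n_genes, size=n_mito, replace=False) if n_mito else []
    is_mito[mito_idx] = True
    gene_ids = np.array(
        [
            f"mt-Sim{i:04d}" if is_mito[i] else f"Gene{i:04d}"
            for i in range(cfg.n_genes)
        ],
        dtype=object,
    )

    raw = rng.lognormal(0.0, 1.0, cfg.n_genes)
    raw[is_mito] *= cfg.mito_rate_multiplier
    weights = raw / raw.sum()
    beta0 = np.log(weights)

    n_traj = int(round(cfg.frac_trajectory_genes * cfg.n_genes))
    eligible = np.flatnonzero(~is_mito)
    traj_idx = rng.choice(eligible, size=n_traj, replace=False) if n_traj else np.array([], int)
    beta1 = np.zeros(cfg.n_genes)
    beta1[traj_idx] = rng.choice([-cfg.beta1_effect, cfg.beta1_effect], size=n_traj)

    marker_state = np.full(cfg.n_genes, "", dtype=object)
    pool = np.setdiff1d(eligible, traj_idx)
    rng.shuffle(pool)
    cursor = 0
    for s in range(cfg.n_states):
        take = pool[cursor : cursor + cfg.n_marker_genes_per_state]
        marker_state[take] = f"state_{s}"
        cursor += cfg.n_marker_genes_per_state
    contam_markers = pool[cursor : cursor + cfg.contaminant_n_markers] \
        if cfg.frac_contaminant > 0 else np.array([], int)
    if cfg.frac_contaminant > 0:
        marker_state[contam_markers] = "contaminant"

    # --- latent cells ----------------------------------------------------
    n_doublets = int(round(cfg.doublet_rate * cfg.n_cells))
    n_singlets = cfg.n_cells - n_doublets
    n_latent = n_singlets + 2 * n_doublets

    n_contam = int(round(cfg.frac_contaminant * n_latent))
    is_contam = np.zeros(n_latent, dtype=bool)
    if n_contam:
        is_contam[rng.choice(n_latent, size=n_contam, replace=False)] = True

    p_latent = rng.uniform(0.0, cfg.pseudotime_max, n_latent)
    p_latent[is_contam] = np.nan
    state_latent = np.full(n_latent, "contaminant", dtype=object)
    on_traj = ~is_contam
    state_latent[on_traj] = _state_of(p_latent[on_traj], cfg.state_breakpoints)

    L = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd, n_latent)
    hashtag_latent = rng.integers(0, cfg.n_hashtags, n_latent)

    # rate matrix genes x latent cells
    log_rate = beta0[:, None] + np.where(
        on_traj[None, :], beta1[:, None] * np.nan_to_num(p_latent)[None, :], 0.0
    )
    for s in range(cfg.n_states):
        cells_s = state_latent == f"state_{s}"
        genes_s = marker_state == f"state_{s}"
        if cells_s.any() and genes_s.any():
            log_rate[np.ix_(genes_s, cells_s)] += cfg.marker_log_fc
    if n_contam and len(contam_markers):
        log_rate[np.ix_(np.isin(np.arange(cfg.n_genes), contam_markers), is_contam)] \
            += cfg.contaminant_log_fc

    rate = L[None, :] * np.exp(log_rate)
    counts_latent = rng.poisson(rate)

    # hashtag counts: multinomial with dominant fraction on the true tag
    hto_totals = rng.poisson(cfg.hto_mean_umi, n_latent)
    hto_latent = np.zeros((cfg.n_hashtags, n_latent), dtype=np.int64)
    off = (1.0 - cfg.hto_dominant_frac) / max(cfg.n_hashtags - 1, 1)
    for j in range(n_latent):
        probs = np.full(cfg.n_hashtags, off)
        probs[hashtag_latent[j]] = cfg.hto_dominant_frac
        probs /= probs.sum()
        hto_latent[:, j] = rng.multinomial(hto_totals[j], probs)

    # --- assemble barcodes (singlets then doublets) ----------------------
    counts = np.empty((cfg.n_genes, cfg.n_cells), dtype=np.int64)
    hto = np.empty((cfg.n_hashtags, cfg.n_cells), dtype=np.int64)
    counts[:, :n_singlets] = counts_latent[:, :n_singlets]
    hto[:, :n_singlets] = hto_latent[:, :n_singlets]
    first = n_singlets + 2 * np.arange(n_doublets)
    second = first + 1
    if n_doublets:
        counts[:, n_singlets:] = counts_latent[:, first] + counts_latent[:, second]
        hto[:, n_singlets:] = hto_latent[:, first] + hto_latent[:, second]

    barcodes = np.array([f"CELL{i:05d}" for i in range(cfg.n_cells)], dtype=object)
    primary = np.concatenate([np.arange(n_singlets), first]).astype(int)
    libsize = L[primary].copy()
    if n_doublets:
        libsize[n_singlets:] = L[first] + L[second]
    cells = pd.DataFrame(
        {
            "true_pseudotime": p_latent[primary],
            "true_state": state_latent[primary],
            "true_hashtag": [f"HTO{h}" for h in hashtag_latent[primary]],
            "is_doublet": np.concatenate(
                [np.zeros(n_singlets, bool), np.ones(n_doublets, bool)]
            ),
            "true_libsize": libsize,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    genes = pd.DataFrame(
        {
            "true_beta0": beta0,
            "true_beta1": beta1,
            "is_mito": is_mito,
            "marker_state": marker_state,
        },
        index=pd.Index(gene_ids, name="gene"),
    )

    umi = UMICountMatrix(sp.csr_matrix(counts), gene_ids, barcodes)
    hashes = HashtagMatrix(
        hto, np.array([f"HTO{h}" for h in range(cfg.n_hashtags)], dtype=object),
        barcodes,
    )
    return umi, hashes, TruthTable(cells, genes)


def simulate_bulk(
    counts: UMICountMatrix,
    groups,
    seed: int = 0,
    resample: bool = True,
) -> BulkExpressionTable:
    """Pseudo-bulk-derived bulk samples in TPM units.

    ``groups`` labels every cell with its bulk sample of origin (a Series
    indexed by barcode or an array aligned to the cells). Per group, a
    bootstrap resample of its cells (or the exact cells when
    ``resample=False``) is summed and scaled so each sample column sums to
    1e6.
    """
    if isinstance(groups, pd.Series):
        groups = groups.reindex(pd.Index(counts.cell_barcodes)).to_numpy(object)
    groups = np.asarray(groups, dtype=object)
    if len(groups) != counts.n_cells:
        raise ValueError("one group label per cell required")
    if any(g is None or (isinstance(g, float) and np.isnan(g)) for g in groups):
        raise ValueError("every cell must have a group label")
    rng = np.random.default_rng(seed)
    labels = pd.unique(groups)
    csc = counts.counts.tocsc()
    cols = {}
    for g in labels:
        members = np.flatnonzero(groups == g)
        if len(members) == 0:
            raise ValueError(f"empty group: {g}")
        chosen = rng.choice(members, size=len(members), replace=True) if resample \
            else members
        total = np.asarray(csc[:, chosen].sum(axis=1)).ravel().astype(float)
        s = total.sum()
        if s == 0:
            raise ValueError(f"group {g} has zero total counts")
        cols[str(g)] = total * (1e6 / s)
    df = pd.DataFrame(cols, index=pd.Index(counts.gene_ids, name="gene"))
    return BulkExpressionTable(df, units="TPM")


def simulate_ctl_counts(
    true_lysis_frac: float, n_events: int, seed: int = 0
) -> CytotoxicityCounts:
    """Simulate the event counts of the in vivo CTL killing assay.

    The naive animal keeps balanced pulsed/unpulsed targets
    (a = b = n_events); in the primed animal the pulsed population is
    binomially thinned with survival probability 1 - true_lysis_frac, so
    the specific-cytotoxicity statistic estimates 100 * true_lysis_frac.
    """
    if not 0.0 <= true_lysis_frac <= 1.0:
        raise ValueError("true_lysis_frac must be in [0, 1]")
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(seed)
    x = int(rng.binomial(n_events, 1.0 - true_lysis_frac))
    return CytotoxicityCounts(x=x, y=n_events, a=n_events, b=n_events)
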