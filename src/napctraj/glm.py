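"""Per-gene Poisson regression of UMI counts on pseudotime.

The core statistic of the pipeline. For gene *i* and cell *j* the model is

    X_ij ~ Poisson(mu_ij),   log mu_ij = beta0_i + beta1_i * P_j + log nUMI_j

i.e. a Poisson log-linear model of counts on pseudotime with the cell's
total UMI as an exposure offset. beta1_i is the log-rate slope per unit
pseudotime; its two-sided Wald p-value (from the observed information at
the maximum) drives the trajectory gene selection, and the fitted slopes
weight the trajectory gene score.

Fitting is iteratively reweighted least squares (IRLS) with the canonical
log link, vectorized across genes: the design [1, P_j] is shared by every
gene, so each IRLS step reduces to a batched 2x2 weighted-least-squares
solve. Convergence is declared when the deviance changes by less than
``tol``; genes that overshoot use step-halving. Genes with zero total
count are not estimable and are returned flagged with beta1 = 0, p = 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm as normal

from .containers import UMICountMatrix
from .trajectory import PseudotimeAssignment

__all__ = [
    "PoissonPseudotimeModel",
    "TrajectoryGLMResults",
    "TrajectoryGeneSet",
    "fit_pseudotime_glm",
    "select_trajectory_genes",
]

_ETA_CAP = 30.0  # linear predictor clip to keep exp() finite during iteration


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Row-wise Poisson log-likelihood (full, with the y! term)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return (term - mu - gammaln(y + 1)).sum(axis=1)


@dataclass
class TrajectoryGeneSet:
    """Genes whose Poisson slope on pseudotime is significant, with their slopes."""

    genes: np.ndarray
    beta1: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if len(self.genes) != len(self.beta1):
            raise ValueError("one slope per gene required")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in gene set")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta1": self.beta1},
                            index=pd.Index(self.genes, name="gene"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, alpha: float = float("nan")
                   ) -> "TrajectoryGeneSet":
        return cls(df.index.to_numpy(object), df["beta1"].to_numpy(float), alpha)


class PoissonPseudotimeModel:
    """Poisson pseudotime regression over every gene of a count matrix.

    Parameters
    ----------
    counts
        UMI count matrix (genes x cells). Cells must align with ``pseudotime``.
    pseudotime
        Per-cell trajectory ordering; cells with NaN pseudotime (off the
        trajectory) are dropped from the fit.
    exposure
        Per-cell offset exposure; defaults to the realized library sizes
        (column sums of ``counts``). Must be positive.
    """

    def __init__(
        self,
        counts: UMICountMatrix,
        pseudotime: PseudotimeAssignment | np.ndarray,
        exposure: np.ndarray | None = None,
    ):
        if isinstance(pseudotime, PseudotimeAssignment):
            if not np.array_equal(counts.cell_barcodes, pseudotime.cell_barcodes):
                raise ValueError("counts and pseudotime cover different cells")
            p = pseudotime.values
        else:
            p = np.asarray(pseudotime, dtype=float)
            if len(p) != counts.n_cells:
                raise ValueError("one pseudotime per cell required")
        keep = np.isfinite(p)
        if exposure is None:
            exposure = counts.n_umi.astype(float)
        else:
            exposure = np.asarray(exposure, dtype=float)
        if np.any(exposure[keep] <= 0):
            raise ValueError("exposure (nUMI) must be positive for all fitted cells")
        self.counts = counts
        self.p = p[keep]
        self.exposure = exposure[keep]
        self._keep = keep
        if np.ptp(self.p) == 0:
            raise ValueError(
                "pseudotime is constant across cells; the slope is not estimable"
            )

    @classmethod
    def from_dataframe(cls, counts_df: pd.DataFrame, pseudotime: pd.Series,
                       exposure: pd.Series | None = None) -> "PoissonPseudotimeModel":
        """Build from a dense genes x cells DataFrame and an aligned Series."""
        import scipy.sparse as sp

        umi = UMICountMatrix(
            sp.csr_matrix(counts_df.to_numpy()),
            counts_df.index.to_numpy(object),
            counts_df.columns.to_numpy(object),
        )
        p = pseudotime.reindex(counts_df.columns).to_numpy(float)
        ex = exposure.reindex(counts_df.columns).to_numpy(float) if exposure is not None else None
        return cls(umi, p, ex)

    def fit(self, max_iter: int = 50, tol: float = 1e-8, chunk_size: int = 2048
            ) -> "TrajectoryGLMResults":
        """Fit every gene by IRLS; returns a results object."""
        Y = np.asarray(self.counts.counts[:, np.flatnonzero(self._keep)].todense(),
                       dtype=float)
        n_genes, n_cells = Y.shape
        offset = np.log(self.exposure)
        p = self.p

        beta0 = np.full(n_genes, np.nan)
        beta1 = np.zeros(n_genes)
        se0 = np.full(n_genes, np.nan)
        se1 = np.full(n_genes, np.nan)
        converged = np.zeros(n_genes, dtype=bool)
        n_iter = np.zeros(n_genes, dtype=int)
        flags = np.full(n_genes, "", dtype=object)

        totals = Y.sum(axis=1)
        zero = totals == 0
        flags[zero] = "zero_count"
        beta1[zero] = 0.0

        active_genes = np.flatnonzero(~zero)
        for start in range(0, len(active_genes), chunk_size):
            idx = active_genes[start : start + chunk_size]
            b0, b1, s0, s1, conv, iters = _irls_chunk(
                Y[idx], p, offset, max_iter=max_iter, tol=tol
            )
            beta0[idx], beta1[idx] = b0, b1
            se0[idx], se1[idx] = s0, s1
            converged[idx] = conv
            n_iter[idx] = iters
            flags[idx[~conv]] = "not_converged"

        # complete/quasi-separation: the slope runs away along the pseudotime
        # range (rate ratio beyond e^20 is not identifiable from UMI counts)
        runaway = np.abs(beta1) * np.ptp(p) > 20.0
        converged[runaway] = False
        flags[runaway] = "separated"

        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta1 / se1
        p_wald = np.where(np.isfinite(z), 2 * normal.sf(np.abs(z)), 1.0)
        p_wald[zero] = 1.0

        table = pd.DataFrame(
            {
                "beta0": beta0,
                "beta1": beta1,
                "se_beta1": se1,
                "wald_z": z,
                "p_value": p_wald,
                "converged": converged,
                "n_cells": n_cells,
                "flag": flags,
            },
            index=pd.Index(self.counts.gene_ids, name="gene"),
        )
        return TrajectoryGLMResults(self, table)

    def loglike(self, gene_idx: int, beta0: float, beta1: float) -> float:
        """Poisson log-likelihood of one gene at given coefficients."""
        y = np.asarray(
            self.counts.counts[gene_idx, np.flatnonzero(self._keep)].todense()
        ).ravel().astype(float)
        mu = self.exposure * np.exp(beta0 + beta1 * self.p)
        return float(_poisson_loglik(y[None, :], mu[None, :])[0])


def _irls_chunk(Y: np.ndarray, p: np.ndarray, offset: np.ndarray,
                max_iter: int, tol: float):
    """Batched IRLS for genes sharing the design [1, p] with offset.

    Returns (beta0, beta1, se0, se1, converged, n_iter) for the chunk.
    Step-halving (up to 20 halvings) is applied per gene whenever a full
    IRLS step fails to increase the log-likelihood.
    """
    n_genes, n_cells = Y.shape
    exposure = np.exp(offset)
    # moment start: beta0 from the mean rate, beta1 = 0
    with np.errstate(divide="ignore"):
        beta0 = np.log(Y.sum(axis=1) / exposure.sum())
    beta1 = np.zeros(n_genes)

    def eta_mu(b0, b1):
        eta = b0[:, None] + b1[:, None] * p[None, :] + offset[None, :]
        return np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))

    mu = eta_mu(beta0, beta1)
    ll = _poisson_loglik(Y, mu)

    active = np.ones(n_genes, dtype=bool)
    n_iter = np.zeros(n_genes, dtype=int)
    for it in range(max_iter):
        if not active.any():
            break
        a = np.flatnonzero(active)
        mu_a = mu[a]
        # weighted normal equations for design [1, p]
        w_sum = mu_a.sum(axis=1)
        w_p = mu_a @ p
        w_pp = mu_a @ (p * p)
        r = Y[a] - mu_a
        g0 = r.sum(axis=1)
        g1 = r @ p
        det = w_sum * w_pp - w_p**2
        det = np.where(det > 0, det, np.nan)
        d0 = (w_pp * g0 - w_p * g1) / det
        d1 = (w_sum * g1 - w_p * g0) / det
        d0 = np.nan_to_num(d0)
        d1 = np.nan_to_num(d1)

        # full Newton/IRLS step, then per-gene step-halving on decrease
        step = np.ones(len(a))
        new_b0 = beta0[a] + d0
        new_b1 = beta1[a] + d1
        new_mu = eta_mu(new_b0, new_b1)
        new_ll = _poisson_loglik(Y[a], new_mu)
        for _ in range(20):
            worse = new_ll < ll[a] - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
            new_b0[worse] = beta0[a][worse] + step[worse] * d0[worse]
            new_b1[worse] = beta1[a][worse] + step[worse] * d1[worse]
            new_mu[worse] = eta_mu(new_b0[worse], new_b1[worse])
            new_ll[worse] = _poisson_loglik(Y[a][worse], new_mu[worse])

        improved = new_ll >= ll[a] - 1e-12
        beta0[a] = np.where(improved, new_b0, beta0[a])
        beta1[a] = np.where(improved, new_b1, beta1[a])
        mu[a] = np.where(improved[:, None], new_mu, mu[a])
        done = np.abs(new_ll - ll[a]) < tol
        ll[a] = np.where(improved, new_ll, ll[a])
        n_iter[a] += 1
        still = np.flatnonzero(active)[~done]
        active = np.zeros(n_genes, dtype=bool)
        active[still] = True

    converged = ~active
    # observed information at the final iterate
    w_sum = mu.sum(axis=1)
    w_p = mu @ p
    w_pp = mu @ (p * p)
    det = w_sum * w_pp - w_p**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se0 = np.sqrt(np.where(det > 0, w_pp / det, np.nan))
        se1 = np.sqrt(np.where(det > 0, w_sum / det, np.nan))
    return beta0, beta1, se0, se1, converged, n_iter


class TrajectoryGLMResults:
    """Fitted per-gene Poisson pseudotime regressions.

    ``table`` holds one row per gene: beta0, beta1, se_beta1, wald_z,
    p_value, converged, n_cells, flag.
    """

    def __init__(self, model: PoissonPseudotimeModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def params(self) -> pd.DataFrame:
        return self.table[["beta0", "beta1"]]

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p_value"]

    def select_genes(self, alpha: float = 5e-5) -> TrajectoryGeneSet:
        """Genes with raw Wald p < alpha (strict); non-converged excluded.

        No multiple-testing adjustment is applied: the selection thresholds
        raw p-values, as the trajectory score definition requires. An empty
        selection returns an empty set with a warning.
        """
        ok = self.table["converged"] & (self.table["p_value"] < alpha)
        if not ok.any():
            warnings.warn("no genes pass the significance threshold", stacklevel=2)
        sel = self.table[ok]
        return TrajectoryGeneSet(
            sel.index.to_numpy(object), sel["beta1"].to_numpy(float), alpha
        )

    def summary(self, top: int = 10) -> str:
        """Plain-text summary of the fit."""
        t = self.table
        n_conv = int(t["converged"].sum())
        lines = [
            "Poisson pseudotime regression (log link, nUMI offset)",
            f"  genes: {len(t)}   cells: {int(t['n_cells'].iloc[0]) if len(t) else 0}",
            f"  converged: {n_conv}   zero-count: {(t['flag'] == 'zero_count').sum()}"
            f"   not converged: {(t['flag'] == 'not_converged').sum()}",
            "",
            f"Top {top} genes by |Wald z|:",
        ]
        show = t[t["converged"]].reindex(
            t[t["converged"]]["wald_z"].abs().sort_values(ascending=False).index
        ).head(top)
        lines.append(
            show[["beta0", "beta1", "se_beta1", "wald_z", "p_value"]]
            .to_string(float_format=lambda v: f"{v: .4g}")
        )
        return "\n".join(lines)


def fit_pseudotime_glm(
    counts: UMICountMatrix,
    pseudotime: PseudotimeAssignment | np.ndarray,
    exposure: np.ndarray | None = None,
    **fit_kwargs,
) -> TrajectoryGLMResults:
    """Functional wrapper: build the model and fit it."""
    return PoissonPseudotimeModel(counts, pseudotime, exposure).fit(**fit_kwargs)


def select_trajectory_genes(results: TrajectoryGLMResults, alpha: float = 5e-5
                            ) -> TrajectoryGeneSet:
    """Functional wrapper around :meth:`TrajectoryGLMResults.select_genes`."""
    return results.select_genes(alpha)
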