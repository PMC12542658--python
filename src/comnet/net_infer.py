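"""Taxon-taxon co-occurrence network inference.

Edges are cross-sample correlation coefficients between taxa: Pearson or
Spearman on relative abundances, or SparCC on raw counts. SparCC is the
compositionally robust estimator of Friedman & Alm: it works on log-ratio
variances, which are invariant to the per-sample closure that makes naive
correlations of proportions spurious, and infers basis (unclosed)
variances under a sparsity assumption. Per-edge significance is assessed
by permuting each taxon's values across samples independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceTable, CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "EdgeSignificance",
    "correlation_network",
    "sparcc_network",
    "edge_significance",
]


@dataclass
class Network:
    """Symmetric signed weighted adjacency over taxa.

    The diagonal is stored as zero: self-correlations of 1 would dominate
    Laplacian degrees and clustering attractors downstream.
    """

    nodes: list[str]
    A: np.ndarray
    method: str = "pearson"
    pvals: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.A, dtype=float)
        n = len(self.nodes)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} != ({n}, {n})")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValueError("adjacency must be symmetric")
        if a.size and np.abs(a).max() > 1 + 1e-8:
            raise ValueError("edge weights must lie in [-1, 1]")
        a = np.clip((a + a.T) / 2, -1.0, 1.0)
        np.fill_diagonal(a, 0.0)
        self.A = a

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.nodes, columns=self.nodes)

    def edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_nodes, k=1)
        rows = {
            "node1": [self.nodes[i] for i in iu[0]],
            "node2": [self.nodes[j] for j in iu[1]],
            "weight": self.A[iu],
        }
        if self.pvals is not None:
            rows["p"] = self.pvals[iu]
        return pd.DataFrame(rows)


@dataclass
class EdgeSignificance:
    """Permutation-test settings for edge filtering."""

    n_perm: int = 1000
    alpha: float = 0.05
    correction: str = "none"  # or "fdr_bh"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("none", "fdr_bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


def _pearson_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows get weight 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc**2).sum(axis=1))
    ok = norm > 0
    xc[ok] /= norm[ok, None]
    xc[~ok] = 0.0
    r = xc @ xc.T
    np.fill_diagonal(r, 0.0)
    return np.clip(r, -1.0, 1.0)


def _corr_matrix(x: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        x = rankdata(x, axis=1)
    return _pearson_rows(np.asarray(x, dtype=float))


def correlation_network(ra: AbundanceTable, method: str = "spearman") -> Network:
    """Pairwise Pearson/Spearman network from relative abundances.

    Constant (zero-variance) taxa are retained as isolated nodes with
    zero-weight edges, keeping node sets identical across subsamples.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if ra.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation inference")
    n_const = int((ra.ra.std(axis=1) == 0).sum())
    if n_const:
        logger.info("correlation_network: %d zero-variance taxa kept as isolated nodes",
                    n_const)
    return Network(list(ra.taxa), _corr_matrix(ra.ra, method), method=method)


# ---------------------------------------------------------------------------
# SparCC


def _basis_variances(t: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Solve M @ omega = rowsum(T) for basis variances (least squares)."""
    omega, *_ = np.linalg.lstsq(m, t.sum(axis=1), rcond=None)
    return np.clip(omega, 1e-10, None)


def _rho_from_omega(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    return np.clip(rho, -1.0, 1.0)


def _sparcc_once(
    fracs: np.ndarray, n_excl_iter: int, excl_threshold: float
) -> np.ndarray:
    """One SparCC estimate from a fraction matrix (taxa x samples)."""
    d = fracs.shape[0]
    logf = np.log(fracs)
    # log-ratio variance matrix t_ij = var(log(x_i / x_j)) across samples
    var_i = logf.var(axis=1, ddof=1)
    cov = np.cov(logf)
    t = var_i[:, None] + var_i[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    t = np.clip(t, 0.0, None)

    m = np.ones((d, d)) + (d - 2) * np.eye(d)
    omega = _basis_variances(t, m)
    rho = _rho_from_omega(t, omega)
    excluded = np.zeros((d, d), dtype=bool)
    for _ in range(n_excl_iter):
        # exclude the strongest remaining pair; its log-ratio variance is
        # dominated by true covariation, violating the sparsity assumption
        cand = np.abs(rho).copy()
        cand[excluded] = 0.0
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= excl_threshold:
            break
        if m[i, i] <= 2 or m[j, j] <= 2:  # keep the system well posed
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, j] -= 1
        m[j, i] -= 1
        m[i, i] -= 1
        m[j, j] -= 1
        t_work = t.copy()
        t_work[excluded] = 0.0
        omega = _basis_variances(t_work, m)
        rho = _rho_from_omega(t, omega)
    np.fill_diagonal(rho, 0.0)
    return rho


def sparcc_network(
    count: CountTable,
    n_excl_iter: int = 10,
    excl_threshold: float = 0.1,
    n_inner: int = 20,
    seed: int = 42,
) -> Network:
    """SparCC compositional correlation network from raw counts.

    Per inner iteration, component fractions are drawn from the per-sample
    Dirichlet posterior with pseudocount 1, log-ratio variances are
    computed, the basis-variance linear system is solved, and the most
    strongly correlated pairs are iteratively excluded from the sparsity
    approximation. The reported network is the element-wise median over
    `n_inner` iterations.
    """
    if count.n_taxa < 4:
        raise ValueError("SparCC needs at least 4 taxa (basis system solvable)")
    rng = np.random.default_rng(seed)
    est = []
    alpha = count.counts.T + 1.0  # Dirichlet posterior, pseudocount 1
    for _ in range(n_inner):
        draws = np.empty_like(alpha)
        for j in range(alpha.shape[0]):
            draws[j] = rng.dirichlet(alpha[j])
        est.append(_sparcc_once(draws.T, n_excl_iter, excl_threshold))
    rho = np.median(est, axis=0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    np.fill_diagonal(rho, 0.0)
    return Network(list(count.taxa), rho, method="sparcc")


# ---------------------------------------------------------------------------
# Edge significance


def _infer_matrix(net: Network, table) -> tuple[np.ndarray, str]:
    if net.method in ("pearson", "spearman"):
        if isinstance(table, CountTable):
            x = table.counts / table.counts.sum(axis=0)
        else:
            x = table.ra
        return np.asarray(x, dtype=float), net.method
    if net.method == "sparcc":
        if not isinstance(table, CountTable):
            raise ValueError("SparCC significance needs the raw count table")
        return table.counts.astype(float), "sparcc"
    raise ValueError(f"unknown method {net.method!r}")


def edge_significance(
    net: Network,
    table,
    sig: EdgeSignificance | None = None,
    seed: int = 42,
) -> Network:
    """Two-sided permutation P-values per edge; non-significant edges zeroed.

    Each taxon's values are shuffled across samples independently,
    destroying all cross-taxon association while preserving marginals.
    P = (#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1); after optional
    Benjamini-Hochberg correction, edges with corrected P >= alpha are
    set to weight 0.
    """
    sig = sig or EdgeSignificance()
    x, method = _infer_matrix(net, table)
    if x.shape[0] != net.n_nodes:
        raise ValueError("table does not match network nodes")
    rng = np.random.default_rng(seed)
    obs = np.abs(net.A)
    count_ge = np.zeros_like(obs)
    for _ in range(sig.n_perm):
        xp = np.array([rng.permutation(row) for row in x])
        if method == "sparcc":
            perm_net = sparcc_network(
                CountTable(net.nodes, [f"s{i}" for i in range(x.shape[1])],
                           xp.astype(np.int64)),
                seed=int(rng.integers(2**31)),
            )
            r = np.abs(perm_net.A)
        else:
            r = np.abs(_corr_matrix(xp, method))
        count_ge += r >= obs
    pvals = (count_ge + 1.0) / (sig.n_perm + 1.0)
    np.fill_diagonal(pvals, 1.0)
    iu = np.triu_indices(net.n_nodes, k=1)
    p_flat = pvals[iu]
    if sig.correction == "fdr_bh":
        p_flat = multipletests(p_flat, method="fdr_bh")[1]
        pvals = np.zeros_like(pvals)
        pvals[iu] = p_flat
        pvals = pvals + pvals.T
        np.fill_diagonal(pvals, 1.0)
    a = net.A.copy()
    a[pvals >= sig.alpha] = 0.0
    np.fill_diagonal(a, 0.0)
    return Network(list(net.nodes), a, method=net.method, pvals=pvals)
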