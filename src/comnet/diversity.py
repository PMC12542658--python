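"""Alpha/beta diversity and distance-based variance partitioning.

Shannon diversity is averaged over repeated rarefactions to remove the
sampling-depth bias of uneven sequencing effort; beta diversity is
Bray-Curtis on relative abundances, embedded by classical PCoA.
``unexplained_r2`` partitions the distance-matrix sum of squares over
metadata factors (sequential, adonis-style) and reports the residual —
the "unexplained variance ratio" used to score how much community
variation the recorded factors fail to account for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import AbundanceTable, CountTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "VariancePartition",
    "rarefy",
    "shannon",
    "bray_curtis",
    "pcoa",
    "unexplained_r2",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with labels (samples or networks)."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if d.size and d.min() < -1e-12:
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(d, 0.0)
        self.d = np.clip(d, 0.0, None)


@dataclass
class OrdinationResult:
    """PCoA embedding: axes ordered by non-increasing positive eigenvalue."""

    labels: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray


@dataclass
class VariancePartition:
    """Sequential distance-based R² per factor plus the unexplained residual."""

    factors: list[str]
    r2_per_factor: np.ndarray
    unexplained: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": [*self.factors, "unexplained"],
             "r2": [*self.r2_per_factor, self.unexplained]}
        )


def rarefy(count: CountTable, depth: int, seed: int = 42) -> CountTable:
    """Subsample each sample to `depth` reads without replacement.

    Samples with fewer than `depth` total reads are dropped (logged).
    Uses the multivariate hypergeometric distribution, i.e. exact
    read-level subsampling without replacement.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = count.counts.sum(axis=0)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches depth {depth}")
    dropped = [s for s, k in zip(count.samples, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    samples = [s for s, k in zip(count.samples, keep) if k]
    cols = []
    for j in np.flatnonzero(keep):
        cols.append(rng.multivariate_hypergeometric(count.counts[:, j], depth))
    return CountTable(list(count.taxa), samples, np.column_stack(cols))


def _shannon_cols(counts: np.ndarray) -> np.ndarray:
    p = counts / counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=0)


def shannon(count: CountTable, depth: int, reps: int = 999, seed: int = 42) -> pd.Series:
    """Mean Shannon index (nats) over `reps` independent rarefactions."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    acc: dict[str, list[float]] = {}
    for _ in range(reps):
        sub = rarefy(count, depth, seed=int(rng.integers(2**31)))
        h = _shannon_cols(sub.counts)
        for s, v in zip(sub.samples, h):
            acc.setdefault(s, []).append(float(v))
    out = pd.Series({s: float(np.mean(v)) for s, v in acc.items()}, name="shannon")
    return out.reindex([s for s in count.samples if s in acc])


def bray_curtis(ra: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, d(x, y) = sum|x-y| / sum(x+y), per sample pair."""
    if ra.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(ra.ra.T, metric="braycurtis"))
    return DistanceMatrix(list(ra.samples), d)


def pcoa(d: DistanceMatrix, k: int = 10) -> OrdinationResult:
    """Classical MDS: eigendecomposition of the double-centered -d²/2.

    Retains min(k, number of positive eigenvalues) axes; negative
    eigenvalues are dropped without correction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(d.labels)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d.d**2) @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals[0])) if n else 1e-12
    pos = evals > tol
    if not pos.any():
        return OrdinationResult(list(d.labels), np.zeros((n, 1)),
                                np.zeros(1), np.zeros(1))
    evals_p, evecs_p = evals[pos], evecs[:, pos]
    m = min(k, evals_p.size)
    coords = evecs_p[:, :m] * np.sqrt(evals_p[:m])
    return OrdinationResult(
        list(d.labels), coords, evals_p[:m], evals_p[:m] / evals_p.sum()
    )


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(1, abs(r[0, 0])))
    q = q[:, :rank]
    return q @ q.T


def unexplained_r2(
    d: DistanceMatrix, meta: SampleMetadata, factors: list[str]
) -> VariancePartition:
    """Sequential (Type-I) distance-based variance partition.

    Gower-centers -d²/2 into G and attributes tr(H_k G) - tr(H_{k-1} G)
    to factor k, where H_k is the hat matrix of the dummy-coded model
    containing the first k factors; the residual fraction is the
    unexplained variance ratio. Factor order matters (documented).
    """
    if not factors:
        raise ValueError("at least one factor required")
    levels = {f: meta.levels(f, d.labels) for f in factors}
    for f, lv in levels.items():
        if len(set(lv)) < 2:
            raise ValueError(f"factor {f!r} is constant across these samples")
    n = len(d.labels)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d.d**2) @ j
    ss_total = float(np.trace(g))
    if ss_total <= 0:
        return VariancePartition(list(factors), np.zeros(len(factors)), 1.0)
    x = np.ones((n, 1))
    ss_prev = float(np.trace(_hat(x) @ g))  # 0 after centering
    r2 = []
    for f in factors:
        dummies = pd.get_dummies(pd.Series(levels[f])).to_numpy(dtype=float)
        x = np.hstack([x, dummies])
        ss_cur = float(np.trace(_hat(x) @ g))
        r2.append((ss_cur - ss_prev) / ss_total)
        ss_prev = ss_cur
    r2 = np.array(r2)
    return VariancePartition(list(factors), r2, float(1.0 - r2.sum()))
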