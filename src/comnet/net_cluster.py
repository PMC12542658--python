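"""Graph clustering of co-occurrence networks and cluster-based diversity.

Nodes that co-vary are grouped into clusters — Markov Clustering on the
positive edges, or Affinity Propagation on the full signed weight matrix
— and the per-sample relative abundances of each cluster's members are
summed (cluster aRA). Beta diversity computed on the cluster aRA table
trades taxon-level noise for module-level signal, which is the point of
the cluster-based diversity index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .core_io import AbundanceTable, SampleMetadata
from .diversity import DistanceMatrix, VariancePartition, bray_curtis, unexplained_r2
from .net_infer import Network
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ClusterAssignment",
    "ClusterAbundanceTable",
    "mcl_cluster",
    "ap_cluster",
    "cluster_abundance",
    "cluster_diversity",
    "cluster_vs_taxon_diversity",
]


@dataclass
class ClusterAssignment:
    """taxon -> cluster label map; labels contiguous integers from 0."""

    nodes: list[str]
    cluster: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.cluster)
        if labels.shape != (len(self.nodes),):
            raise ValueError("one label per node required")
        # relabel to contiguous ints in order of first appearance
        _, first = np.unique(labels, return_index=True)
        order = labels[np.sort(first)]
        remap = {lab: i for i, lab in enumerate(order)}
        self.cluster = np.array([remap[l] for l in labels], dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1 if len(self.cluster) else 0

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, lab in zip(self.nodes, self.cluster):
            out.setdefault(int(lab), []).append(node)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.nodes, "cluster": self.cluster})


@dataclass
class ClusterAbundanceTable:
    """Aggregated relative abundance (aRA) of each cluster per sample."""

    clusters: list[str]
    samples: list[str]
    ra: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ra, index=self.clusters, columns=self.samples)


def mcl_cluster(
    net: Network,
    inflation: float = 2.5,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Markov Clustering on the positive edges of the network.

    Negative weights are zeroed, self-loops of weight 1 added, and the
    columns normalized to a stochastic matrix. Expansion (matrix power)
    spreads random-walk flow; inflation (elementwise power + column
    renormalization) sharpens it; small entries are pruned. Clusters are
    read off the attractor rows of the limit matrix, merging overlapping
    attractor systems.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    n = net.n_nodes
    m = np.clip(net.A, 0.0, None)
    m = m + np.eye(n)
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {np.abs(m - prev).max():.2e})"
        )
    # attractors: rows with mass on the diagonal; merge overlapping systems
    attractors = np.flatnonzero(np.diag(m) > prune)
    labels = np.full(n, -1, dtype=int)
    cluster_sets: list[set[int]] = []
    for a in attractors:
        nodes = set(np.flatnonzero(m[a] > prune)) | {int(a)}
        merged = False
        for cs in cluster_sets:
            if cs & nodes:
                cs |= nodes
                merged = True
                break
        if not merged:
            cluster_sets.append(set(nodes))
    # a node attracted by several systems joins the first; leftovers singleton
    for lab, cs in enumerate(cluster_sets):
        for node in sorted(cs):
            if labels[node] == -1:
                labels[node] = lab
    nxt = len(cluster_sets)
    for i in range(n):
        if labels[i] == -1:
            labels[i] = nxt
            nxt += 1
    return ClusterAssignment(
        list(net.nodes), labels, "mcl",
        {"inflation": inflation, "expansion": expansion},
    )


def ap_cluster(
    net: Network,
    preference: float = 0.0,
    damping: float = 0.9,
    seed: int = 42,
    max_iter: int = 1000,
    convergence_iter: int = 15,
) -> ClusterAssignment:
    """Affinity Propagation on the signed weight matrix as similarity.

    Both positive and negative edges are used; the similarity diagonal
    (input preference) defaults to 0.
    """
    if not 0.5 <= damping < 1:
        raise ValueError("damping must lie in [0.5, 1)")
    s = net.A.copy()
    np.fill_diagonal(s, preference)
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=damping,
        preference=preference,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            labels = ap.fit_predict(s)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                "affinity propagation did not converge; try a higher damping"
            ) from exc
    if (labels < 0).any():
        raise RuntimeError(
            "affinity propagation found no exemplars; try a higher damping"
        )
    return ClusterAssignment(
        list(net.nodes), labels, "ap",
        {"preference": preference, "damping": damping},
    )


def cluster_abundance(
    ra: AbundanceTable, cls: ClusterAssignment
) -> ClusterAbundanceTable:
    """Sum member relative abundances per cluster and sample.

    Taxa absent from the assignment become "singleton:<id>" groups so
    total RA per sample is conserved exactly.
    """
    pos = {node: int(lab) for node, lab in zip(cls.nodes, cls.cluster)}
    names = [f"C{k}" for k in range(cls.n_clusters)]
    rows = {name: np.zeros(ra.n_samples) for name in names}
    for i, taxon in enumerate(ra.taxa):
        if taxon in pos:
            rows[names[pos[taxon]]] += ra.ra[i]
        else:
            rows[f"singleton:{taxon}"] = ra.ra[i].copy()
    clusters = list(rows)
    return ClusterAbundanceTable(clusters, list(ra.samples),
                                 np.vstack([rows[c] for c in clusters]))


def _bray_curtis_rows(ra: np.ndarray, labels: list[str]) -> DistanceMatrix:
    return DistanceMatrix(labels, squareform(pdist(ra.T, metric="braycurtis")))


def cluster_diversity(
    ct: ClusterAbundanceTable, meta: SampleMetadata, factors: list[str]
) -> VariancePartition:
    """Bray-Curtis on cluster aRA, then the sequential variance partition."""
    d = _bray_curtis_rows(ct.ra, list(ct.samples))
    return unexplained_r2(d, meta, factors)


def cluster_vs_taxon_diversity(
    ra: AbundanceTable,
    cls: ClusterAssignment,
    meta: SampleMetadata,
    factors: list[str],
) -> tuple[VariancePartition, VariancePartition]:
    """(cluster-level, taxon-level) variance partitions for comparison."""
    taxon_part = unexplained_r2(bray_curtis(ra), meta, factors)
    cluster_part = cluster_diversity(cluster_abundance(ra, cls), meta, factors)
    return cluster_part, taxon_part
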