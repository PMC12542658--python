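"""Statistical comparison of co-occurrence networks between sample groups.

Rebuilding a network from every possible subsample is intractable, so the
test subsamples: for each group, `bs` networks are inferred from random
subsets of `s_size` samples (observed ensemble), and `pm` networks are
inferred the same way after shuffling group labels across the pooled
samples (permuted ensemble). The distance between two networks is either

* spectral — Euclidean distance between the leading-k eigenvalues of the
  graph Laplacians L = D - A (D the diagonal of signed degree sums), or
* Jaccard — sum of |A_ij - B_ij| over the sum of max(|A_ij|, |B_ij|).

Replicate i contributes one observed inter-group distance (network i of
group A vs network i of group B) and one permuted distance; significance
is the fraction of permuted distances at least as large as observed ones
over all cross pairs:
P = (#{(i, j): d_perm_j >= d_obs_i} + 1) / (bs * pm + 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigvalsh

from .core_io import CountTable, SampleMetadata, relative_abundance
from .diversity import DistanceMatrix, OrdinationResult, VariancePartition, pcoa, unexplained_r2
from .net_infer import EdgeSignificance, Network, correlation_network, edge_significance, sparcc_network

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleSpec",
    "NetworkEnsemble",
    "ComparisonResult",
    "build_ensembles",
    "laplacian_spectrum",
    "spectral_distance",
    "jaccard_distance",
    "compare_groups",
    "network_pca",
]


@dataclass
class EnsembleSpec:
    """Subsampling/permutation design for group-wise network ensembles."""

    group_var: str
    g_size: int = 40
    s_size: int = 20
    bs: int = 33
    pm: int = 33
    method: str = "spearman"
    sig: bool = False
    sig_params: EdgeSignificance | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.s_size > self.g_size:
            raise ValueError("s_size must be <= g_size")
        if self.bs < 2 or self.pm < 2:
            raise ValueError("bs and pm must be >= 2")
        if self.method not in ("pearson", "spearman", "sparcc"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class NetworkEnsemble:
    """Networks over an identical node set for one group and kind."""

    group: str
    kind: str  # observed | permuted
    networks: list[Network]

    def __post_init__(self) -> None:
        if self.networks:
            nodes = self.networks[0].nodes
            for net in self.networks[1:]:
                if net.nodes != nodes:
                    raise ValueError("ensemble networks must share one node set")


@dataclass
class ComparisonResult:
    """Observed vs permuted inter-group distances with permutation P."""

    pair: tuple[str, str]
    d_obs: np.ndarray
    d_perm: np.ndarray
    p: float
    metric: str
    fstat: float = float("nan")

    @property
    def N(self) -> int:
        return len(self.d_obs) * len(self.d_perm)

    @property
    def mean_obs(self) -> float:
        return float(np.mean(self.d_obs))

    @property
    def mean_perm(self) -> float:
        return float(np.mean(self.d_perm))


def _infer_one(sub: CountTable, method: str) -> Network:
    if method == "sparcc":
        return sparcc_network(sub)
    return correlation_network(relative_abundance(sub), method)


def build_ensembles(
    count: CountTable,
    meta: SampleMetadata,
    spec: EnsembleSpec,
    include_permuted: bool = True,
) -> dict[str, tuple[NetworkEnsemble, NetworkEnsemble]]:
    """Observed and permuted network ensembles per eligible group.

    Groups with fewer than g_size samples are dropped (logged). For the
    permuted ensembles, group labels are shuffled once across the pooled
    retained samples (the permutation data set), then the identical
    subsample-and-infer step is applied pm times per pseudo-group —
    observed and permuted networks are built from count matrices of
    equal dimensions, and permuted inter-group pairs draw from disjoint
    pseudo-pools exactly as observed pairs draw from disjoint groups.
    """
    levels = meta.levels(spec.group_var, count.samples)
    by_group: dict[str, list[int]] = {}
    for i, lab in enumerate(levels):
        by_group.setdefault(lab, []).append(i)
    eligible = {g: idx for g, idx in by_group.items() if len(idx) >= spec.g_size}
    for g in sorted(set(by_group) - set(eligible)):
        logger.warning("build_ensembles: group %r dropped (%d < g_size %d)",
                       g, len(by_group[g]), spec.g_size)
    if len(eligible) < 2:
        raise ValueError("fewer than 2 groups reach g_size")
    rng = np.random.default_rng(spec.seed)
    groups = sorted(eligible)
    pooled = np.concatenate([eligible[g] for g in groups])
    sizes = [len(eligible[g]) for g in groups]

    def infer(cols: np.ndarray) -> Network:
        sub = count.select_samples([count.samples[c] for c in cols])
        net = _infer_one(sub, spec.method)
        if spec.sig:
            table = sub if spec.method == "sparcc" else relative_abundance(sub)
            net = edge_significance(net, table, spec.sig_params,
                                    seed=int(rng.integers(2**31)))
        return net

    out: dict[str, tuple[NetworkEnsemble, NetworkEnsemble]] = {}
    observed = {
        g: [infer(rng.choice(eligible[g], spec.s_size, replace=False))
            for _ in range(spec.bs)]
        for g in groups
    }
    permuted: dict[str, list[Network]] = {g: [] for g in groups}
    if include_permuted:
        shuffled = rng.permutation(pooled)
        pseudo: dict[str, np.ndarray] = {}
        start = 0
        for g, size in zip(groups, sizes):
            pseudo[g] = shuffled[start:start + size]
            start += size
        for _ in range(spec.pm):
            for g in groups:
                permuted[g].append(
                    infer(rng.choice(pseudo[g], spec.s_size, replace=False)))
    for g in groups:
        out[g] = (
            NetworkEnsemble(g, "observed", observed[g]),
            NetworkEnsemble(g, "permuted", permuted[g]),
        )
    return out


def laplacian_spectrum(net: Network, k: int | None = None,
                       use_abs: bool = False) -> np.ndarray:
    """Leading-k eigenvalues (descending) of L = D - A.

    Degrees are signed weight sums by default; `use_abs` switches to
    absolute-weight degrees, which keeps L positive semidefinite for
    signed networks.
    """
    a = np.abs(net.A) if use_abs else net.A
    lap = np.diag(a.sum(axis=1)) - a
    evals = np.sort(eigvalsh(lap))[::-1]
    if k is not None:
        if k > net.n_nodes:
            raise ValueError(f"k={k} exceeds {net.n_nodes} nodes")
        evals = evals[:k]
    return evals


def spectral_distance(a: Network, b: Network, k: int | None = None,
                      use_abs: bool = False) -> float:
    """Euclidean distance between leading-k Laplacian eigenvalue vectors."""
    if a.nodes != b.nodes:
        raise ValueError("networks must share one node set")
    if k is None:
        k = min(100, a.n_nodes)
    sa = laplacian_spectrum(a, k, use_abs)
    sb = laplacian_spectrum(b, k, use_abs)
    return float(np.linalg.norm(sa - sb))


def jaccard_distance(a: Network, b: Network) -> float:
    """Weighted Jaccard contrast of two adjacency matrices (off-diagonal)."""
    if a.nodes != b.nodes:
        raise ValueError("networks must share one node set")
    mask = ~np.eye(a.n_nodes, dtype=bool)
    num = np.abs(a.A - b.A)[mask].sum()
    den = np.maximum(np.abs(a.A), np.abs(b.A))[mask].sum()
    if den == 0:
        return 0.0
    return float(num / den)


def _spectra(nets: list[Network], k: int | None, use_abs: bool) -> np.ndarray:
    if k is None:
        k = min(100, nets[0].n_nodes)
    return np.array([laplacian_spectrum(n, k, use_abs) for n in nets])


def _cross_distances(na: list[Network], nb: list[Network], metric: str,
                     k: int | None, use_abs: bool = False) -> np.ndarray:
    if metric == "spectral":
        sa, sb = _spectra(na, k, use_abs), _spectra(nb, k, use_abs)
        return np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1)).ravel()
    if metric == "jaccard":
        return np.array([jaccard_distance(x, y) for x in na for y in nb])
    raise ValueError(f"unknown metric {metric!r}")


def _paired_distances(na: list[Network], nb: list[Network], metric: str,
                      k: int | None, use_abs: bool = False) -> np.ndarray:
    """One inter-group distance per replicate: d_i = d(na_i, nb_i)."""
    if len(na) != len(nb):
        raise ValueError("ensembles must have equal size for pairing")
    if metric == "spectral":
        sa, sb = _spectra(na, k, use_abs), _spectra(nb, k, use_abs)
        return np.sqrt(((sa - sb) ** 2).sum(-1))
    if metric == "jaccard":
        return np.array([jaccard_distance(x, y) for x, y in zip(na, nb)])
    raise ValueError(f"unknown metric {metric!r}")


def permutation_p(d_obs: np.ndarray, d_perm: np.ndarray) -> float:
    """P = (#{(i, j): d_perm_j >= d_obs_i} + 1) / (N + 1), pooled pairs."""
    ge = (np.asarray(d_perm)[None, :] >= np.asarray(d_obs)[:, None]).sum()
    n = len(d_obs) * len(d_perm)
    return float((ge + 1) / (n + 1))


def compare_groups(
    ensembles: dict[str, tuple[NetworkEnsemble, NetworkEnsemble]],
    metric: str = "spectral",
    k: int | None = None,
    use_abs: bool = False,
) -> dict[tuple[str, str], ComparisonResult]:
    """Permutation test of inter-group network distance per group pair.

    d_obs holds one distance per bootstrap replicate (observed network i
    of group A vs observed network i of group B); d_perm one distance per
    permutation replicate. The P formula then compares every observed
    distance with every permuted one: with bs = pm = 99 and complete
    separation, P = 1/(99*99 + 1). The secondary F statistic is the
    variance ratio of the two distance samples; the permutation P is
    authoritative.
    """
    out: dict[tuple[str, str], ComparisonResult] = {}
    for ga, gb in itertools.combinations(sorted(ensembles), 2):
        d_obs = _paired_distances(ensembles[ga][0].networks,
                                  ensembles[gb][0].networks, metric, k, use_abs)
        d_perm = _paired_distances(ensembles[ga][1].networks,
                                   ensembles[gb][1].networks, metric, k, use_abs)
        var_perm = float(np.var(d_perm, ddof=1))
        fstat = float(np.var(d_obs, ddof=1) / var_perm) if var_perm > 0 else float("nan")
        out[(ga, gb)] = ComparisonResult(
            (ga, gb), d_obs, d_perm, permutation_p(d_obs, d_perm), metric, fstat
        )
    return out


def network_pca(
    networks: list[Network],
    groups: list[str],
    metric: str = "spectral",
    k: int | None = None,
    n_axes: int = 10,
    use_abs: bool = False,
) -> tuple[OrdinationResult, VariancePartition]:
    """Embed networks by pairwise distance; partition variance by group.

    The group-factor R² measures how much of the network-to-network
    variance the group labels explain; its complement is the unexplained
    ratio reported alongside.
    """
    if len(networks) < 3:
        raise ValueError("need at least 3 networks")
    if len(groups) != len(networks):
        raise ValueError("one group label per network required")
    labels = [f"net{i}" for i in range(len(networks))]
    if metric == "spectral":
        s = _spectra(networks, k, use_abs)
        d = np.sqrt(((s[:, None, :] - s[None, :, :]) ** 2).sum(-1))
    else:
        n = len(networks)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = jaccard_distance(networks[i], networks[j])
    dm = DistanceMatrix(labels, d)
    ordination = pcoa(dm, k=n_axes)
    meta = SampleMetadata(labels, {"group": list(groups)})
    part = unexplained_r2(dm, meta, ["group"])
    return ordination, part
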