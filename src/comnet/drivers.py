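"""Identification of taxa groups that drive network differences.

A group of taxa (a taxonomic family or a network cluster) "drives" the
separation between condition-specific networks if destroying its
association with the conditions — permuting the group's counts across
samples while leaving all other taxa untouched — shrinks the
inter-condition network distance. Groups are scored singly (mean
distance change), then permuted cumulatively in order of impact until
the condition comparisons lose significance; the smallest prefix at
which more than half of the condition pairs become non-significant is
the changing point, marking the set of groups that carries the
discriminative network signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .core_io import CountTable, SampleMetadata, relative_abundance
from .diversity import VariancePartition
from .net_cluster import ClusterAssignment
from .net_compare import EnsembleSpec, build_ensembles, compare_groups, network_pca

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonGroup",
    "GroupImpact",
    "CumulativeScan",
    "make_groups",
    "groups_from_clusters",
    "partial_permute",
    "single_group_impacts",
    "cumulative_scan",
    "discriminative_subset_check",
]


@dataclass
class TaxonGroup:
    """A named set of taxa with its community-level summary features."""

    group_id: str
    members: list[str]
    grouping: str = "network_cluster"  # or "family"
    size: int = 0
    ara: float = 0.0        # accumulated relative abundance, mean over samples
    ara_norm: float = 0.0   # aRA / size (mean member RA)
    occupancy: float = 0.0  # fraction of samples with >= 1 member detected

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id!r} has no members")
        self.size = len(self.members)


@dataclass
class GroupImpact:
    """Effect of permuting one group on the inter-condition distance."""

    group_id: str
    mean_d_partial: float
    delta: float           # mean observed distance - mean partial distance
    decrease_ratio: float  # delta / mean observed distance


@dataclass
class CumulativeScan:
    """Per-prefix results of the cumulative group permutation."""

    ranked_groups: list[str]
    decrease_ratio: np.ndarray            # per prefix
    p_values: pd.DataFrame                # prefix x condition pair, permutation P
    significant: pd.DataFrame             # prefix x pair, Wilcoxon BH flags
    changing_point: int | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "prefix": np.arange(1, len(self.ranked_groups) + 1),
            "group": self.ranked_groups,
            "decrease_ratio": self.decrease_ratio,
        })
        for pair in self.p_values.columns:
            df[f"p[{pair}]"] = self.p_values[pair].to_numpy()
            df[f"sig[{pair}]"] = self.significant[pair].to_numpy()
        return df


def make_groups(
    count: CountTable, mapping: dict[str, list[str]], grouping: str = "family"
) -> list[TaxonGroup]:
    """Build TaxonGroups from a group -> member-taxa map, with features."""
    ra = relative_abundance(count)
    idx = {t: i for i, t in enumerate(count.taxa)}
    out = []
    for gid, members in mapping.items():
        members = [m for m in members if m in idx]
        if not members:
            continue
        rows = [idx[m] for m in members]
        ara = float(ra.ra[rows].sum(axis=0).mean())
        occ = float((count.counts[rows].sum(axis=0) > 0).mean())
        out.append(TaxonGroup(gid, members, grouping, ara=ara,
                              ara_norm=ara / len(members), occupancy=occ))
    return out


def groups_from_clusters(count: CountTable, cls: ClusterAssignment) -> list[TaxonGroup]:
    mapping = {f"C{k}": v for k, v in cls.members().items()}
    return make_groups(count, mapping, grouping="network_cluster")


def partial_permute(
    count: CountTable,
    meta: SampleMetadata,
    group: TaxonGroup,
    seed: int = 42,
    shared: bool = True,
) -> CountTable:
    """Permute the group members' counts across samples; others untouched.

    By default one shared sample permutation is applied to all member
    rows, which breaks the member-condition association while preserving
    the members' co-occurrence with each other. `shared=False` shuffles
    each member row independently instead.
    """
    idx = {t: i for i, t in enumerate(count.taxa)}
    missing = [m for m in group.members if m not in idx]
    if missing:
        raise ValueError(f"group members absent from table: {missing}")
    rng = np.random.default_rng(seed)
    counts = count.counts.copy()
    rows = [idx[m] for m in group.members]
    if shared:
        perm = rng.permutation(count.n_samples)
        counts[rows] = counts[np.ix_(rows, perm)]
    else:
        for r in rows:
            counts[r] = counts[r, rng.permutation(count.n_samples)]
    return CountTable(list(count.taxa), list(count.samples), counts)


def _mean_observed_distance(
    count: CountTable,
    meta: SampleMetadata,
    spec: EnsembleSpec,
    metric: str,
    k: int | None,
    include_permuted: bool = False,
):
    ens = build_ensembles(count, meta, spec, include_permuted=include_permuted)
    if include_permuted:
        results = compare_groups(ens, metric=metric, k=k)
        mean_d = float(np.mean([r.mean_obs for r in results.values()]))
        return mean_d, results, ens
    from .net_compare import _cross_distances
    import itertools
    ds = []
    for ga, gb in itertools.combinations(sorted(ens), 2):
        ds.append(_cross_distances(ens[ga][0].networks, ens[gb][0].networks,
                                   metric, k).mean())
    return float(np.mean(ds)), None, ens


def single_group_impacts(
    count: CountTable,
    meta: SampleMetadata,
    groups: list[TaxonGroup],
    spec: EnsembleSpec,
    metric: str = "spectral",
    k: int | None = None,
) -> tuple[list[GroupImpact], pd.DataFrame]:
    """Score each group by the distance drop its permutation causes.

    Returns the per-group impacts and the Spearman correlations of the
    distance change with group size, aRA, normalized aRA, and occupancy.
    """
    if not groups:
        raise ValueError("no groups given")
    mean_obs, _, _ = _mean_observed_distance(count, meta, spec, metric, k)
    rng = np.random.default_rng(spec.seed)
    impacts = []
    for g in groups:
        table_p = partial_permute(count, meta, g, seed=int(rng.integers(2**31)))
        mean_partial, _, _ = _mean_observed_distance(table_p, meta, spec, metric, k)
        delta = mean_obs - mean_partial
        impacts.append(GroupImpact(g.group_id, mean_partial, delta,
                                   delta / mean_obs if mean_obs > 0 else 0.0))
    deltas = np.array([im.delta for im in impacts])
    corr_rows = []
    for feat in ("size", "ara", "ara_norm", "occupancy"):
        vals = np.array([getattr(g, feat) for g in groups], dtype=float)
        if len(groups) >= 3 and np.std(vals) > 0 and np.std(deltas) > 0:
            rho, p = spearmanr(deltas, vals)
        else:
            rho, p = float("nan"), float("nan")
        corr_rows.append({"feature": feat, "rho": rho, "p": p})
    return impacts, pd.DataFrame(corr_rows)


def _permute_prefix(
    count: CountTable,
    meta: SampleMetadata,
    groups: list[TaxonGroup],
    seed: int,
) -> CountTable:
    rng = np.random.default_rng(seed)
    table = count
    for g in groups:
        table = partial_permute(table, meta, g, seed=int(rng.integers(2**31)))
    return table


def cumulative_scan(
    count: CountTable,
    meta: SampleMetadata,
    ranked_groups: list[TaxonGroup],
    spec: EnsembleSpec,
    metric: str = "spectral",
    k: int | None = None,
    alpha: float = 0.05,
) -> CumulativeScan:
    """Cumulatively permute groups in ranked order; find the changing point.

    For each prefix length m the first m groups are permuted jointly (one
    shared sample permutation per group), ensembles are rebuilt from the
    partially permuted table, and for every condition pair the
    permutation P plus a rank-sum test (observed-ensemble vs
    permuted-ensemble distances, BH-corrected across pairs) is computed.
    The changing point is the smallest m at which strictly more than half
    of the condition pairs are non-significant.
    """
    if not ranked_groups:
        raise ValueError("no groups given")
    mean_obs, _, _ = _mean_observed_distance(count, meta, spec, metric, k)
    rng = np.random.default_rng(spec.seed)
    ratios, p_rows, sig_rows = [], [], []
    pairs: list[str] | None = None
    changing_point = None
    for m in range(1, len(ranked_groups) + 1):
        table_m = _permute_prefix(count, meta, ranked_groups[:m],
                                  seed=int(rng.integers(2**31)))
        ens = build_ensembles(table_m, meta, spec)
        results = compare_groups(ens, metric=metric, k=k)
        if pairs is None:
            pairs = [f"{a}|{b}" for a, b in sorted(results)]
        mean_partial = float(np.mean([r.mean_obs for r in results.values()]))
        ratios.append((mean_obs - mean_partial) / mean_obs if mean_obs > 0 else 0.0)
        p_perm, p_wilcox = {}, []
        for (a, b), r in sorted(results.items()):
            p_perm[f"{a}|{b}"] = r.p
            p_wilcox.append(
                mannwhitneyu(r.d_obs, r.d_perm, alternative="two-sided").pvalue
            )
        reject = multipletests(p_wilcox, alpha=alpha, method="fdr_bh")[0]
        p_rows.append(p_perm)
        sig_rows.append(dict(zip(pairs, reject)))
        n_nonsig = int((~reject).sum())
        if changing_point is None and n_nonsig * 2 > len(reject):
            changing_point = m
    return CumulativeScan(
        [g.group_id for g in ranked_groups],
        np.array(ratios),
        pd.DataFrame(p_rows, index=range(1, len(ranked_groups) + 1)),
        pd.DataFrame(sig_rows, index=range(1, len(ranked_groups) + 1)),
        changing_point,
    )


def discriminative_subset_check(
    count: CountTable,
    meta: SampleMetadata,
    top_groups: list[TaxonGroup],
    spec: EnsembleSpec,
    metric: str = "spectral",
    k: int | None = None,
) -> tuple[VariancePartition, VariancePartition]:
    """Do the top groups carry the network separation?

    Returns the network-PCA group-factor variance partitions (a) after
    permuting the top groups (separation should collapse) and (b) using
    only the top groups' taxa (separation should persist).
    """
    rng = np.random.default_rng(spec.seed)

    def observed_partition(table: CountTable) -> VariancePartition:
        ens = build_ensembles(table, meta, spec, include_permuted=False)
        nets, labels = [], []
        for g in sorted(ens):
            nets.extend(ens[g][0].networks)
            labels.extend([g] * len(ens[g][0].networks))
        return network_pca(nets, labels, metric=metric, k=k)[1]

    table_a = _permute_prefix(count, meta, top_groups,
                              seed=int(rng.integers(2**31))) if top_groups else count
    part_a = observed_partition(table_a)
    members = sorted({m for g in top_groups for m in g.members},
                     key=count.taxa.index) if top_groups else list(count.taxa)
    part_b = observed_partition(count.select_taxa(members))
    return part_a, part_b
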