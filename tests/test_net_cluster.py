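import numpy as np
import pytest

from comnet import (
    AbundanceTable,
    Network,
    ap_cluster,
    cluster_abundance,
    cluster_vs_taxon_diversity,
    correlation_network,
    mcl_cluster,
    relative_abundance,
)
from comnet.net_cluster import ClusterAssignment


def _net(a, nodes=None):
    a = np.asarray(a, float)
    return Network(nodes or [f"n{i}" for i in range(a.shape[0])], a)


def _two_cliques():
    a = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    a[i, j] = 1.0
    return _net(a)


def _mcl_oracle(adj, inflation=2.5, expansion=2):
    """Independent step-by-step Markov-cluster iteration (no pruning)."""
    n = adj.shape[0]
    m = np.clip(adj, 0, None) + np.eye(n)
    m = m / m.sum(axis=0)
    for _ in range(200):
        prev = m.copy()
        expanded = m.copy()
        for _ in range(expansion - 1):
            expanded = expanded @ m
        m = expanded**inflation
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < 1e-9:
            break
    clusters = []
    for i in range(n):
        if m[i, i] > 1e-6:
            members = frozenset(np.flatnonzero(m[i] > 1e-6))
            if members not in clusters:
                clusters.append(members)
    return clusters


class TestMcl:
    def test_two_disjoint_cliques(self):
        net = _two_cliques()
        cls = mcl_cluster(net)
        assert cls.n_clusters == 2
        labels = cls.cluster
        assert len({labels[0], labels[1], labels[2]}) == 1
        assert len({labels[3], labels[4], labels[5]}) == 1
        assert labels[0] != labels[3]
        oracle = _mcl_oracle(net.A)
        assert sorted(map(sorted, oracle)) == [[0, 1, 2], [3, 4, 5]]

    def test_single_node(self):
        cls = mcl_cluster(_net([[0.0]]))
        assert cls.n_clusters == 1

    def test_uniform_complete_graph_single_cluster(self):
        a = np.ones((5, 5)) - np.eye(5)
        cls = mcl_cluster(_net(a), inflation=2.5)
        assert cls.n_clusters == 1

    def test_negative_edges_ignored(self):
        a = np.array([[0, 1, -0.9], [1, 0, -0.9], [-0.9, -0.9, 0]])
        cls = mcl_cluster(_net(a))
        assert cls.cluster[0] == cls.cluster[1]
        assert cls.cluster[2] != cls.cluster[0]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="inflation"):
            mcl_cluster(_two_cliques(), inflation=1.0)


def _ap_oracle(s, damping=0.9, iters=500):
    """Reference responsibility/availability message passing."""
    n = s.shape[0]
    r = np.zeros((n, n))
    a = np.zeros((n, n))
    for _ in range(iters):
        # responsibilities
        as_ = a + s
        idx = np.argmax(as_, axis=1)
        first = as_[np.arange(n), idx]
        as_[np.arange(n), idx] = -np.inf
        second = as_.max(axis=1)
        r_new = s - first[:, None]
        r_new[np.arange(n), idx] = s[np.arange(n), idx] - second
        r = damping * r + (1 - damping) * r_new
        # availabilities
        rp = np.maximum(r, 0)
        np.fill_diagonal(rp, np.diag(r))
        a_new = rp.sum(axis=0)[None, :] - rp
        da = np.diag(a_new).copy()
        a_new = np.minimum(a_new, 0)
        np.fill_diagonal(a_new, da)
        a = damping * a + (1 - damping) * a_new
    exemplars = np.flatnonzero(np.diag(r + a) > 0)
    labels = exemplars[np.argmax(s[:, exemplars], axis=1)]
    labels[exemplars] = exemplars
    return labels


def _block_similarity(seed=0):
    rng = np.random.default_rng(seed)
    s = rng.uniform(-0.4, -0.2, size=(10, 10))
    s = (s + s.T) / 2
    for block in (range(5), range(5, 10)):
        for i in block:
            for j in block:
                if i != j:
                    s[i, j] = rng.uniform(0.75, 0.95)
    s = (s + s.T) / 2
    np.fill_diagonal(s, 0.0)
    return s


class TestAp:
    def test_two_block_similarity_matches_reference(self):
        s = _block_similarity()
        cls = ap_cluster(_net(np.clip(s, -1, 1)), preference=0.0, damping=0.9,
                         seed=1)
        assert cls.n_clusters == 2
        assert len(set(cls.cluster[:5])) == 1
        assert len(set(cls.cluster[5:])) == 1
        ref = _ap_oracle(np.clip(s, -1, 1) + np.diag(np.zeros(10)))
        # reference oracle agrees on the partition
        assert len(set(ref[:5])) == 1 and len(set(ref[5:])) == 1
        assert ref[0] != ref[5]

    def test_dominant_preference_all_singletons(self):
        a = np.full((6, 6), 0.01)
        np.fill_diagonal(a, 0.0)
        cls = ap_cluster(_net(a), preference=0.9, damping=0.9, seed=2)
        assert cls.n_clusters == 6

    def test_cluster_count_bounds(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-1, 1, size=(12, 12))
        a = np.clip((a + a.T) / 2, -1, 1)
        cls = ap_cluster(_net(a), preference=0.0, damping=0.9, seed=4)
        assert 1 <= cls.n_clusters <= 12

    def test_invalid_damping(self):
        with pytest.raises(ValueError, match="damping"):
            ap_cluster(_two_cliques(), damping=0.2)


class TestClusterAbundance:
    def _ra(self):
        return AbundanceTable(
            ["t1", "t2", "t3"], ["s1", "s2"],
            np.array([[0.2, 0.1], [0.3, 0.2], [0.5, 0.7]]),
        )

    def test_identity_partition(self):
        ra = self._ra()
        cls = ClusterAssignment(["t1", "t2", "t3"], [0, 1, 2], "x")
        ct = cluster_abundance(ra, cls)
        np.testing.assert_allclose(ct.ra, ra.ra)

    def test_single_cluster_closure(self):
        ra = self._ra()
        cls = ClusterAssignment(["t1", "t2", "t3"], [0, 0, 0], "x")
        ct = cluster_abundance(ra, cls)
        np.testing.assert_allclose(ct.ra, [[1.0, 1.0]])

    def test_pair_sum(self):
        ra = self._ra()
        cls = ClusterAssignment(["t1", "t2", "t3"], [0, 0, 1], "x")
        ct = cluster_abundance(ra, cls)
        np.testing.assert_allclose(ct.ra[0], [0.5, 0.3])

    def test_unassigned_taxa_become_singletons(self):
        ra = self._ra()
        cls = ClusterAssignment(["t1", "t2"], [0, 0], "x")
        ct = cluster_abundance(ra, cls)
        assert "singleton:t3" in ct.clusters
        np.testing.assert_allclose(ct.ra.sum(axis=0), 1.0)

    def test_total_ra_conserved(self):
        rng = np.random.default_rng(5)
        m = rng.random((9, 7))
        ra = AbundanceTable([f"t{i}" for i in range(9)],
                            [f"s{j}" for j in range(7)], m / m.sum(axis=0))
        cls = ClusterAssignment([f"t{i}" for i in range(9)],
                                rng.integers(0, 3, 9), "x")
        ct = cluster_abundance(ra, cls)
        np.testing.assert_allclose(ct.ra.sum(axis=0), 1.0, atol=1e-12)


class TestClusterDiversity:
    def test_identity_partition_identical_r2(self, planted_community):
        count, meta, _ = planted_community
        ra = relative_abundance(count)
        cls = ClusterAssignment(list(count.taxa),
                                np.arange(count.n_taxa), "x")
        cpart, tpart = cluster_vs_taxon_diversity(ra, cls, meta, ["group"])
        assert cpart.unexplained == pytest.approx(tpart.unexplained, abs=1e-12)

    def test_planted_modules_reduce_unexplained(self, planted_community):
        count, meta, truth = planted_community
        ra = relative_abundance(count)
        cls = truth.module_assignment()
        cpart, tpart = cluster_vs_taxon_diversity(ra, cls, meta, ["group"])
        assert cpart.unexplained < tpart.unexplained
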