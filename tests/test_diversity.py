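import numpy as np
import pytest

from comnet import (
    AbundanceTable,
    CountTable,
    DistanceMatrix,
    SampleMetadata,
    bray_curtis,
    pcoa,
    rarefy,
    relative_abundance,
    shannon,
    unexplained_r2,
)


def _table(counts, prefix="t"):
    counts = np.asarray(counts)
    return CountTable(
        [f"{prefix}{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestRarefy:
    def test_forced_outcome(self):
        t = _table([[10], [0]])
        out = rarefy(t, 10, seed=0)
        assert out.counts[:, 0].tolist() == [10, 0]

    def test_shallow_samples_dropped(self):
        t = _table([[5, 10], [3, 5]])  # totals 8, 15
        out = rarefy(t, 10, seed=0)
        assert out.samples == ["s1"]

    def test_column_sums_equal_depth(self):
        rng = np.random.default_rng(3)
        t = _table(rng.integers(0, 200, size=(12, 8)))
        out = rarefy(t, 300, seed=1)
        assert (out.counts.sum(axis=0) == 300).all()
        # subsample never exceeds the source counts
        src = t.select_samples(out.samples)
        assert (out.counts <= src.counts).all()

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        t = _table(rng.integers(0, 100, size=(6, 5)))
        a = rarefy(t, 100, seed=9)
        b = rarefy(t, 100, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_all_below_depth_errors(self):
        with pytest.raises(ValueError, match="no sample"):
            rarefy(_table([[1], [1]]), 10)


class TestShannon:
    def test_uniform_four_taxa(self):
        t = _table([[25], [25], [25], [25]])
        h = shannon(t, depth=100, reps=1, seed=0)
        assert h.iloc[0] == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        t = _table([[50]])
        assert shannon(t, depth=50, reps=1, seed=0).iloc[0] == 0.0

    def test_hand_value_three_to_one(self):
        # depth equals the total, so rarefaction is the identity
        t = _table([[3000], [1000]])
        h = shannon(t, depth=4000, reps=1, seed=0)
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert h.iloc[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5623, abs=5e-5)

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(5)
        t = _table(rng.integers(0, 500, size=(10, 6)) + 1)
        h = shannon(t, depth=200, reps=5, seed=2)
        richness = (t.counts > 0).sum(axis=0)
        for val, r in zip(h.to_numpy(), richness):
            assert val <= np.log(r) + 1e-9


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        ra = AbundanceTable(
            ["t0", "t1"], ["a", "b", "c"],
            np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 1.0]]),
        )
        d = bray_curtis(ra)
        assert d.d[0, 1] == 0.0
        assert d.d[0, 2] == pytest.approx(0.5)

    def test_disjoint_supports_distance_one(self):
        ra = AbundanceTable(
            ["t0", "t1"], ["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]])
        )
        assert bray_curtis(ra).d[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        ra = AbundanceTable(
            ["t0", "t1", "t2"], ["x", "y"],
            np.array([[0.5, 0.25], [0.5, 0.25], [0.0, 0.5]]),
        )
        assert bray_curtis(ra).d[0, 1] == pytest.approx(0.5)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(6)
        m = rng.random((8, 10))
        m /= m.sum(axis=0)
        d = bray_curtis(AbundanceTable([f"t{i}" for i in range(8)],
                                       [f"s{j}" for j in range(10)], m)).d
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(d, d.T)
        assert np.diag(d).max() == 0.0


class TestPcoa:
    def test_collinear_equidistant_points(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        res = pcoa(d, k=2)
        x = np.sort(res.coords[:, 0])
        np.testing.assert_allclose(np.diff(x), [1, 1], atol=1e-9)

    def test_all_zero_distances(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(d, k=2)
        np.testing.assert_allclose(res.coords, 0.0)

    def test_euclidean_round_trip(self):
        from scipy.spatial import procrustes as sp_procrustes
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        d = DistanceMatrix([f"p{i}" for i in range(12)],
                           squareform(pdist(pts)))
        res = pcoa(d, k=2)
        _, _, disparity = sp_procrustes(pts, res.coords)
        assert disparity < 1e-12

    def test_eigenvalues_sorted_positive(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(9, 4))
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix([f"p{i}" for i in range(9)], squareform(pdist(pts)))
        res = pcoa(d, k=9)
        assert (res.eigenvalues > 0).all()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestUnexplainedR2:
    def test_perfectly_separated_groups(self):
        d = DistanceMatrix(
            list("abcd"),
            np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [1, 1, 0, 0], [1, 1, 0, 0]], float),
        )
        meta = SampleMetadata(list("abcd"), {"g": ["x", "x", "y", "y"]})
        part = unexplained_r2(d, meta, ["g"])
        assert part.r2_per_factor[0] == pytest.approx(1.0, abs=1e-12)
        assert part.unexplained == pytest.approx(0.0, abs=1e-12)

    def test_matches_permanova_r2_single_factor(self):
        """Independent route: R² derived from scikit-bio's PERMANOVA F."""
        from skbio.stats.distance import DistanceMatrix as SkDM, permanova

        rng = np.random.default_rng(11)
        n, a = 16, 4
        pts = rng.normal(size=(n, 3))
        from scipy.spatial.distance import pdist, squareform
        dmat = squareform(pdist(pts))
        labels = [f"s{i}" for i in range(n)]
        grouping = [f"g{i % a}" for i in range(n)]
        f = permanova(SkDM(dmat, ids=labels), grouping,
                      permutations=0)["test statistic"]
        r2_ref = f * (a - 1) / (f * (a - 1) + (n - a))
        meta = SampleMetadata(labels, {"g": grouping})
        part = unexplained_r2(DistanceMatrix(labels, dmat), meta, ["g"])
        assert part.r2_per_factor[0] == pytest.approx(r2_ref, abs=1e-10)

    def test_random_labels_expectation(self):
        """i.i.d. distances, random k-level factor: E[unexplained] ≈ 1-(k-1)/(n-1)."""
        rng = np.random.default_rng(12)
        n, k, reps = 20, 4, 120
        vals = []
        for _ in range(reps):
            m = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            m[iu] = rng.random(len(iu[0]))
            m += m.T
            labels = [f"s{i}" for i in range(n)]
            meta = SampleMetadata(
                labels, {"g": [f"g{i}" for i in rng.integers(0, k, n)]})
            if len(set(meta.factors["g"])) < 2:
                continue
            vals.append(
                unexplained_r2(DistanceMatrix(labels, m), meta, ["g"]).unexplained)
        assert np.mean(vals) == pytest.approx(1 - (k - 1) / (n - 1), abs=0.02)

    def test_components_sum_to_one(self):
        rng = np.random.default_rng(13)
        n = 12
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.random(len(iu[0]))
        m += m.T
        labels = [f"s{i}" for i in range(n)]
        meta = SampleMetadata(labels, {
            "g1": [f"a{i % 2}" for i in range(n)],
            "g2": [f"b{i % 3}" for i in range(n)],
        })
        part = unexplained_r2(DistanceMatrix(labels, m), meta, ["g1", "g2"])
        assert part.unexplained + part.r2_per_factor.sum() == pytest.approx(1.0)

    def test_constant_factor_errors(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        meta = SampleMetadata(["a", "b"], {"g": ["x", "x"]})
        with pytest.raises(ValueError, match="constant"):
            unexplained_r2(d, meta, ["g"])
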