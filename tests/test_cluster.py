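"""Hierarchical clustering against brute-force oracles, plus k-means."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import heatcraft as hc


def brute_force_agglomerate(dm, linkage):
    """Independent oracle: cluster lists and explicit cross-pair scans.

    Returns the sequence of (frozenset_a, frozenset_b, height) merges with
    the same tie rule (smallest pair of minimum member indices).
    """
    clusters = [[i] for i in range(len(dm))]
    merges = []
    while len(clusters) > 1:
        candidates = []
        for a, b in itertools.combinations(range(len(clusters)), 2):
            cross = [dm[i][j] for i in clusters[a] for j in clusters[b]]
            if linkage == "average":
                h = math.fsum(cross) / len(cross)
            elif linkage == "minimum":
                h = min(cross)
            else:
                h = max(cross)
            ka, kb = min(clusters[a]), min(clusters[b])
            candidates.append((h, min(ka, kb), max(ka, kb), a, b))
        h, _, _, a, b = min(candidates)
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), h))
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def _leafsets(tree):
    """Member sets of both children of every merge, in merge order."""
    sets = [frozenset([i]) for i in range(tree.n_leaves)]
    out = []
    for left, right, h in tree.merges:
        out.append((sets[left], sets[right], h))
        sets.append(sets[left] | sets[right])
    return out


def mst_edge_weights(dm):
    """Prim's algorithm written out longhand as an independent oracle."""
    n = len(dm)
    in_tree = {0}
    weights = []
    while len(in_tree) < n:
        best = min(
            (dm[i][j], j)
            for i in in_tree for j in range(n) if j not in in_tree
        )
        weights.append(best[0])
        in_tree.add(best[1])
    return sorted(weights)


class TestHierarchical:
    def test_three_points_on_a_line_all_linkages(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        d = hc.pairwise(pts, "euclidean", axis="rows")
        for linkage, h2 in [("minimum", 9.0), ("maximum", 10.0), ("average", 9.5)]:
            tree = hc.hierarchical(d, linkage)
            assert tree.merges[0][:2] == (0, 1)
            assert tree.merges[0][2] == pytest.approx(1.0)
            assert tree.merges[1][2] == pytest.approx(h2)

    def test_two_items_forced_merge(self):
        d = hc.DistanceMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), "euclidean", ["a", "b"])
        for linkage in hc.LINKAGE_NAMES:
            tree = hc.hierarchical(d, linkage)
            assert tree.merges == [(0, 1, 3.0)]

    def test_single_item_rejected(self):
        d = hc.DistanceMatrix(np.zeros((1, 1)), "euclidean", ["a"])
        with pytest.raises(hc.ValidationError):
            hc.hierarchical(d)

    @pytest.mark.parametrize("linkage", hc.LINKAGE_NAMES)
    @pytest.mark.parametrize("metric", hc.METRIC_NAMES)
    def test_matches_brute_force_oracle(self, linkage, metric):
        rng = np.random.default_rng(hash((linkage, metric)) % 2**31)
        for _ in range(5):
            n = int(rng.integers(3, 8))
            m = rng.normal(size=(n, 5))
            d = hc.pairwise(m, metric, axis="rows")
            tree = hc.hierarchical(d, linkage)
            expected = brute_force_agglomerate(d.d.tolist(), linkage)
            got = _leafsets(tree)
            for (ea, eb, eh), (ga, gb, gh) in zip(expected, got):
                assert {ea, eb} == {ga, gb}
                assert gh == pytest.approx(eh, abs=1e-9)

    @pytest.mark.parametrize("linkage", hc.LINKAGE_NAMES)
    def test_merge_heights_non_decreasing(self, linkage):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = rng.normal(size=(9, 4))
            d = hc.pairwise(m, "euclidean", axis="rows")
            heights = [h for _, _, h in hc.hierarchical(d, linkage).merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_minimum_linkage_heights_equal_sorted_mst_edges(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            m = rng.normal(size=(8, 3))
            d = hc.pairwise(m, "euclidean", axis="rows")
            heights = [h for _, _, h in hc.hierarchical(d, "minimum").merges]
            np.testing.assert_allclose(heights, mst_edge_weights(d.d.tolist()),
                                       atol=1e-12)

    def test_default_linkage_is_average(self):
        assert hc.DEFAULT_LINKAGE == "average"


class TestLeafOrder:
    def test_two_leaves(self):
        tree = hc.Dendrogram(merges=[(0, 1, 1.0)], n_leaves=2)
        assert hc.leaf_order(tree) == [0, 1]

    def test_line_example(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        d = hc.pairwise(pts, "euclidean", axis="rows")
        tree = hc.hierarchical(d, "minimum")
        assert hc.leaf_order(tree) == [0, 1, 2]

    def test_is_a_permutation(self):
        rng = np.random.default_rng(13)
        m = rng.normal(size=(12, 4))
        tree = hc.hierarchical(hc.pairwise(m, "manhattan", axis="rows"))
        assert sorted(hc.leaf_order(tree)) == list(range(12))

    def test_smaller_min_leaf_goes_left(self):
        rng = np.random.default_rng(19)
        m = rng.normal(size=(7, 3))
        tree = hc.hierarchical(hc.pairwise(m, "euclidean", axis="rows"))
        order = hc.leaf_order(tree)
        # the leftmost leaf of the whole tree must be leaf 0's cluster head
        sets = [frozenset([i]) for i in range(7)]
        for left, right, _ in tree.merges:
            assert min(sets[left]) < min(sets[right])
            sets.append(sets[left] | sets[right])
        assert order[0] == 0


class TestCutTree:
    def test_extremes(self):
        rng = np.random.default_rng(21)
        m = rng.normal(size=(6, 3))
        tree = hc.hierarchical(hc.pairwise(m, "euclidean", axis="rows"))
        assert hc.cut_tree(tree, 1) == [0] * 6
        assert sorted(hc.cut_tree(tree, 6)) == list(range(6))

    def test_line_example_k2(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        tree = hc.hierarchical(hc.pairwise(pts, "euclidean", axis="rows"))
        assert hc.cut_tree(tree, 2) == [0, 0, 1]

    def test_k_out_of_range(self):
        tree = hc.Dendrogram(merges=[(0, 1, 1.0)], n_leaves=2)
        for k in (0, 3):
            with pytest.raises(hc.ValidationError):
                hc.cut_tree(tree, k)

    def test_labels_numbered_in_leaf_order(self):
        rng = np.random.default_rng(27)
        m = rng.normal(size=(8, 4))
        tree = hc.hierarchical(hc.pairwise(m, "euclidean", axis="rows"))
        for k in (2, 3, 4):
            labels = hc.cut_tree(tree, k)
            seen = []
            for leaf in hc.leaf_order(tree):
                if labels[leaf] not in seen:
                    seen.append(labels[leaf])
            assert seen == list(range(k))


class TestKMeans:
    def test_k_equals_n_is_a_zero_cost_optimum(self):
        rng = np.random.default_rng(31)
        m = rng.normal(size=(5, 3))
        res = hc.kmeans(m, k=5, metric="squared_euclidean", seed=0)
        assert res.cost == pytest.approx(0.0, abs=1e-12)
        assert sorted(res.labels.tolist()) == list(range(5))

    def test_two_separated_blobs_recovered(self):
        m = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        res = hc.kmeans(m, k=2, metric="squared_euclidean", seed=3)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]
        # optimal cost: enumerate all 2-partitions as an oracle
        best = min(
            sum(((m[list(part)] - m[list(part)].mean(axis=0)) ** 2).sum()
                for part in (subset, rest))
            for subset, rest in (
                (s, tuple(i for i in range(4) if i not in s))
                for r in range(1, 4)
                for s in itertools.combinations(range(4), r)
            )
            if rest
        )
        assert res.cost == pytest.approx(best, abs=1e-9)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(37)
        m = rng.normal(size=(20, 4))
        a = hc.kmeans(m, k=3, seed=11)
        b = hc.kmeans(m, k=3, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.cost == b.cost

    def test_cost_non_increasing_under_squared_euclidean(self):
        rng = np.random.default_rng(41)
        for seed in range(5):
            m = rng.normal(size=(30, 5))
            res = hc.kmeans(m, k=4, metric="squared_euclidean", seed=seed)
            diffs = np.diff(res.cost_history)
            assert np.all(diffs <= 1e-9)

    def test_k_out_of_range(self):
        with pytest.raises(hc.ValidationError):
            hc.kmeans(np.zeros((3, 2)), k=4, seed=0)

    def test_every_cluster_non_empty(self):
        rng = np.random.default_rng(43)
        m = rng.normal(size=(12, 3))
        res = hc.kmeans(m, k=5, seed=2)
        assert set(res.labels.tolist()) == set(range(5))


class TestPlantedRecovery:
    def test_hierarchical_recovers_planted_groups(self):
        """Three well-separated row groups are recovered almost perfectly."""
        aris = []
        for seed in range(20):
            data = hc.generate(hc.SynthSpec(
                n_rows=60, n_cols=6, n_row_groups=3, effect=10.0, seed=seed))
            d = hc.pairwise(data.table.values, "pearson", axis="rows")
            tree = hc.hierarchical(d, "average")
            labels = hc.cut_tree(tree, 3)
            aris.append(adjusted_rand_score(data.true_row_labels, labels))
        assert np.mean(aris) >= 0.9
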