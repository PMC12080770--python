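"""K-means, silhouette, threshold extraction and level consolidation."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

from opfatigue import (
    GradeThresholds,
    REFERENCE_CONSOLIDATION,
    REFERENCE_THRESHOLDS_5LEVEL,
    REFERENCE_WEIGHTS,
    cluster_thresholds,
    consolidate_levels,
    euclidean,
    kmeans,
    select_k,
    silhouette,
    weighted_thresholds,
)


def blobs(rng, centers, n_per=10, sd=0.1):
    return np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])


class TestEuclidean:
    def test_3_4_5_triangle(self):
        assert euclidean((0, 0), (3, 4)) == 5.0

    def test_zero_iff_equal_and_symmetric(self):
        assert euclidean((1.5, -2), (1.5, -2)) == 0.0
        assert euclidean((1, 2), (4, 6)) == euclidean((4, 6), (1, 2)) == 5.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean((1, 2), (1, 2, 3))


class TestKMeans:
    def test_k_equals_n_gives_zero_within_ss(self, rng):
        pts = rng.uniform(0, 1, (6, 2))
        model = kmeans(pts, K=6, seed=0)
        assert model.within_ss == pytest.approx(0.0, abs=1e-20)

    def test_two_blobs_recovered(self, rng):
        pts = blobs(rng, [(0, 0), (10, 10)])
        model = kmeans(pts, K=2, seed=1)
        labels = model.labels
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_matches_exhaustive_best_2_partition(self, rng):
        # brute force over all 2-partitions of <= 8 points
        pts = rng.uniform(0, 10, (8, 2))
        best = np.inf
        for assignment in itertools.product([0, 1], repeat=8):
            a = np.array(assignment)
            if a.min() == a.max():
                continue
            ss = sum(
                ((pts[a == k] - pts[a == k].mean(axis=0)) ** 2).sum()
                for k in (0, 1)
            )
            best = min(best, ss)
        model = kmeans(pts, K=2, replicates=20, seed=2)
        assert model.within_ss == pytest.approx(best, rel=1e-9)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="K"):
            kmeans(rng.uniform(0, 1, (4, 2)), K=5)

    def test_deterministic_under_seed(self, rng):
        pts = rng.uniform(0, 1, (30, 2))
        a = kmeans(pts, 3, seed=7)
        b = kmeans(pts, 3, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.within_ss == b.within_ss


class TestSilhouette:
    def test_extreme_separation(self, rng):
        pts = blobs(rng, [(0, 0), (1000, 1000)], n_per=2, sd=0.5)
        _, mean_s = silhouette(pts, np.array([0, 0, 1, 1]))
        assert mean_s > 0.99

    def test_equidistant_point_scores_zero(self):
        pts = np.array([[0.0, 0], [0, 2], [4, 0], [4, 2], [2, 1]])
        labels = np.array([0, 0, 1, 1, 0])
        s, _ = silhouette(pts, labels)
        # the middle point's mean distance to each group is equal
        assert s[4] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_1d_oracle(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        labels = np.array([0, 0, 0, 1, 1])
        s, mean_s = silhouette(pts, labels)
        # manual a_i / b_i evaluation
        expected = []
        for i in range(5):
            own = [j for j in range(5) if labels[j] == labels[i] and j != i]
            other = [j for j in range(5) if labels[j] != labels[i]]
            a = np.mean([abs(pts[i, 0] - pts[j, 0]) for j in own])
            b = np.mean([abs(pts[i, 0] - pts[j, 0]) for j in other])
            expected.append((b - a) / max(a, b))
        np.testing.assert_allclose(s, expected, atol=1e-12)
        assert mean_s == pytest.approx(np.mean(expected))

    def test_matches_sklearn(self, rng):
        pts = rng.uniform(0, 1, (40, 2))
        labels = kmeans(pts, 3, seed=0).labels
        s_ours, _ = silhouette(pts, labels)
        np.testing.assert_allclose(s_ours, silhouette_samples(pts, labels),
                                   atol=1e-10)

    def test_values_in_unit_range(self, rng):
        pts = rng.uniform(0, 1, (30, 3))
        s, _ = silhouette(pts, kmeans(pts, 4, seed=1).labels)
        assert (s >= -1).all() and (s <= 1).all()

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette(rng.uniform(0, 1, (5, 2)), np.zeros(5, dtype=int))


class TestSelectK:
    def test_two_blobs_argmax_at_2(self, rng):
        pts = blobs(rng, [(0, 0), (10, 10)])
        table, best = select_k(pts, range(2, 11), seed=4)
        assert best == 2
        assert set(table["K"]) == set(range(2, 11))

    def test_five_blobs_argmax_at_5(self, rng):
        pts = blobs(rng, [(0, 0), (5, 0), (0, 5), (5, 5), (10, 10)], n_per=8)
        _, best = select_k(pts, range(2, 11), seed=5)
        assert best == 5

    def test_single_candidate(self, rng):
        pts = rng.uniform(0, 1, (12, 2))
        table, best = select_k(pts, [2], seed=0)
        assert len(table) == 1 and best == 2


class TestClusterThresholds:
    def test_min_max_extraction(self):
        pts = np.array([[0.1, 0.2], [0.2, 0.3], [0.3, 0.1],
                        [0.8, 0.9], [0.9, 0.8]])
        labels = np.array([0, 0, 0, 1, 1])
        th = cluster_thresholds(pts, labels)
        assert th.levels[0]["rt"] == (0.1, 0.3)
        assert th.levels[0]["borg"] == (0.1, 0.3)
        assert th.levels[1]["rt"] == (0.8, 0.9)

    def test_levels_ordered_by_centroid(self):
        pts = np.array([[0.9, 0.9], [0.8, 0.95], [0.1, 0.1], [0.15, 0.05]])
        labels = np.array([5, 5, 2, 2])
        th = cluster_thresholds(pts, labels)
        assert th.levels[0]["rt"][1] < th.levels[1]["rt"][0]

    def test_singleton_cluster_degenerate_interval(self):
        pts = np.array([[0.2, 0.2], [0.3, 0.3], [0.9, 0.9]])
        th = cluster_thresholds(pts, np.array([0, 0, 1]))
        assert th.levels[1]["rt"] == (0.9, 0.9)

    def test_unnormalized_points_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            cluster_thresholds(np.array([[1.5, 0.2], [0.1, 0.3]]),
                               np.array([0, 1]))


class TestWeightedThresholds:
    def test_reference_level3_band(self):
        # the published moderate band arises from the weighted
        # combination of the level-3 indicator bounds
        gt = GradeThresholds(levels=REFERENCE_THRESHOLDS_5LEVEL)
        intervals = weighted_thresholds(gt, REFERENCE_WEIGHTS)
        lo, hi = intervals[2]
        assert lo == pytest.approx(0.2710)
        assert hi == pytest.approx(0.6619)
        assert (round(lo, 2), round(hi, 2)) == (0.27, 0.66)

    def test_degenerate_weight_recovers_one_indicator(self):
        gt = GradeThresholds(levels=REFERENCE_THRESHOLDS_5LEVEL)
        intervals = weighted_thresholds(gt, {"rt": 1.0, "borg": 0.0})
        assert intervals == [lvl["rt"] for lvl in REFERENCE_THRESHOLDS_5LEVEL]

    def test_equal_weights_on_equal_indicators(self):
        levels = [{"rt": (0.1, 0.4), "borg": (0.1, 0.4)}]
        out = weighted_thresholds(GradeThresholds(levels=levels),
                                  {"rt": 0.5, "borg": 0.5})
        assert out[0] == pytest.approx((0.1, 0.4))

    def test_missing_weight_rejected(self):
        gt = GradeThresholds(levels=REFERENCE_THRESHOLDS_5LEVEL)
        with pytest.raises(ValueError, match="missing"):
            weighted_thresholds(gt, {"rt": 1.0})


class TestConsolidateLevels:
    # F bands printed in the reference study's summary table
    PUBLISHED_F = [(0.00, 0.18), (0.15, 0.30), (0.27, 0.66),
                   (0.66, 0.89), (0.87, 0.92)]

    def test_published_bands_consolidate_to_3_levels(self):
        bands, mapping = consolidate_levels(self.PUBLISHED_F)
        assert len(bands) == 3
        assert mapping == REFERENCE_CONSOLIDATION
        assert bands[0] == (0.00, 0.30)
        assert bands[1] == (0.27, 0.66)
        assert bands[2] == (0.66, 0.92)

    def test_disjoint_intervals_unchanged(self):
        iv = [(0.0, 0.1), (0.2, 0.3), (0.4, 0.5), (0.6, 0.7)]
        bands, mapping = consolidate_levels(iv)
        assert bands == iv
        assert mapping == {i + 1: i + 1 for i in range(4)}

    def test_nested_pair_merged(self):
        bands, mapping = consolidate_levels([(0.0, 0.5), (0.1, 0.4)])
        assert bands == [(0.0, 0.5)]
        assert mapping == {1: 1, 2: 1}

    def test_order_preserving_map(self):
        _, mapping = consolidate_levels(self.PUBLISHED_F)
        orig = sorted(mapping)
        assert all(mapping[a] <= mapping[b]
                   for a, b in zip(orig, orig[1:]))

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="lo <= hi"):
            consolidate_levels([(0.5, 0.2)])
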