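"""Mean-shift clustering: bandwidth contract, mode seeking, ranking, tiers."""

import math

import numpy as np
import pytest

from polyrisk.clustering import (
    FeatureMatrix,
    QuantileMeanShift,
    assign_tiers,
    cluster_risk_profiles,
    estimate_bandwidth,
    mean_shift,
    rank_clusters,
)


def naive_mode_seek_1d(xs, bandwidth, tol=1e-3, max_iter=300):
    """Exhaustive 1-D oracle: iterate the flat-kernel update from every
    point to convergence, then merge modes by support count (descending,
    ties by coordinate) with one-bandwidth suppression."""
    xs = [float(x) for x in xs]
    modes = []
    for x in xs:
        m = x
        for _ in range(max_iter):
            neighbours = [y for y in xs if abs(y - m) <= bandwidth]
            new = sum(neighbours) / len(neighbours)
            moved = abs(new - m)
            m = new
            if moved < tol * bandwidth:
                break
        modes.append(m)
    support = [sum(1 for y in xs if abs(y - m) <= bandwidth) for m in modes]
    order = sorted(range(len(modes)), key=lambda i: (-support[i], modes[i]))
    kept = []
    for i in order:
        if all(abs(modes[i] - modes[j]) > bandwidth for j in kept):
            kept.append(i)
    centers = [modes[i] for i in kept]
    labels = [min(range(len(centers)), key=lambda c: (abs(x - centers[c]), c)) for x in xs]
    return centers, labels


def as_partition(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


class TestEstimateBandwidth:
    def test_derived_four_point_example(self):
        # k = floor(4*0.5) = 2; 2nd-nearest (self included) distances are
        # 1, 1, 1 and 8; mean 2.75 — verified by sorting the full distance matrix.
        assert estimate_bandwidth(np.array([[0.0], [1.0], [2.0], [10.0]]), 0.5) == pytest.approx(2.75)

    def test_identical_points_give_zero(self):
        assert estimate_bandwidth(np.ones((5, 2)), 0.9) == 0.0

    def test_two_points_low_quantile_degenerates_to_zero(self):
        # k = max(1, floor(2*0.3)) = 1: each point's nearest neighbour is itself.
        assert estimate_bandwidth(np.array([[0.0], [5.0]]), 0.3) == 0.0

    def test_matches_sklearn_reference(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(42)
        X = rng.normal(size=(120, 2))
        for quantile in (0.1, 0.3, 0.5):
            ours = estimate_bandwidth(X, quantile)
            theirs = sklearn_cluster.estimate_bandwidth(X, quantile=quantile)
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_rejects_empty_and_bad_quantile(self):
        with pytest.raises(ValueError):
            estimate_bandwidth(np.empty((0, 1)))
        with pytest.raises(ValueError):
            estimate_bandwidth(np.ones((3, 1)), quantile=0.0)


class TestMeanShift:
    def test_identical_points_form_one_cluster(self):
        X = np.full((7, 2), 3.0)
        model = QuantileMeanShift().fit(X)
        assert len(model.cluster_centers_) == 1
        assert np.allclose(model.cluster_centers_[0], [3.0, 3.0])
        assert set(model.labels_) == {0}

    def test_two_blobs_converge_to_their_means(self):
        X = np.array([[0.0], [1.0], [2.0], [100.0], [101.0], [102.0]])
        centers, labels = mean_shift(X, bandwidth=5.0)
        assert sorted(float(c) for c in centers[:, 0]) == pytest.approx([1.0, 101.0], abs=1e-6)
        assert as_partition(labels) == as_partition([0, 0, 0, 1, 1, 1])

    def test_three_separated_components_recovered_exactly(self):
        rng = np.random.default_rng(0)
        means = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        component = np.repeat(np.arange(3), 50)
        X = means[component] + rng.normal(scale=1.0, size=(150, 2))
        model = QuantileMeanShift(quantile=0.3).fit(X)
        assert means[0] @ means[1] == 0  # sanity: orthogonal placement
        assert np.min(np.linalg.norm(means[0] - means[1:], axis=1)) >= 10 * model.bandwidth_
        assert len(model.cluster_centers_) == 3
        # Oracle: nearest-component assignment of each generated point.
        oracle = np.argmin(
            np.linalg.norm(X[:, None, :] - means[None, :, :], axis=2), axis=1
        )
        assert as_partition(model.labels_) == as_partition(oracle)

    def test_centers_are_fixed_points_of_the_flat_kernel_update(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(0, 1, (40, 2)), rng.normal(8, 1, (40, 2))])
        model = QuantileMeanShift(quantile=0.3).fit(X)
        for center in model.cluster_centers_:
            inside = X[np.linalg.norm(X - center, axis=1) <= model.bandwidth_]
            drift = np.linalg.norm(inside.mean(axis=0) - center)
            assert drift < 1e-3 * model.bandwidth_

    def test_matches_naive_1d_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            xs = rng.integers(0, 12, size=rng.integers(2, 20)).astype(float)
            model = QuantileMeanShift(quantile=0.3).fit(xs[:, None])
            if model.bandwidth_ == 0.0:
                continue
            _centers, labels = naive_mode_seek_1d(xs, model.bandwidth_)
            assert as_partition(model.labels_) == as_partition(labels)

    def test_matches_sklearn_mean_shift_on_blobs(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(0, 1, (60, 2)), rng.normal(20, 1, (60, 2))])
        bandwidth = estimate_bandwidth(X, 0.3)
        ours = QuantileMeanShift(bandwidth=bandwidth).fit(X)
        theirs = sklearn_cluster.MeanShift(bandwidth=bandwidth, bin_seeding=False).fit(X)
        assert as_partition(ours.labels_) == as_partition(theirs.labels_)
        assert np.allclose(
            np.sort(ours.cluster_centers_, axis=0),
            np.sort(theirs.cluster_centers_, axis=0),
            atol=1e-3 * bandwidth,
        )

    def test_deterministic_for_identical_input(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 15, size=(300, 2)).astype(float)
        a = QuantileMeanShift().fit(X)
        b = QuantileMeanShift().fit(X)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.array_equal(a.cluster_centers_, b.cluster_centers_)
        assert a.bandwidth_ == b.bandwidth_

    def test_degenerate_bandwidth_falls_back_to_max_distance_fraction(self):
        X = np.array([[0.0], [5.0]])  # quantile estimate is 0 here
        model = QuantileMeanShift(quantile=0.3).fit(X)
        assert model.bandwidth_ == pytest.approx(1e-3 * 5.0)
        assert len(model.cluster_centers_) == 2

    def test_non_positive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            QuantileMeanShift(bandwidth=-1.0).fit(np.ones((3, 1)))

    def test_sklearn_protocol_round_trip(self):
        model = QuantileMeanShift(quantile=0.2)
        params = model.get_params()
        clone = QuantileMeanShift().set_params(**params)
        assert clone.get_params() == params
        X = np.array([[0.0], [0.5], [10.0]])
        labels = clone.fit_predict(X)
        assert np.array_equal(clone.predict(X), labels)


def grouping_from(points, labels, ids=None):
    ids = ids or [f"p{i}" for i in range(len(points))]
    features = FeatureMatrix(tuple(ids), np.asarray(points, dtype=float))
    return rank_clusters(features, np.asarray(labels), bandwidth=1.0)


class TestRankClusters:
    def test_single_cluster_is_rank_one(self):
        grouping = grouping_from([[4.0], [5.0]], [0, 0])
        assert grouping.n_groups == 1
        assert grouping.groups[0].rank == 1
        assert grouping.groups[0].mean_risk == (4.5,)

    def test_ranks_follow_descending_means(self):
        points = [[2.0], [2.0], [9.5], [4.1]]
        grouping = grouping_from(points, [0, 0, 1, 2])
        assert [g.mean_risk[0] for g in grouping.groups] == [9.5, 4.1, 2.0]
        assert grouping.labels == (3, 3, 1, 2)

    def test_ten_group_report_shape(self):
        # Ten constructed clusters with means 11..1 must rank in that order,
        # yielding a (rank, size, mean risk) table.
        means = [11, 9, 8, 7, 6, 5, 4, 3, 2, 1]
        points, labels = [], []
        for cluster, mean in enumerate(means):
            for delta in (-0.5, 0.0, 0.5):
                points.append([mean + delta])
                labels.append(cluster)
        grouping = grouping_from(points, labels)
        assert grouping.n_groups == 10
        assert [g.rank for g in grouping.groups] == list(range(1, 11))
        assert [g.mean_risk[0] for g in grouping.groups] == means
        assert all(g.size == 3 for g in grouping.groups)
        assert all(
            g.score_range[0][0] <= g.mean_risk[0] <= g.score_range[0][1]
            for g in grouping.groups
        )

    def test_2d_ranking_normalises_axes(self):
        # Raw WIRS range dwarfs WARS; after per-axis max scaling the cluster
        # with a high WARS but modest WIRS can outrank a mid-WIRS cluster.
        points = [[10.0, 5.0], [10.0, 5.0], [1.0, 50.0], [1.0, 50.0], [1.0, 1.0], [1.0, 1.0]]
        grouping = grouping_from(points, [0, 0, 1, 1, 2, 2])
        keys = {tuple(g.center): g.rank for g in grouping.groups}
        assert keys[(1.0, 1.0)] == 3  # lowest on both axes is always last
        assert keys[(10.0, 5.0)] == 1  # norm(1, 0.1) > norm(0.1, 1.0)

    def test_label_profile_mismatch_rejected(self):
        features = FeatureMatrix(("a", "b"), np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError):
            rank_clusters(features, np.array([0]), bandwidth=1.0)


class TestAssignTiers:
    @pytest.mark.parametrize(
        "n_groups, expected",
        [
            (11, ["red"] * 4 + ["amber"] * 4 + ["green"] * 3),  # ceil(11/3) = 4
            (3, ["red", "amber", "green"]),
            (1, ["red"]),
        ],
    )
    def test_default_thirds(self, n_groups, expected):
        points, labels = [], []
        for cluster in range(n_groups):
            points.append([float(n_groups - cluster)])
            labels.append(cluster)
        grouping = assign_tiers(grouping_from(points, labels))
        assert [g.tier for g in grouping.groups] == expected

    def test_invalid_fractions_rejected(self):
        grouping = grouping_from([[1.0]], [0])
        with pytest.raises(ValueError):
            assign_tiers(grouping, (0.7, 0.5))


class TestClusterRiskProfiles:
    def test_partition_and_ordering_invariants(self):
        rng = np.random.default_rng(21)
        points = rng.integers(1, 15, size=(400, 2)).astype(float)
        ids = tuple(f"p{i}" for i in range(len(points)))
        grouping = cluster_risk_profiles(FeatureMatrix(ids, points))
        assert sum(g.size for g in grouping.groups) == len(points)
        assert all(g.tier in ("red", "amber", "green") for g in grouping.groups)
        axis_max = points.max(axis=0)
        keys = [float(np.linalg.norm(np.array(g.mean_risk) / axis_max)) for g in grouping.groups]
        assert keys == sorted(keys, reverse=True)

    def test_scale_switch_changes_geometry_not_reporting_scale(self):
        rng = np.random.default_rng(2)
        points = np.column_stack([rng.integers(1, 5, 200), rng.integers(1, 80, 200)]).astype(float)
        ids = tuple(f"p{i}" for i in range(len(points)))
        grouping = cluster_risk_profiles(FeatureMatrix(ids, points), scale=True)
        # Reported statistics stay on the raw score scale.
        for g in grouping.groups:
            for (lo, hi), mean in zip(g.score_range, g.mean_risk):
                assert lo <= mean <= hi
        assert max(hi for g in grouping.groups for _lo, hi in [g.score_range[1]]) <= 80
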