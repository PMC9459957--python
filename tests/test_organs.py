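"""Morphological features, dataset splitting, Random Forest, ring filter."""

import numpy as np
import pytest

import phenoscan as ps
from phenoscan.organs import (
    DEGENERATE_SENTINEL,
    LabeledScan,
    RingFilterParams,
    SplitSpec,
)


class TestExtractFeatures:
    def test_vertical_line_is_linear(self):
        pts = np.column_stack([np.zeros(200), np.zeros(200),
                               np.linspace(0, 20, 200)])
        feats = ps.extract_features(ps.PointCloud(pts), 1.0)
        ok = ~feats.degenerate
        assert feats.values[ok, 0].mean() > 0.99  # linearity
        assert feats.values[ok, 1].max() < 0.01  # planarity
        assert feats.values[ok, 4].mean() > 0.99  # dominant direction vertical

    def test_horizontal_plane_is_planar(self):
        rng = np.random.default_rng(0)
        n = 10_000
        pts = np.column_stack([rng.uniform(0, 10, n),
                               rng.uniform(0, 10, n), np.full(n, 5.0)])
        feats = ps.extract_features(ps.PointCloud(pts), 1.0)
        ok = ~feats.degenerate
        # exact coplanarity: sphericity vanishes; planarity dominates but is
        # bounded below 1 by the sampling anisotropy of finite neighbourhoods
        assert feats.values[ok, 1].mean() > 0.75  # planarity
        assert feats.values[ok, 1].mean() > feats.values[ok, 0].mean()
        assert feats.values[ok, 2].max() < 1e-9  # sphericity
        assert feats.values[ok, 3].mean() > 0.99  # normal vertical

    def test_uniform_ball_matches_bruteforce_covariance(self):
        """Eigen-features agree with a direct per-point covariance oracle."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(400, 3))
        cloud = ps.PointCloud(pts)
        feats = ps.extract_features(cloud, 1.0)
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(radius=1.0).fit(pts)
        lists = nn.radius_neighbors(pts, return_distance=False)
        for i in rng.choice(len(pts), 40, replace=False):
            idx = lists[i]
            if len(idx) < 3:
                assert feats.degenerate[i]
                continue
            patch = pts[idx] - pts[idx].mean(axis=0)
            evals = np.linalg.eigvalsh(patch.T @ patch / len(idx))
            l3, l2, l1 = np.maximum(evals, 0)
            np.testing.assert_allclose(
                feats.values[i, :3],
                [(l1 - l2) / l1, (l2 - l3) / l1, l3 / l1], atol=1e-9)

    def test_feature_ranges(self):
        rng = np.random.default_rng(2)
        cloud = ps.PointCloud(rng.random((500, 3)) * 10)
        feats = ps.extract_features(cloud, 1.0)
        ok = ~feats.degenerate
        assert np.all(feats.values[ok, :5] >= 0)
        assert np.all(feats.values[ok, :5] <= 1 + 1e-9)
        assert np.all((feats.values[:, 6] >= 0) & (feats.values[:, 6] <= 1))

    def test_degenerate_neighborhood_flagged(self):
        pts = np.vstack([np.random.default_rng(0).random((20, 3)),
                         [[500.0, 500.0, 500.0]]])  # isolated point
        feats = ps.extract_features(ps.PointCloud(pts), 0.5)
        assert feats.degenerate[-1]
        assert np.all(feats.values[-1, :5] == DEGENERATE_SENTINEL)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ps.extract_features(ps.PointCloud(np.zeros((5, 3))), 1.0)


def _dummy_scans(n, n_leaves=2):
    rng = np.random.default_rng(0)
    out = []
    for i in range(n):
        pts = rng.random((30, 3))
        labels = np.where(rng.random(30) < 0.5, "stem", "leaf")
        out.append(LabeledScan(f"p{i}", ps.PointCloud(pts), labels, n_leaves))
    return out


class TestSplitDataset:
    def test_ten_scans_split_6_2_2(self):
        split = ps.split_dataset(_dummy_scans(10), SplitSpec(rng_seed=0))
        train, tune, val = split["early"]
        assert (len(train), len(tune), len(val)) == (6, 2, 2)

    def test_partition_is_exact_and_deterministic(self):
        scans = _dummy_scans(9)
        a = ps.split_dataset(scans, SplitSpec(rng_seed=5))
        b = ps.split_dataset(scans, SplitSpec(rng_seed=5))
        ids = lambda part: [s.plant_id for s in part]
        for stage in ("early", "late"):
            assert [ids(p) for p in a[stage]] == [ids(p) for p in b[stage]]
        train, tune, val = a["early"]
        all_ids = ids(train) + ids(tune) + ids(val)
        assert sorted(all_ids) == sorted(s.plant_id for s in scans)
        assert len(set(all_ids)) == len(all_ids)

    def test_stage_routing_by_leaf_count(self):
        scans = _dummy_scans(5, n_leaves=2) + _dummy_scans(5, n_leaves=5)
        # fix distinct ids across the two groups
        for i, s in enumerate(scans):
            s.plant_id = f"s{i}"
        split = ps.split_dataset(scans, SplitSpec(rng_seed=0))
        early = [s for part in split["early"] for s in part]
        late = [s for part in split["late"] for s in part]
        assert all(s.n_leaves <= 3 for s in early) and len(early) == 5
        assert all(s.n_leaves > 3 for s in late) and len(late) == 5

    def test_too_few_scans(self):
        with pytest.raises(ValueError):
            ps.split_dataset(_dummy_scans(3), SplitSpec(rng_seed=0))


class TestClassifier:
    def test_linearly_separable_features_perfect(self):
        # a vertical line ("stem") vs a horizontal plane patch ("leaf"):
        # linearity/planarity/verticality separate the classes exactly
        rng = np.random.default_rng(0)
        scans = []
        for i in range(3):
            n = 200
            line = np.column_stack([np.zeros(n), np.zeros(n),
                                    np.linspace(0, 20, n)])
            plane = np.column_stack([rng.uniform(3, 10, n),
                                     rng.uniform(-4, 4, n), np.full(n, 10.0)])
            pts = np.vstack([line, plane])
            labels = np.array(["stem"] * n + ["leaf"] * n)
            scans.append(LabeledScan(f"p{i}", ps.PointCloud(pts), labels))
        model = ps.train_classifier(
            scans[:2], scans[2:], tuning_grid=({"n_estimators": 50,
                                                "max_depth": 8},))
        pred = ps.classify(model, scans[2].cloud)
        assert ps.accuracy(pred, scans[2].labels) == 100.0

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(0)
        scans = [LabeledScan("p", ps.PointCloud(rng.random((50, 3))),
                             np.full(50, "stem"))]
        with pytest.raises(ValueError):
            ps.train_classifier(scans, [], tuning_grid=({"n_estimators": 10,
                                                         "max_depth": 4},))

    def test_permuted_labels_near_prior(self, seedling_benchmark_small):
        """Training on shuffled labels collapses to the majority prior."""
        scans = [s for _, _, s in seedling_benchmark_small]
        rng = np.random.default_rng(0)
        shuffled = [
            LabeledScan(s.plant_id, s.cloud, rng.permutation(s.labels),
                        s.n_leaves) for s in scans[:4]
        ]
        model = ps.train_classifier(
            shuffled[:3], shuffled[3:],
            tuning_grid=({"n_estimators": 30, "max_depth": 8},),
            max_train_points=15000)
        val = scans[5]
        acc = ps.accuracy(ps.classify(model, val.cloud), val.labels)
        prior = max((val.labels == "stem").mean(),
                    (val.labels == "leaf").mean()) * 100
        assert abs(acc - prior) < 15.0

    def test_synthetic_benchmark_validation_accuracy(self,
                                                     seedling_benchmark_small):
        scans = [s for _, _, s in seedling_benchmark_small]
        model = ps.train_classifier(
            scans[:4], scans[4:5],
            tuning_grid=({"n_estimators": 100, "max_depth": 16},),
            max_train_points=30000)
        val = scans[5]
        acc = ps.accuracy(ps.classify(model, val.cloud), val.labels)
        assert acc >= 85.0


class TestRingFilter:
    def _seedling_with_mislabels(self, benchmark):
        params, scene, scan = benchmark[1]
        rng = np.random.default_rng(0)
        labels = scan.labels.copy()
        leaf_idx = np.flatnonzero(labels == "leaf")
        flip = rng.choice(leaf_idx, size=max(1, len(leaf_idx) // 20),
                          replace=False)
        labels[flip] = "stem"
        return params, scan.cloud, labels, scan.labels

    def test_all_stem_inside_ring_unchanged(self):
        pts = np.column_stack([np.zeros(100), np.zeros(100),
                               np.linspace(0, 10, 100)])
        labels = np.full(100, "stem")
        out = ps.ring_filter(ps.PointCloud(pts), labels,
                             RingFilterParams(radius=1.0))
        assert np.all(out == "stem")

    def test_far_stem_point_relabeled(self):
        pts = np.vstack([
            np.column_stack([np.zeros(100), np.zeros(100),
                             np.linspace(0, 10, 100)]),
            [[10.0, 0.0, 5.0]],
        ])
        labels = np.full(101, "stem")
        out = ps.ring_filter(ps.PointCloud(pts), labels,
                             RingFilterParams(radius=1.0))
        assert out[-1] == "leaf"
        assert np.all(out[:-1] == "stem")

    def test_no_stem_points_warns_and_returns_unchanged(self):
        labels = np.full(10, "leaf")
        with pytest.warns(UserWarning):
            out = ps.ring_filter(ps.PointCloud(np.random.default_rng(0)
                                               .random((10, 3))),
                                 labels, RingFilterParams(radius=1.0))
        assert np.all(out == "leaf")

    def test_idempotent_and_leaf_count_never_drops(self, seedling_benchmark_small):
        params, cloud, noisy, truth = self._seedling_with_mislabels(
            seedling_benchmark_small)
        p = RingFilterParams(radius=2 * params.stem_radius_cm)
        once = ps.ring_filter(cloud, noisy, p)
        twice = ps.ring_filter(cloud, once, p)
        np.testing.assert_array_equal(once, twice)
        assert (once == "leaf").sum() >= (noisy == "leaf").sum()

    def test_stem_precision_increases(self, seedling_benchmark_small):
        params, cloud, noisy, truth = self._seedling_with_mislabels(
            seedling_benchmark_small)
        p = RingFilterParams(radius=2 * params.stem_radius_cm)
        out = ps.ring_filter(cloud, noisy, p)

        def precision(pred):
            tp = ((pred == "stem") & (truth == "stem")).sum()
            fp = ((pred == "stem") & (truth != "stem")).sum()
            return tp / (tp + fp)

        assert precision(out) > precision(noisy)


class TestAccuracy:
    def test_identical_and_half(self):
        a = np.array(["stem", "leaf", "stem", "leaf"])
        assert ps.accuracy(a, a) == 100.0
        b = np.array(["stem", "leaf", "leaf", "stem"])
        assert ps.accuracy(a, b) == 50.0

    def test_confusion_matrix_example(self):
        # TP=40, TN=45, FP=5, FN=10 -> 85%
        truth = np.array(["stem"] * 50 + ["leaf"] * 50)
        pred = np.array(["stem"] * 40 + ["leaf"] * 10 +
                        ["stem"] * 5 + ["leaf"] * 45)
        assert ps.accuracy(pred, truth) == pytest.approx(85.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ps.accuracy(np.array(["stem"]), np.array(["stem", "leaf"]))
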