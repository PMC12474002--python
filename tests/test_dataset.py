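import json

import numpy as np
import pytest

from orchard3d.annotation import read_labels_csv
from orchard3d.cloud import LabeledCloud, read_ply
from orchard3d.dataset import (
    CameraIntrinsics,
    DatasetVariantSpec,
    build_variants,
    center_cloud,
    cloud_to_depth,
    depth_to_cloud,
    normalize_cloud,
    sample_points,
    split_dataset,
    voxelize_labeled,
)
from orchard3d.cloud import PointCloud


K = CameraIntrinsics()


class TestDepthBackProjection:
    def test_principal_point_maps_to_optical_axis(self):
        depth = np.zeros((K.height, K.width), dtype=np.uint16)
        depth[int(K.cy), int(K.cx)] = 1000  # 1 m in millimeters
        cloud = depth_to_cloud(depth, None, K)
        assert len(cloud) == 1
        np.testing.assert_allclose(cloud.points[0], [(int(K.cx) - K.cx) / K.fx, (int(K.cy) - K.cy) / K.fy, 1.0], atol=1e-9)

    def test_zero_depth_image_gives_empty_cloud(self):
        cloud = depth_to_cloud(np.zeros((K.height, K.width), dtype=np.uint16), None, K)
        assert len(cloud) == 0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            depth_to_cloud(np.zeros((10, 10)), None, K)

    def test_back_projected_plane_satisfies_plane_equation(self):
        # analytic depth render of the plane 0.1x - 0.2y + z = 1.5
        a, b, c = 0.1, -0.2, 1.5
        u, v = np.meshgrid(np.arange(K.width), np.arange(K.height))
        denom = a * (u - K.cx) / K.fx + b * (v - K.cy) / K.fy + 1.0
        depth = c / denom  # float meters; use depth_scale = 1
        K1 = CameraIntrinsics(depth_scale=1.0)
        cloud = depth_to_cloud(depth, None, K1)
        residual = a * cloud.points[:, 0] + b * cloud.points[:, 1] + cloud.points[:, 2] - c
        assert np.abs(residual).max() < 1e-6

    def test_forward_projection_round_trip(self, rng):
        pts = np.column_stack([rng.uniform(-0.5, 0.5, 500), rng.uniform(-0.4, 0.4, 500), rng.uniform(1.0, 2.0, 500)])
        colors = rng.integers(0, 256, size=(500, 3), dtype=np.uint8)
        depth, rgb = cloud_to_depth(PointCloud(points=pts, colors=colors), K)
        back = depth_to_cloud(depth, rgb, K)
        assert len(back) > 400  # a few collisions are expected
        # every back-projected point is within quantization of an input point
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(back.points, k=1)
        assert d.max() < 5e-3


class TestCenterNormalize:
    def test_centered_centroid_is_origin(self, rng):
        out = center_cloud(rng.normal(size=(100, 3)) + 5.0)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_normalize_gives_unit_max_radius(self, rng):
        out = normalize_cloud(rng.normal(size=(100, 3)) * 3.0)
        assert np.linalg.norm(out, axis=1).max() == pytest.approx(1.0, abs=1e-12)

    def test_normalize_idempotent_on_unit_centered_cloud(self, rng):
        once = normalize_cloud(rng.normal(size=(80, 3)))
        twice = normalize_cloud(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_labels_and_counts_survive(self, rng):
        cloud = LabeledCloud(points=rng.normal(size=(30, 3)), labels=rng.integers(0, 2, 30).astype(np.uint8))
        out = normalize_cloud(cloud)
        assert len(out) == 30
        np.testing.assert_array_equal(out.labels, cloud.labels)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            center_cloud(np.zeros((0, 3)))


class TestVoxelizeLabeled:
    def test_majority_vote_with_tie_to_positive(self):
        pts = np.array([[0.001, 0, 0], [0.002, 0, 0], [0.003, 0, 0]])
        cloud = LabeledCloud(points=pts, labels=np.array([1, 1, 0], dtype=np.uint8))
        out = voxelize_labeled(cloud, 0.02)
        assert len(out) == 1 and out.labels[0] == 1
        tie = LabeledCloud(points=pts[:2], labels=np.array([1, 0], dtype=np.uint8))
        assert voxelize_labeled(tie, 0.02).labels[0] == 1

    def test_all_negative_stays_negative(self, rng):
        cloud = LabeledCloud(points=rng.normal(size=(200, 3)), labels=np.zeros(200, dtype=np.uint8))
        assert voxelize_labeled(cloud, 0.05).labels.sum() == 0

    def test_counts_shrink_and_positives_bounded(self, rng):
        cloud = LabeledCloud(points=rng.normal(size=(500, 3)) * 0.1, labels=rng.integers(0, 2, 500).astype(np.uint8))
        out = voxelize_labeled(cloud, 0.03)
        assert len(out) <= len(cloud)
        assert int(out.labels.sum()) <= int(cloud.labels.sum())


class TestSamplePoints:
    def test_small_cloud_upsampled_with_replacement(self, rng):
        cloud = LabeledCloud(points=rng.normal(size=(3, 3)), labels=np.array([0, 1, 0], dtype=np.uint8))
        out = sample_points(cloud, 5, seed=1)
        assert len(out) == 5
        rows = {tuple(p) for p in cloud.points}
        assert all(tuple(p) in rows for p in out.points)

    def test_output_length_always_npoints(self, rng):
        cloud = LabeledCloud(points=rng.normal(size=(100, 3)), labels=np.zeros(100, dtype=np.uint8))
        for n in (1, 50, 100, 173):
            assert len(sample_points(cloud, n, seed=0)) == n

    def test_fixed_seed_reproducible(self, rng):
        cloud = LabeledCloud(points=rng.normal(size=(50, 3)), labels=np.zeros(50, dtype=np.uint8))
        a = sample_points(cloud, 20, seed=9)
        b = sample_points(cloud, 20, seed=9)
        np.testing.assert_array_equal(a.points, b.points)

    def test_empty_cloud_rejected(self):
        cloud = LabeledCloud(points=np.zeros((1, 3)), labels=np.zeros(1, dtype=np.uint8))
        with pytest.raises(ValueError):
            sample_points(cloud, 0, seed=0)


class TestSplitDataset:
    def test_field_study_split_sizes(self):
        train, val, test = split_dataset(101, (0.7, 0.1, 0.2), seed=42)
        assert (len(train), len(val), len(test)) == (70, 10, 21)

    def test_small_n_floor_rule(self):
        train, val, test = split_dataset(10, (0.7, 0.1, 0.2), seed=0)
        assert (len(train), len(val), len(test)) == (7, 1, 2)

    def test_partition_is_disjoint_and_exhaustive(self):
        train, val, test = split_dataset(37, (0.7, 0.1, 0.2), seed=3)
        all_idx = np.concatenate([train, val, test])
        assert len(all_idx) == 37
        assert set(all_idx.tolist()) == set(range(37))

    def test_too_few_instances_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2, (0.7, 0.1, 0.2), seed=0)


@pytest.fixture(scope="module")
def built(tmp_path_factory):
    rng = np.random.default_rng(77)
    models = {}
    for i in range(3):
        pts = rng.normal(size=(4000, 3)) * 0.5
        labels = (rng.random(4000) < 0.2).astype(np.uint8)
        models[f"tree_1_V_{i+1}"] = LabeledCloud(points=pts, labels=labels)
    out_dir = tmp_path_factory.mktemp("dataset")
    manifest = build_variants(models, DatasetVariantSpec(seed=42), out_dir)
    return models, manifest, out_dir


class TestBuildVariants:
    def test_ten_variants_per_model(self, built):
        _, manifest, out_dir = built
        assert len(manifest["variants"]) == 10
        for vdir in out_dir.iterdir():
            if vdir.is_dir():
                assert len(list(vdir.glob("*.ply"))) == 3

    def test_voxel_counts_monotone_nonincreasing(self, built):
        _, manifest, _ = built
        sizes = [
            manifest["variants"][f"voxelized_model_{v:.4f}"]["max_points"]
            for v in DatasetVariantSpec().voxel_sizes
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_round_trip_of_written_variants(self, built):
        models, _, out_dir = built
        name = "tree_1_V_2"
        back = read_ply(out_dir / "original" / f"{name}.ply")
        np.testing.assert_array_equal(back.points, models[name].points)
        np.testing.assert_array_equal(back.labels, models[name].labels)
        csv_entries = {n: l for _, n, l in read_labels_csv(out_dir / "original" / "labels.csv")}
        np.testing.assert_array_equal(csv_entries[name], models[name].labels)

    def test_manifest_split_is_tree_level(self, built):
        _, manifest, out_dir = built
        split = json.loads((out_dir / "manifest.json").read_text())["split"]
        names = sorted(manifest["model_names"])
        assert sorted(split["train"] + split["val"] + split["test"]) == names
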