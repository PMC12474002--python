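import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import random_rotation
from orchard3d.cloud import PointCloud
from orchard3d.preprocessing import cull_background, remove_grass, reorient
from orchard3d.registration import (
    CorrespondenceSet,
    RigidTransform,
    RobustSolverConfig,
    apply_transform,
    estimate_transform_robust,
    fpfh_features,
    kabsch,
    match_features,
    rotation_geodesic_deg,
    sequential_register,
    voxel_downsample,
)
from orchard3d.synthetic import TreeSpec, build_scene, build_tree, default_view_poses, render_view
from orchard3d.pipeline import RunConfig, _true_view_transform


def _pairs(n):
    return CorrespondenceSet(np.column_stack([np.arange(n), np.arange(n)]))


class TestRigidTransform:
    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection

    def test_compose_inverse_round_trip(self, rng):
        T = RigidTransform(random_rotation(rng), rng.normal(size=3))
        pts = rng.normal(size=(40, 3))
        np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-12)
        np.testing.assert_allclose(T.compose(T.inverse()).matrix(), np.eye(4), atol=1e-12)


class TestVoxelDownsample:
    def test_points_in_one_voxel_collapse_to_centroid(self):
        out = voxel_downsample(np.array([[0.0, 0.0, 0.0], [0.005, 0.0, 0.0]]), 0.02)
        np.testing.assert_allclose(out, [[0.0025, 0.0, 0.0]], atol=1e-15)

    def test_distant_points_survive(self):
        out = voxel_downsample(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]), 0.02)
        assert len(out) == 2

    def test_uniform_grid_count_matches_grid_oracle(self):
        # 1 cm grid, 2 cm voxels: voxel occupancy is exactly ceil(k/2)^3
        axis = np.arange(10) * 0.01 + 0.0005
        g = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
        out = voxel_downsample(g, 0.02)
        assert len(out) == 5**3
        assert len(out) / len(g) == pytest.approx(1 / 8)

    def test_invalid_voxel_rejected(self):
        with pytest.raises(ValueError):
            voxel_downsample(np.zeros((3, 3)), 0.0)


class TestFPFH:
    def test_identical_clouds_identical_descriptors(self, rng):
        pts = rng.normal(size=(80, 3)) * 0.1
        a = fpfh_features(pts, 0.05, 0.12)
        b = fpfh_features(pts.copy(), 0.05, 0.12)
        np.testing.assert_array_equal(a.descriptors, b.descriptors)

    def test_descriptors_pose_invariant(self, rng):
        # a curved surface patch: neighborhoods have a well-conditioned normal
        xy = rng.uniform(-0.15, 0.15, size=(200, 2))
        z = 0.8 * xy[:, 0] ** 2 - 0.5 * xy[:, 1] ** 2 + 0.3 * xy[:, 0] * xy[:, 1]
        pts = np.column_stack([xy, z])
        R = random_rotation(rng)
        t = rng.normal(size=3)
        a = fpfh_features(pts, 0.05, 0.12)
        b = fpfh_features(pts @ R.T + t, 0.05, 0.12)
        np.testing.assert_allclose(a.descriptors, b.descriptors, atol=1e-6)

    def test_isolated_point_has_zero_descriptor(self, rng):
        pts = np.vstack([rng.normal(size=(30, 3)) * 0.05, [[50.0, 50.0, 50.0]]])
        fs = fpfh_features(pts, 0.05, 0.12)
        np.testing.assert_array_equal(fs.descriptors[-1], np.zeros(33))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fpfh_features(np.zeros((4, 3)), 0.05, 0.12)


class TestMatchFeatures:
    def test_self_match_is_identity_and_total(self, rng):
        pts = rng.normal(size=(60, 3)) * 0.1
        fs = fpfh_features(pts, 0.05, 0.12)
        corr = match_features(fs, fs)
        assert len(corr) == len(fs)
        # identity pairing wherever the descriptor is unique
        desc = fs.descriptors
        unique = np.array([(np.abs(desc - d).sum(axis=1) < 1e-12).sum() == 1 for d in desc])
        assert (corr.pairs[unique, 0] == corr.pairs[unique, 1]).all()

    def test_agrees_with_exhaustive_scan(self, rng):
        a = rng.normal(size=(150, 33)) ** 2
        b = rng.normal(size=(90, 33)) ** 2
        from orchard3d.registration import FeatureSet

        fs = FeatureSet(a, np.arange(len(a)))
        ft = FeatureSet(b, np.arange(len(b)))
        corr = match_features(fs, ft)
        brute = np.argmin(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1), axis=1)
        np.testing.assert_array_equal(corr.pairs[:, 1], brute)


class TestKabsch:
    def test_identity_on_equal_clouds(self, rng):
        pts = rng.normal(size=(30, 3))
        T = kabsch(_pairs(30), pts, pts)
        np.testing.assert_allclose(T.R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.t, np.zeros(3), atol=1e-12)

    def test_exact_recovery_of_known_transform(self, rng):
        pts = rng.normal(size=(50, 3))
        ang = np.deg2rad(30.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        t = np.array([0.4, -0.2, 1.1])
        T = kabsch(_pairs(50), pts, pts @ R.T + t)
        np.testing.assert_allclose(T.R, R, atol=1e-9)
        np.testing.assert_allclose(T.t, t, atol=1e-9)

    def test_least_squares_optimality_spot_check(self, rng):
        pts = rng.normal(size=(40, 3))
        target = pts @ random_rotation(rng).T + rng.normal(size=3) + rng.normal(0, 0.01, size=(40, 3))
        T = kabsch(_pairs(40), pts, target)
        best = np.sum((T.apply(pts) - target) ** 2)
        for _ in range(100):
            T_rand = RigidTransform(random_rotation(rng), rng.normal(size=3))
            assert best <= np.sum((T_rand.apply(pts) - target) ** 2) + 1e-12

    def test_collinear_configuration_rejected(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            kabsch(_pairs(5), line, line)


class TestRobustEstimation:
    def test_outlier_free_matches_kabsch_oracle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(100, 3))
            R, t = random_rotation(rng), rng.normal(size=3)
            target = pts @ R.T + t + rng.normal(0, 0.001, size=pts.shape)
            T_ls = kabsch(_pairs(100), pts, target)
            T_rb = estimate_transform_robust(_pairs(100), pts, target, RobustSolverConfig())
            assert rotation_geodesic_deg(T_ls.R, T_rb.R) < np.degrees(1e-6)
            np.testing.assert_allclose(T_ls.t, T_rb.t, atol=1e-6)

    def test_half_outliers_recovered(self, rng):
        pts = rng.normal(size=(100, 3))
        R, t = random_rotation(rng), rng.normal(size=3)
        target = pts @ R.T + t + rng.normal(0, 0.005, size=pts.shape)
        bad = rng.choice(100, size=50, replace=False)
        target[bad] = rng.uniform(-2, 2, size=(50, 3))
        T = estimate_transform_robust(_pairs(100), pts, target, RobustSolverConfig())
        assert rotation_geodesic_deg(T.R, R) < 2.0
        assert np.linalg.norm(T.t - t) < 0.04

    def test_all_outliers_still_returns_valid_rigid_transform(self, rng):
        pts = rng.normal(size=(50, 3))
        target = rng.uniform(-3, 3, size=(50, 3))
        T = estimate_transform_robust(_pairs(50), pts, target, RobustSolverConfig())
        np.testing.assert_allclose(T.R.T @ T.R, np.eye(3), atol=1e-9)
        assert np.linalg.det(T.R) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_transform_robust(_pairs(2), rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestApplyTransform:
    @given(st.integers(0, 2**16))
    def test_transform_then_inverse_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        T = RigidTransform(random_rotation(rng), rng.normal(size=3))
        cloud = PointCloud(points=rng.normal(size=(25, 3)), labels=rng.integers(0, 2, 25).astype(np.uint8))
        back = apply_transform(apply_transform(cloud, T), T.inverse())
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-12)
        np.testing.assert_array_equal(back.labels, cloud.labels)

    def test_pairwise_distances_preserved(self, rng):
        T = RigidTransform(random_rotation(rng), rng.normal(size=3))
        pts = rng.normal(size=(30, 3))
        out = apply_transform(pts, T)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-12)


@pytest.fixture(scope="module")
def clean_views():
    """Four noise-free preprocessed views of one synthetic tree."""
    tree = build_tree(TreeSpec(n_branches=18, point_density=2500.0, seed=31))
    scene = build_scene(tree, seed=31)
    poses = default_view_poses(depth_noise_sigma=0.0, dropout_rate=0.0)
    views = []
    for v, pose in enumerate(poses):
        view = render_view(scene, pose, seed=v)
        views.append(remove_grass(cull_background(reorient(view, 180.0, 0.0)), seed=v))
    return views


class TestSequentialRegister:
    def test_wrong_view_count_rejected(self, rng):
        clouds = [PointCloud(points=rng.normal(size=(10, 3))) for _ in range(3)]
        with pytest.raises(ValueError):
            sequential_register(clouds)

    def test_identical_views_give_identity_transforms(self, rng):
        base = voxel_downsample(rng.normal(size=(3000, 3)) * 0.4, 0.02)
        merged, transforms = sequential_register([base] * 4, RobustSolverConfig(), 0.02)
        assert len(merged) == 4 * len(base)
        for T in transforms:
            assert T.rotation_angle_deg() < 0.5
            assert np.linalg.norm(T.t) < 0.02

    def test_recovers_ground_truth_poses_on_clean_views(self, clean_views):
        merged, transforms = sequential_register(clean_views, RobustSolverConfig(), 0.02)
        assert len(merged) == sum(len(v) for v in clean_views)
        cfg = RunConfig()
        for k, T in enumerate(transforms, start=1):
            R_true, t_true = _true_view_transform(clean_views[k], clean_views[0], cfg)
            assert rotation_geodesic_deg(T.R, R_true) < 2.0
            assert np.linalg.norm(T.t - t_true) < 0.04

    def test_merged_points_land_on_their_true_positions(self, clean_views):
        # end-to-end accuracy: transformed view points lie within noise_bound
        # of where the ground-truth transform would put them
        merged, transforms = sequential_register(clean_views, RobustSolverConfig(), 0.02)
        cfg = RunConfig()
        offset = len(clean_views[0])
        for k, T in enumerate(transforms, start=1):
            R_true, t_true = _true_view_transform(clean_views[k], clean_views[0], cfg)
            estimated = T.apply(clean_views[k].points)
            true = clean_views[k].points @ R_true.T + t_true
            mean_err = np.linalg.norm(estimated - true, axis=1).mean()
            assert mean_err < RobustSolverConfig().noise_bound
            offset += len(clean_views[k])
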