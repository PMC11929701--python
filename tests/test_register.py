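import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from usnav.geometry import (RigidTransform, random_rigid_transform,
                            rotation_error_deg, translation_error_mm)
from usnav.phantom import (jitter_along_normals, make_vessel_tree,
                           sample_tree_surface)
from usnav.reconstruct import VesselPointCloud
from usnav.register import (best_rigid_fit, compute_rmsa,
                            extract_feature_points, feature_score,
                            icp_register, initial_align, register_clouds)


def _plane_cloud(n=400, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                           np.zeros(n)])
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    return VesselPointCloud(pts, normals)


def _tree_cloud(seed=1, depth=3, density=2.0):
    tree = make_vessel_tree(seed=seed, depth=depth)
    return tree, sample_tree_surface(tree, density, seed=seed + 100)


class TestFeatureScore:
    def test_parallel_normals_score_zero(self):
        scores = feature_score(_plane_cloud(), radius=3.0)
        assert np.all(np.abs(scores) < 1e-6)

    def test_isolated_point_scores_zero(self):
        pts = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        normals = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        scores = feature_score(VesselPointCloud(pts, normals), radius=1.0)
        assert np.array_equal(scores, [0.0, 0.0])

    def test_invariant_under_normal_sign_flips(self):
        _, cloud = _tree_cloud(seed=4, depth=2)
        flips = np.random.default_rng(0).integers(0, 2, len(cloud)) * 2 - 1
        flipped = VesselPointCloud(cloud.points,
                                   cloud.normals * flips[:, None])
        assert np.allclose(feature_score(cloud, 3.0),
                           feature_score(flipped, 3.0), atol=1e-12)

    def test_missing_normals_raise(self):
        with pytest.raises(ValueError):
            feature_score(VesselPointCloud(np.zeros((5, 3))), 3.0)

    def test_junction_hosts_the_top_scores(self, make_segment_tree):
        # symmetric Y of equal-radius tubes: the junction is where normals mix
        s, c = np.sin(np.radians(40.0)), np.cos(np.radians(40.0))
        tree = make_segment_tree([
            ((0, 0, 0), (0, 0, 30), 3.0),
            ((0, 0, 30), (25 * s, 0, 30 + 25 * c), 3.0),
            ((0, 0, 30), (-25 * s, 0, 30 + 25 * c), 3.0)],
            parents=[-1, 0, 0])
        junction = np.array([0.0, 0.0, 30.0])
        cloud = sample_tree_surface(tree, density=4.0, seed=2)
        scores = feature_score(cloud, radius=3.0)
        decile = np.quantile(scores, 0.9)
        top = cloud.points[scores >= decile]
        dist = np.linalg.norm(top - junction, axis=1)
        assert (dist <= 2.0 * 3.0).mean() >= 0.9


class TestExtractFeaturePoints:
    def test_straight_cylinder_selects_few_points(self, make_segment_tree):
        tree = make_segment_tree([((0, 0, 0), (0, 0, 50), 4.0)])
        cloud = sample_tree_surface(tree, density=3.0, seed=5)
        feats = extract_feature_points(cloud)
        assert len(feats) < 0.05 * len(cloud)

    def test_tree_junctions_all_covered(self):
        tree, cloud = _tree_cloud(seed=7)
        feats = extract_feature_points(cloud)
        assert len(feats) >= 7
        selected = feats.points
        for junction in tree.junctions():
            dist = np.linalg.norm(selected - junction, axis=1)
            assert dist.min() <= 2.0 * 3.0

    def test_selection_is_rigid_invariant(self):
        _, cloud = _tree_cloud(seed=9)
        t = random_rigid_transform(np.random.default_rng(1), 60.0, 40.0)
        feats = extract_feature_points(cloud)
        feats_moved = extract_feature_points(cloud.transformed(t))
        assert np.array_equal(feats.indices, feats_moved.indices)

    def test_empty_cloud_gives_empty_set(self):
        feats = extract_feature_points(VesselPointCloud(np.empty((0, 3))))
        assert len(feats) == 0

    def test_selected_scores_meet_threshold_and_spacing(self):
        _, cloud = _tree_cloud(seed=11)
        feats = extract_feature_points(cloud, score_threshold=0.2,
                                       nms_radius=1.0)
        assert np.all(feats.scores >= 0.2)
        pts = feats.points
        diffs = np.linalg.norm(pts[None] - pts[:, None], axis=-1)
        np.fill_diagonal(diffs, np.inf)
        assert diffs.min() > 1.0


class TestBestRigidFit:
    def test_identity_when_target_equals_source(self):
        src = np.random.default_rng(0).normal(size=(30, 3)) * 10
        fit = best_rigid_fit(src, src)
        assert np.allclose(fit.matrix, np.eye(4), atol=1e-12)

    def test_exact_recovery_of_known_transform(self):
        rng = np.random.default_rng(1)
        src = rng.normal(size=(50, 3)) * 20
        t = random_rigid_transform(rng, 90.0, 50.0)
        fit = best_rigid_fit(src, t.apply(src))
        assert rotation_error_deg(fit, t) < 1e-9
        assert translation_error_mm(fit, t) < 1e-9

    def test_matches_nonlinear_least_squares_oracle(self):
        from scipy.optimize import least_squares
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        src = rng.normal(size=(100, 3)) * 15
        t = random_rigid_transform(rng, 30.0, 20.0)
        tgt = t.apply(src) + rng.normal(0, 0.1, size=src.shape)
        fit = best_rigid_fit(src, tgt)
        fit_rms = np.sqrt(np.mean(np.sum((fit.apply(src) - tgt) ** 2, axis=1)))

        def residuals(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            return (src @ rot.T + params[3:] - tgt).ravel()

        sol = least_squares(residuals, np.zeros(6), xtol=1e-15, ftol=1e-15,
                            gtol=1e-15)
        oracle_rms = np.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 3) ** 2, axis=1)))
        assert abs(fit_rms - oracle_rms) < 1e-6

    def test_degenerate_configurations_raise(self):
        line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            best_rigid_fit(line, line)
        with pytest.raises(ValueError):
            best_rigid_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.booleans())
    def test_output_is_always_a_proper_rigid_transform(self, seed, planar):
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(25, 3)) * 10
        if planar:
            src[:, 2] *= 1e-6   # near-planar configuration
        t = random_rigid_transform(rng, 170.0, 80.0)
        tgt = t.apply(src) + rng.normal(0, 0.05, size=src.shape)
        fit = best_rigid_fit(src, tgt)   # constructor enforces invariants
        assert abs(np.linalg.det(fit.rotation) - 1.0) < 1e-9

    def test_weighted_fit_prefers_heavy_pairs(self):
        src = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [5.0, 5, 0]])
        tgt = src + [1.0, 0.0, 0.0]
        tgt[3] += [0.0, 5.0, 0.0]    # outlier pair
        w = np.array([1.0, 1.0, 1.0, 1e-9])
        fit = best_rigid_fit(src, tgt, weights=w)
        assert np.allclose(fit.translation, [1.0, 0.0, 0.0], atol=1e-3)


class TestInitialAlign:
    def test_identity_for_identical_sets(self):
        _, cloud = _tree_cloud(seed=3)
        feats = extract_feature_points(cloud)
        init = initial_align(feats, feats)
        assert rotation_error_deg(init, RigidTransform.identity()) < 1e-6
        assert translation_error_mm(init, RigidTransform.identity()) < 1e-6

    def test_translation_recovered_exactly(self):
        _, cloud = _tree_cloud(seed=3)
        feats = extract_feature_points(cloud)
        shift = RigidTransform.from_rotation_translation(np.eye(3),
                                                         [7.0, -4.0, 2.0])
        feats_shifted = extract_feature_points(cloud.transformed(shift))
        init = initial_align(feats, feats_shifted)
        assert translation_error_mm(init, shift) < 1e-9
        assert rotation_error_deg(init, shift) < 1e-9

    def test_180_degree_rotation_of_asymmetric_set(self):
        _, cloud = _tree_cloud(seed=13)
        feats = extract_feature_points(cloud)
        t = RigidTransform.from_rotvec_translation([0.0, 0.0, np.pi],
                                                   [0.0, 0.0, 0.0])
        feats_rot = extract_feature_points(cloud.transformed(t))
        init = initial_align(feats, feats_rot)
        moved = init.apply(feats.points)
        rms = np.sqrt(np.mean(np.min(
            np.linalg.norm(moved[:, None] - feats_rot.points[None], axis=-1),
            axis=1) ** 2))
        assert rms < 1e-6

    def test_collinear_sets_raise(self):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        normals = np.tile([0.0, 0.0, 1.0], (5, 1))
        cloud = VesselPointCloud(pts, normals)
        from usnav.register import FeaturePointSet
        feats = FeaturePointSet(cloud, np.arange(5), np.ones(5))
        with pytest.raises(ValueError):
            initial_align(feats, feats)


class TestComputeRmsa:
    def test_exact_values(self):
        assert compute_rmsa([0.0, 0.0, 0.0]) == 0.0
        assert compute_rmsa([2.0]) == 2.0
        assert compute_rmsa([3.0, 4.0]) == pytest.approx(3.5355339059327378,
                                                         abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compute_rmsa([])


class TestIcpRegister:
    def test_identity_case_converges_immediately(self):
        _, cloud = _tree_cloud(seed=6)
        feats = extract_feature_points(cloud)
        result = icp_register(feats, feats, init=RigidTransform.identity())
        assert result.rmsa == 0.0
        assert result.converged
        assert result.iterations <= 2
        assert rotation_error_deg(result.transform,
                                  RigidTransform.identity()) < 1e-9

    def test_noiseless_hidden_transform_recovered(self):
        _, cloud = _tree_cloud(seed=17)
        hidden = random_rigid_transform(np.random.default_rng(5), 15.0, 30.0)
        result = register_clouds(cloud.transformed(hidden), cloud)
        assert rotation_error_deg(result.transform, hidden.inverse()) < 0.1
        assert translation_error_mm(result.transform, hidden.inverse()) < 0.05
        assert result.rmsa < 1e-3

    def test_rmsa_matches_correspondence_distances(self):
        tree, cloud = _tree_cloud(seed=19)
        rng = np.random.default_rng(3)
        hidden = random_rigid_transform(rng, 10.0, 20.0)
        moving = jitter_along_normals(cloud, 0.05, rng).transformed(hidden)
        fixed = jitter_along_normals(cloud, 0.05, rng)
        result = register_clouds(moving, fixed)
        dists = [d for _, _, d in result.correspondences]
        assert result.rmsa == pytest.approx(compute_rmsa(dists), abs=1e-9)

    def test_rmsa_history_is_monotone_non_increasing(self):
        _, cloud = _tree_cloud(seed=23)
        rng = np.random.default_rng(4)
        hidden = random_rigid_transform(rng, 15.0, 30.0)
        moving = jitter_along_normals(cloud, 0.05, rng).transformed(hidden)
        fixed = jitter_along_normals(cloud, 0.05, rng)
        result = register_clouds(moving, fixed)
        history = np.array(result.history)
        assert np.all(np.diff(history) <= 1e-12)

    def test_equivariance_under_source_premultiplication(self):
        _, cloud = _tree_cloud(seed=29)
        rng = np.random.default_rng(6)
        hidden = random_rigid_transform(rng, 12.0, 25.0)
        moving = jitter_along_normals(cloud, 0.05, rng).transformed(hidden)
        fixed = jitter_along_normals(cloud, 0.05, rng)
        extra = random_rigid_transform(rng, 20.0, 15.0)
        base = register_clouds(moving, fixed).transform
        shifted = register_clouds(moving.transformed(extra), fixed).transform
        recombined = shifted @ extra
        assert rotation_error_deg(recombined, base) < 1e-6
        assert translation_error_mm(recombined, base) < 1e-6

    def test_empty_feature_sets_raise(self):
        from usnav.register import FeaturePointSet
        cloud = VesselPointCloud(np.zeros((0, 3)))
        empty = FeaturePointSet(cloud, np.empty(0, dtype=int), np.empty(0))
        with pytest.raises(ValueError):
            icp_register(empty, empty)
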