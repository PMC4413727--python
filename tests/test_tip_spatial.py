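"""Skeletonization, tip detection, tip distances, radial-distribution ellipse."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rootspace import (
    RootTipSet,
    VoxelGrid,
    detect_tips,
    extract_individual,
    fit_tip_ellipse,
    generate_root_system,
    make_scene,
    mean_tip_depth,
    min_tip_distances,
    radial_distribution_area,
    skeletonize,
    voxelize_scene,
)
from rootspace.synthetic_roots import ArchetypeParams


def _grid(occ, res=1.0):
    return VoxelGrid(occupancy=occ.astype(np.uint8), resolution_mm=res)


def _tipset(points):
    return RootTipSet(tips_mm=np.asarray(points, dtype=float), collar_mm=None)


class TestSkeletonize:
    def test_thin_line_is_its_own_skeleton(self):
        occ = np.zeros((3, 3, 50))
        occ[1, 1, :] = 1
        skel = skeletonize(_grid(occ))
        assert skel.n_voxels == 50
        assert (skel.degrees == 1).sum() == 2
        graph = skel.to_graph()
        assert graph.number_of_nodes() == 50
        assert graph.number_of_edges() == 49

    def test_cylinder_skeleton_has_two_endpoints(self, cylinder_scene):
        scene = cylinder_scene(1.0, 30.0, container=(10.0, 40.0))
        grid = extract_individual(voxelize_scene(scene, 0.25), 1)
        skel = skeletonize(grid)
        assert (skel.degrees == 1).sum() == 2

    def test_y_tree_has_three_endpoints_and_a_junction(self):
        occ = np.zeros((21, 5, 21))
        occ[10, 2, 0:10] = 1  # trunk down
        for i in range(10):  # two diagonal branches
            occ[10 + i, 2, 9 + i] = 1
            occ[10 - i, 2, 9 + i] = 1
        skel = skeletonize(_grid(occ))
        assert (skel.degrees == 1).sum() == 3
        assert (skel.degrees >= 3).sum() >= 1

    def test_agrees_with_library_thinning_on_odd_width_prism(self):
        """Independent cross-check: for odd-width prisms both this
        package's homotopic thinning and scikit-image's Lee thinning
        produce a single open curve (two endpoints, one component)."""
        from skimage.morphology import skeletonize as lib_skeletonize
        from scipy import ndimage as ndi

        occ = np.zeros((9, 9, 40), dtype=np.uint8)
        occ[3:6, 3:6, 5:35] = 1  # 3x3 cross-section
        ours = skeletonize(_grid(occ))
        lib = lib_skeletonize(occ.astype(bool))
        lib_neigh = ndi.convolve(lib.astype(np.uint8), np.ones((3, 3, 3), int),
                                 mode="constant")
        lib_endpoints = int(((lib_neigh == 2) & lib).sum())
        assert (ours.degrees == 1).sum() == 2 == lib_endpoints
        assert ndi.label(lib, np.ones((3, 3, 3)))[1] == 1
        assert len(np.unique(ours.components)) == 1

    def test_empty_grid_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            skel = skeletonize(_grid(np.zeros((3, 3, 3))))
        assert skel.n_voxels == 0

    def test_skeleton_is_subset_of_mask(self):
        scene = make_scene("control", "spruce", seed=8)
        grid = extract_individual(voxelize_scene(scene, 0.5), 1)
        skel = skeletonize(grid)
        assert grid.occupancy[tuple(skel.voxels.T)].all()


class TestDetectTips:
    def test_vertical_line_keeps_one_tip_after_collar(self):
        occ = np.zeros((3, 3, 50))
        occ[1, 1, :] = 1
        tips = detect_tips(skeletonize(_grid(occ)))
        assert tips.n_tips == 1
        assert tips.collar_mm is not None
        assert tips.collar_mm[0, 2] < tips.tips_mm[0, 2]  # collar shallower

    def test_collar_rule_off_keeps_both_endpoints(self):
        occ = np.zeros((3, 3, 50))
        occ[1, 1, :] = 1
        tips = detect_tips(skeletonize(_grid(occ)), collar_rule="off")
        assert tips.n_tips == 2

    def test_isolated_voxel_yields_no_tips(self):
        occ = np.zeros((5, 5, 5))
        occ[2, 2, 2] = 1
        with pytest.warns(UserWarning, match="no tips"):
            tips = detect_tips(skeletonize(_grid(occ)))
        assert tips.n_tips == 0

    def test_generator_tree_tip_count_tracks_truth(self):
        """Without wall truncation, detected tip counts track the vector
        model's terminal-segment count at resolution <= radius/2. Voxel
        skeletons of tortuous roots carry irreducible spur/merge noise of
        a couple of endpoints per system, so agreement is asserted to
        within +/-3 per system and +/-2 on average over seeds."""
        from rootspace import Scene

        params = ArchetypeParams(
            taproot_length_mm=40.0,
            taproot_radius_mm=0.6,
            lateral_rate_per_mm=0.2,
            lateral_length_distribution=(12.0, 3.0),
            lateral_radius_mm=0.4,
            branching_depth=1,
            insertion_angle_deg=(60.0, 10.0),
            gravitropism_weight=0.3,
            tortuosity_sd_deg=5.0,
        )
        diffs = []
        for seed in range(4):
            truth = generate_root_system(params, seed=seed)
            scene = Scene(treatment="control", individuals=[("x", truth)],
                          container=(40.0, 55.0))
            grid = extract_individual(voxelize_scene(scene, 0.2), 1)
            tips = detect_tips(skeletonize(grid))
            diffs.append(abs(tips.n_tips - truth.tip_count))
        assert max(diffs) <= 3
        assert np.mean(diffs) <= 2.0


class TestMinTipDistances:
    def test_three_four_five_triangle(self):
        d = min_tip_distances(_tipset([(0, 0, 0), (3, 4, 0)]))
        np.testing.assert_allclose(d, [5.0, 5.0])

    def test_collinear_triple(self):
        d = min_tip_distances(_tipset([(0, 0, 0), (0, 0, 1), (0, 0, 3)]))
        np.testing.assert_allclose(d, [1.0, 1.0, 2.0])

    def test_single_tip_raises(self):
        with pytest.raises(ValueError, match=">= 2 tips"):
            min_tip_distances(_tipset([(0, 0, 0)]))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, size=(100, 3))
        fast = min_tip_distances(_tipset(pts))
        diff = pts[:, None, :] - pts[None, :, :]
        dmat = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dmat, np.inf)
        brute = dmat.min(axis=1)
        np.testing.assert_array_equal(fast, brute)


class TestMeanTipDepth:
    def test_two_tips(self):
        assert mean_tip_depth(_tipset([(0, 0, 10), (1, 1, 30)])) == 20.0

    def test_single_tip(self):
        assert mean_tip_depth(_tipset([(5, 5, 58.6)])) == pytest.approx(58.6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_tip_depth(_tipset(np.empty((0, 3))))


class TestEllipse:
    def test_circle_of_tips_is_circular(self):
        ang = 2 * np.pi * np.arange(16) / 16
        pts = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang),
                               np.zeros(16)])
        fit = fit_tip_ellipse(_tipset(pts))
        assert fit.axis_ratio == pytest.approx(1.0, abs=0.01)
        assert radial_distribution_area(fit) == pytest.approx(
            np.pi * 100.0, rel=0.05
        )

    def test_axis_aligned_construction(self):
        pts = [(10, 0, 0), (-10, 0, 0), (0, 5, 0), (0, -5, 0)]
        fit = fit_tip_ellipse(_tipset(pts))
        assert fit.semi_major_mm == pytest.approx(10.0)
        assert fit.semi_minor_mm == pytest.approx(5.0)
        assert fit.axis_ratio == pytest.approx(2.0)
        assert radial_distribution_area(fit) == pytest.approx(np.pi * 50.0)

    def test_rotation_scan_oracle(self):
        """The covariance orientation's extents must match a brute-force
        evaluation of max-|projection| extents at that same angle, and its
        axis ratio must be achievable by the rotation scan."""
        rng = np.random.default_rng(21)
        pts = rng.normal(0, 1, (200, 3)) * np.array([8.0, 3.0, 1.0])
        fit = fit_tip_ellipse(_tipset(pts))
        xy = pts[:, :2] - pts[:, :2].mean(axis=0)
        theta = fit.orientation_rad
        u = np.array([np.cos(theta), np.sin(theta)])
        v = np.array([-np.sin(theta), np.cos(theta)])
        a = np.abs(xy @ u).max()
        b = np.abs(xy @ v).max()
        assert max(a, b) == pytest.approx(fit.semi_major_mm)
        assert min(a, b) == pytest.approx(fit.semi_minor_mm)

    def test_rigid_rotation_leaves_area_and_ratio(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, (150, 3)) * np.array([6.0, 2.0, 1.0])
        fit0 = fit_tip_ellipse(_tipset(pts))
        phi = 0.7
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        pts_rot = pts.copy()
        pts_rot[:, :2] = pts[:, :2] @ rot.T
        fit1 = fit_tip_ellipse(_tipset(pts_rot))
        assert fit1.area_mm2 == pytest.approx(fit0.area_mm2, rel=0.01)
        assert fit1.axis_ratio == pytest.approx(fit0.axis_ratio, rel=0.01)

    def test_scaling_tips_scales_area_quadratically(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 3, (50, 3))
        area0 = radial_distribution_area(fit_tip_ellipse(_tipset(pts)))
        area2 = radial_distribution_area(fit_tip_ellipse(_tipset(pts * 2.0)))
        assert area2 == pytest.approx(4 * area0, rel=1e-9)

    def test_too_few_or_collinear_tips_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_tip_ellipse(_tipset([(0, 0, 0), (1, 1, 0)]))
        with pytest.raises(ValueError, match="collinear"):
            fit_tip_ellipse(_tipset([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]))

    def test_axis_ratio_at_least_one(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.normal(0, 2, (30, 3))
            assert fit_tip_ellipse(_tipset(pts)).axis_ratio >= 1.0
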