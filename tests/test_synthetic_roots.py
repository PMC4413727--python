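"""Root-scene generator: growth model, voxelization, experiment designs."""

import numpy as np
import pytest

from rootspace import (
    ArchetypeParams,
    ASPEN_LIKE,
    SPRUCE_LIKE,
    Scene,
    extract_individual,
    generate_root_system,
    make_experiment,
    make_scene,
    root_volume,
    voxelize_scene,
)
from rootspace.synthetic_roots import truncate_at_wall, wall_truncated_scene

BARE = ArchetypeParams(
    taproot_length_mm=100.0,
    taproot_radius_mm=1.0,
    lateral_rate_per_mm=0.0,
    lateral_length_distribution=(10.0, 2.0),
    lateral_radius_mm=0.5,
    branching_depth=1,
    insertion_angle_deg=(60.0, 10.0),
    gravitropism_weight=0.5,
    tortuosity_sd_deg=3.0,
)


class TestGenerateRootSystem:
    def test_zero_lateral_rate_gives_bare_taproot(self):
        truth = generate_root_system(BARE, seed=1)
        assert truth.tip_count == 1
        assert truth.analytic_length_mm == pytest.approx(100.0)

    def test_same_params_and_seed_reproduce_segments(self):
        a = generate_root_system(ASPEN_LIKE, seed=11)
        b = generate_root_system(ASPEN_LIKE, seed=11)
        assert len(a.segments) == len(b.segments)
        for (s1, e1, r1, p1), (s2, e2, r2, p2) in zip(a.segments, b.segments):
            np.testing.assert_array_equal(s1, s2)
            np.testing.assert_array_equal(e1, e2)
            assert (r1, p1) == (r2, p2)

    def test_lateral_count_matches_poisson_expectation(self):
        """Laterals arise as Poisson(rate x length); mean over replicates
        must sit within 3 standard errors of the thinned expectation."""
        params = ArchetypeParams(
            taproot_length_mm=100.0,
            taproot_radius_mm=1.0,
            lateral_rate_per_mm=0.05,
            lateral_length_distribution=(5.0, 1.0),
            lateral_radius_mm=0.4,
            branching_depth=1,
            insertion_angle_deg=(60.0, 10.0),
            gravitropism_weight=0.3,
            tortuosity_sd_deg=5.0,
        )
        counts = [
            generate_root_system(params, seed=s).tip_count - 1
            for s in range(200)
        ]
        # apical step never branches: expectation = rate * (steps - 1)
        expect = 0.05 * 99.0
        se = np.sqrt(expect / 200)
        assert abs(np.mean(counts) - expect) <= 3 * se

    def test_tree_invariants(self):
        truth = generate_root_system(ASPEN_LIKE, seed=4)
        parents = [p for _, _, _, p in truth.segments]
        assert parents.count(-1) == 1  # single collar segment
        for i, p in enumerate(parents):
            assert p < i  # parents precede children
        lengths = [np.linalg.norm(e - s) for s, e, _, _ in truth.segments]
        radii = [r for _, _, r, _ in truth.segments]
        assert truth.analytic_length_mm == pytest.approx(sum(lengths))
        assert truth.analytic_volume_mm3 == pytest.approx(
            sum(np.pi * r**2 * l for r, l in zip(radii, lengths))
        )
        assert truth.analytic_surface_area_mm2 == pytest.approx(
            sum(2 * np.pi * r * l for r, l in zip(radii, lengths))
        )


class TestVoxelizeScene:
    def test_cylinder_volume_within_5_percent(self, cylinder_scene):
        scene = cylinder_scene(2.0, 20.0)
        vol = voxelize_scene(scene, 0.25)
        grid = extract_individual(vol, 1)
        expected = np.pi * 4.0 * 20.0
        assert root_volume(grid) == pytest.approx(expected, rel=0.05)

    def test_voxel_error_shrinks_on_refinement(self, cylinder_scene):
        scene = cylinder_scene(2.0, 20.0)
        expected = np.pi * 4.0 * 20.0
        errs = []
        for res in (1.0, 0.25):
            grid = extract_individual(voxelize_scene(scene, res), 1)
            errs.append(abs(root_volume(grid) - expected))
        assert errs[1] < errs[0]

    def test_two_disjoint_systems_superpose(self):
        """Per-label voxel counts of a two-individual scene equal the counts
        from voxelizing each individual alone (no-overlap superposition)."""
        from conftest import cylinder_truth

        t1 = cylinder_truth(1.5, 15.0, xy=(-8.0, 0.0))
        t2 = cylinder_truth(1.0, 20.0, xy=(8.0, 0.0))
        pair = Scene(
            treatment="intra",
            individuals=[("aspen", t1), ("aspen", t2)],
            container=(30.0, 40.0),
        )
        vol = voxelize_scene(pair, 0.5)
        for ind_id, truth in ((1, t1), (2, t2)):
            solo = Scene(
                treatment="control",
                individuals=[("aspen", truth)],
                container=(30.0, 40.0),
            )
            solo_vol = voxelize_scene(solo, 0.5)
            assert (vol.labels == ind_id).sum() == (solo_vol.labels == 1).sum()

    def test_empty_scene_allowed_via_make_experiment(self):
        assert make_experiment([], base_seed=0) == []

    def test_thin_radius_warns(self, cylinder_scene):
        scene = cylinder_scene(0.2, 10.0)
        with pytest.warns(UserWarning, match="undersampled"):
            voxelize_scene(scene, 1.0)


class TestWallExclusion:
    def test_truncation_removes_material(self):
        """A crowded pair reaches the wall, so cutting at the wall strictly
        shrinks the scene's total length and volume (and never grows any
        individual)."""
        scene = make_scene("intra", "aspen", seed=7)
        full_len = full_vol = cut_len = cut_vol = 0.0
        for _, truth in scene.individuals:
            cut = truncate_at_wall(truth, scene.container)
            assert cut.analytic_length_mm <= truth.analytic_length_mm
            assert cut.analytic_volume_mm3 <= truth.analytic_volume_mm3
            full_len += truth.analytic_length_mm
            full_vol += truth.analytic_volume_mm3
            cut_len += cut.analytic_length_mm
            cut_vol += cut.analytic_volume_mm3
        assert cut_len < full_len
        assert cut_vol < full_vol

    def test_no_voxel_center_closer_to_wall_than_radius(self):
        scene = make_scene("intra", "aspen", seed=7)
        res = 0.5
        vol = voxelize_scene(scene, res, wall_exclusion=True)
        occ = np.argwhere(vol.labels > 0).astype(float)
        d = scene.container[0]
        xy = (occ[:, :2] + 0.5) * res - d / 2.0
        radial = np.hypot(xy[:, 0], xy[:, 1])
        min_radius = min(
            r for _, t in scene.individuals for _, _, r, _ in t.segments
        )
        # centers lie within (wall - segment_radius) + in-plane half diagonal
        assert radial.max() <= d / 2.0 - min_radius + res * np.sqrt(0.5) + 1e-9

    def test_truncated_scene_keeps_tree_structure(self):
        scene = make_scene("inter", ("aspen", "spruce"), seed=9)
        cut = wall_truncated_scene(scene)
        for _, truth in cut.individuals:
            parents = [p for _, _, _, p in truth.segments]
            for i, p in enumerate(parents):
                assert p < i


class TestMakeExperiment:
    def test_study_roster_gives_13_scenes(self):
        design = [
            ("control", "aspen", 3),
            ("intra", "aspen", 1),
            ("inter", ("aspen", "spruce"), 3),
            ("intra", "spruce", 3),
            ("control", "spruce", 3),
        ]
        scenes = make_experiment(design, base_seed=0)
        assert len(scenes) == 13
        assert sum(len(s.individuals) for s in scenes) == 20

    def test_single_control_replicate(self):
        scenes = make_experiment([("control", "spruce", 1)], base_seed=5)
        assert len(scenes) == 1
        assert len(scenes[0].individuals) == 1

    def test_same_base_seed_reproduces_scene_list(self):
        design = [("intra", "aspen", 2)]
        a = make_experiment(design, base_seed=3)
        b = make_experiment(design, base_seed=3)
        for sa, sb in zip(a, b):
            for (_, ta), (_, tb) in zip(sa.individuals, sb.individuals):
                assert ta.tip_count == tb.tip_count
                np.testing.assert_allclose(
                    np.asarray(ta.tip_coordinates),
                    np.asarray(tb.tip_coordinates),
                )

    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError, match="treatment"):
            make_experiment([("mystery", "aspen", 1)], base_seed=0)


class TestSceneInvariants:
    def test_intra_pair_must_share_species(self, cylinder_scene):
        t1 = cylinder_scene(1.0, 10.0).individuals[0][1]
        with pytest.raises(ValueError, match="share a species"):
            Scene(treatment="intra", individuals=[("aspen", t1), ("spruce", t1)])

    def test_control_has_one_individual(self, cylinder_scene):
        t1 = cylinder_scene(1.0, 10.0).individuals[0][1]
        with pytest.raises(ValueError, match="exactly 1"):
            Scene(treatment="control", individuals=[("a", t1), ("a", t1)])
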