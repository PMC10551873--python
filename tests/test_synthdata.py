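"""Simulator: scene sampling, rendering, ground truth, motion."""

import numpy as np
import pytest

from rodtrack.config import OpticsConfig
from rodtrack.synthdata import (BubbleSpec, GroundTruthTrajectory, MotorPose,
                                Scene, capsule_mask, make_training_set,
                                render_frame, render_ground_truth,
                                sample_scene, simulate_video)


class TestSampleScene:
    @pytest.mark.parametrize("n_motors,n_bubbles", [(3, 2), (0, 0), (1, 5)])
    def test_counts(self, optics128, n_motors, n_bubbles):
        scene = sample_scene(optics128, n_motors, n_bubbles, seed=3)
        assert len(scene.motors) == n_motors
        background = [b for b in scene.bubbles if b.kind == "background"]
        trailing = [b for b in scene.bubbles if b.kind == "trailing"]
        assert len(background) == n_bubbles
        # each motor drags a plume of 2-5 exhaust bubbles
        assert 2 * n_motors <= len(trailing) <= 5 * n_motors

    def test_seeded_determinism(self, optics128):
        a = sample_scene(optics128, 3, 2, seed=7)
        b = sample_scene(optics128, 3, 2, seed=7)
        assert a == b

    def test_motors_inside_bounds(self, optics128):
        scene = sample_scene(optics128, 20, 0, seed=1)
        for m in scene.motors:
            assert 0 <= m.x < optics128.image_width
            assert 0 <= m.y < optics128.image_height

    def test_negative_count_rejected(self, optics128):
        with pytest.raises(ValueError):
            sample_scene(optics128, -1, 0, seed=0)

    def test_trailing_bubbles_behind_tail(self, optics128):
        """Exhaust bubbles sit beyond the rod end opposite the heading."""
        scene = sample_scene(optics128, 1, 0, seed=2)
        m = scene.motors[0]
        back = np.array([-np.cos(m.heading_phi), -np.sin(m.heading_phi)])
        for b in scene.bubbles:
            assert b.kind == "trailing"
            offset = np.array([b.x - m.x, b.y - m.y])
            # projection onto the reversed heading clears the rod tail
            assert offset @ back > m.length / 2 - 1e-9


class TestRenderFrame:
    def test_empty_scene_uniform(self, optics_clean):
        img = render_frame(Scene(), optics_clean)
        assert img.shape == optics_clean.shape
        assert np.allclose(img, optics_clean.background_level, atol=1e-6)

    def test_dark_rod_minimum_inside_capsule(self, optics_clean):
        pose = MotorPose(60.0, 70.0, 0.5)
        img = render_frame(Scene(motors=[pose]), optics_clean)
        footprint = capsule_mask(optics_clean.shape, pose.x, pose.y,
                                 pose.heading_phi, pose.length, pose.width)
        ys, xs = np.unravel_index(img.argmin(), img.shape)
        assert footprint[ys, xs] == 1

    def test_axial_symmetry_of_rendering(self, optics_clean):
        """A capsule is symmetric under heading -> heading + pi."""
        a = render_frame(Scene(motors=[MotorPose(64, 64, 0.0)]), optics_clean)
        b = render_frame(Scene(motors=[MotorPose(64, 64, np.pi)]), optics_clean)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_range_and_determinism(self, optics128):
        scene = sample_scene(optics128, 2, 2, seed=5)
        a = render_frame(scene, optics128)
        b = render_frame(scene, optics128)
        assert a.min() >= 0 and a.max() <= 1
        np.testing.assert_array_equal(a, b)


class TestGroundTruth:
    def test_bubbles_excluded(self, optics128):
        bubbles = [BubbleSpec(40, 40, 8.0), BubbleSpec(70, 70, 3.0, "trailing")]
        mask = render_ground_truth(Scene(bubbles=bubbles), optics128)
        assert mask.sum() == 0

    def test_bubble_deletion_leaves_mask_unchanged(self, optics128):
        scene = sample_scene(optics128, 3, 4, seed=9)
        full = render_ground_truth(scene, optics128)
        bare = render_ground_truth(
            Scene(motors=scene.motors, bubbles=[]), optics128)
        np.testing.assert_array_equal(full, bare)

    def test_filled_area_matches_capsule_formula(self, optics128):
        length, width = 10.0, 3.0
        scene = Scene(motors=[MotorPose(64.3, 60.7, 0.4, length, width)])
        mask = render_ground_truth(scene, optics128, "filled")
        analytic = width * (length - width) + np.pi * (width / 2) ** 2
        assert abs(mask.sum() - analytic) / analytic < 0.15

    def test_outline_within_boundary_band(self, optics128):
        from scipy.ndimage import binary_erosion

        scene = sample_scene(optics128, 2, 0, seed=4)
        filled = render_ground_truth(scene, optics128, "filled").astype(bool)
        outline = render_ground_truth(scene, optics128, "outline").astype(bool)
        band = filled & ~binary_erosion(filled, iterations=3)
        assert np.all(~outline | band)

    def test_filled_centroid_matches_pose(self, optics128):
        pose = MotorPose(58.2, 71.6, 1.1)
        mask = render_ground_truth(Scene(motors=[pose]), optics128, "filled")
        ys, xs = np.nonzero(mask)
        assert abs(xs.mean() - pose.x) < 0.5
        assert abs(ys.mean() - pose.y) < 0.5

    def test_bad_mode_rejected(self, optics128):
        with pytest.raises(ValueError):
            render_ground_truth(Scene(), optics128, "solid")


class TestSimulateVideo:
    def test_stationary_motor(self, optics_clean):
        scene = Scene(motors=[MotorPose(64, 64, 0.3)])
        _, masks, trajs = simulate_video(scene, 10, motion=[(0.0, 0.0)],
                                         optics=optics_clean, render=False)
        poses = [p for _, p in trajs[0].poses]
        assert len(poses) == 10
        assert all(p == poses[0] for p in poses)

    def test_straight_motion_update_rule(self, optics_clean):
        scene = Scene(motors=[MotorPose(10, 64, 0.0)])
        _, _, trajs = simulate_video(scene, 15, motion=[(2.0, 0.0)],
                                     optics=optics_clean, render=False)
        xs = trajs[0].xy()[:, 0]
        np.testing.assert_allclose(xs, 10 + 2.0 * np.arange(15), atol=1e-12)
        np.testing.assert_allclose(trajs[0].xy()[:, 1], 64.0, atol=1e-12)

    def test_turning_closes_orbit(self, optics_clean):
        """omega = 2*pi/20 per frame returns to the initial heading after
        20 steps."""
        scene = Scene(motors=[MotorPose(64, 64, 0.25)])
        omega = 2 * np.pi / 20
        _, _, trajs = simulate_video(scene, 21, motion=[(1.5, omega)],
                                     optics=optics_clean, render=False)
        phi0 = trajs[0].poses[0][1].heading_phi
        phi20 = trajs[0].poses[20][1].heading_phi
        assert abs((phi20 - phi0 + np.pi) % (2 * np.pi) - np.pi) < 1e-9

    def test_circular_motion_is_concyclic(self, optics_clean):
        """Constant (v, omega) traces a regular polygon inscribed in a
        circle: every chord has length exactly v, and the circumradius is
        v / (2 sin(|omega|/2)), which approaches v/|omega| for small turn
        rates."""
        v, omega = 2.0, 0.12
        scene = Scene(motors=[MotorPose(64, 64, 1.0)])
        _, _, trajs = simulate_video(scene, 30, motion=[(v, omega)],
                                     optics=optics_clean, render=False)
        xy = trajs[0].xy()
        chords = np.hypot(*np.diff(xy, axis=0).T)
        np.testing.assert_allclose(chords, v, atol=1e-9)
        radius = v / (2 * np.sin(omega / 2))
        # exact center from the update-rule algebra: the displacement
        # directions rotate uniformly, so the path sums a geometric
        # series of unit phasors
        z0 = xy[0, 0] + 1j * xy[0, 1]
        phi0 = 1.0
        center = z0 + v * np.exp(1j * phi0) / (1 - np.exp(1j * omega))
        dists = np.abs((xy[:, 0] + 1j * xy[:, 1]) - center)
        np.testing.assert_allclose(dists, radius, atol=1e-6)
        assert abs(radius - v / omega) < 0.05 * v / omega

    def test_wrap_boundary_keeps_positions_inside(self, optics_clean):
        scene = Scene(motors=[MotorPose(100, 64, 0.0)])
        _, _, trajs = simulate_video(scene, 40, motion=[(10.0, 0.0)],
                                     optics=optics_clean, boundary="wrap",
                                     render=False)
        xy = trajs[0].xy()
        assert xy[:, 0].max() < optics_clean.image_width
        assert xy[:, 0].min() >= 0

    def test_masks_track_motion(self, optics_clean):
        scene = Scene(motors=[MotorPose(30, 64, 0.0)])
        _, masks, trajs = simulate_video(scene, 5, motion=[(4.0, 0.0)],
                                         optics=optics_clean, render=False)
        for mask, (_, pose) in zip(masks, trajs[0].poses):
            ys, xs = np.nonzero(mask)
            assert abs(xs.mean() - pose.x) < 0.5


class TestMakeTrainingSet:
    def test_pair_count_and_alignment(self, optics128):
        frames, masks = make_training_set(8, optics128, seed=21)
        assert frames.shape == (8, 128, 128)
        assert masks.shape == (8, 128, 128)
        assert set(np.unique(masks)) <= {0, 1}
        # aligned: mask pixels are dark in the rendered frame (dark rods)
        for f, m in zip(frames, masks):
            if m.sum():
                assert f[m > 0].mean() < f[m == 0].mean()

    def test_determinism(self, optics128):
        a = make_training_set(4, optics128, seed=13)
        b = make_training_set(4, optics128, seed=13)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_masks_sparse(self, optics128):
        _, masks = make_training_set(16, optics128, seed=2)
        assert (masks.mean(axis=(1, 2)) <= 0.5).all()
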