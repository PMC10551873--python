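"""Axial angles, calibrated velocities, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rodtrack.config import CameraCalibration, LinkConfig
from rodtrack.detect import Detection
from rodtrack.kinematics import (axial_difference, compute_kinematics,
                                 summarize)
from rodtrack.link import Track


def _track(points, track_id=0):
    """points: iterable of (frame, x, y, theta_axial)."""
    return Track(track_id, [Detection(f, x, y, th, 27.0, 3.0)
                            for f, x, y, th in points])


CAL = CameraCalibration(px_size=1.53, frame_rate=7.0)


class TestAxialDifference:
    def test_small_positive_step(self):
        assert axial_difference(0.1, 0.2) == pytest.approx(0.1)

    def test_wrap_across_pi(self):
        # 0.05 - (pi - 0.05) + pi = 0.1
        assert axial_difference(np.pi - 0.05, 0.05) == pytest.approx(0.1)

    def test_identity(self):
        for a in (0.0, 1.0, np.pi - 1e-6):
            assert axial_difference(a, a) == 0.0

    def test_boundary_maps_to_positive_half(self):
        assert axial_difference(0.0, np.pi / 2) == pytest.approx(np.pi / 2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_range_and_consistency(self, t1, t2):
        d = axial_difference(t1, t2)
        assert -np.pi / 2 < d <= np.pi / 2
        # adding the step to t1 lands on t2 modulo pi
        assert abs((t1 + d - t2) % np.pi) % np.pi < 1e-9 or \
            abs(((t1 + d - t2) % np.pi) - np.pi) < 1e-9


class TestComputeKinematics:
    def test_unit_pixel_step_calibration(self):
        """1 px/frame at 1.53 um/px and 7 fps is 10.71 um/s."""
        track = _track([(0, 10, 20, 0.0), (1, 11, 20, 0.0)])
        (s,) = compute_kinematics(track, CAL)
        assert s.v == pytest.approx(1.53 * 7.0)
        assert s.omega == 0.0
        assert s.t == pytest.approx(1 / 7.0)

    def test_stationary_track(self):
        track = _track([(f, 30, 40, 0.7) for f in range(5)])
        samples = compute_kinematics(track, CAL)
        assert len(samples) == 4
        assert all(s.v == 0 and s.omega == 0 for s in samples)

    def test_constant_axial_rotation(self):
        """0.1 rad/frame at 7 fps gives omega = 0.7 rad/s at every step."""
        track = _track([(f, 50, 50, (0.1 * f) % np.pi) for f in range(10)])
        samples = compute_kinematics(track, CAL)
        assert all(s.omega == pytest.approx(0.7) for s in samples)

    def test_theta_unwraps_monotonically(self):
        track = _track([(f, 50, 50, (0.2 * f) % np.pi) for f in range(25)])
        thetas = [s.theta for s in compute_kinematics(track, CAL)]
        assert np.all(np.diff(thetas) > 0)

    def test_gap_divides_velocity(self):
        track = _track([(0, 0, 0, 0.0), (2, 4, 0, 0.0)])
        (s,) = compute_kinematics(track, CAL)
        assert s.gap == 2
        assert s.v == pytest.approx(2.0 * 1.53 * 7.0)  # 4 px over 2 frames

    def test_calibration_linearity(self):
        track = _track([(f, 10 + 2 * f, 20, (0.05 * f) % np.pi)
                        for f in range(8)])
        base = compute_kinematics(track, CAL)
        px2 = compute_kinematics(
            track, CameraCalibration(px_size=2 * 1.53, frame_rate=7.0))
        fps2 = compute_kinematics(
            track, CameraCalibration(px_size=1.53, frame_rate=14.0))
        for b, p, f in zip(base, px2, fps2):
            assert p.v == pytest.approx(2 * b.v)
            assert p.omega == pytest.approx(b.omega)
            assert f.v == pytest.approx(2 * b.v)
            assert f.omega == pytest.approx(2 * b.omega)

    def test_time_base(self):
        track = _track([(f, 10 + f, 20, 0.0) for f in (3, 4, 5, 7)])
        for s in compute_kinematics(track, CAL):
            assert s.t == pytest.approx(s.frame_index / 7.0)

    def test_head_aligned_with_motion(self):
        # motor moving in -x: axial angle 0 should be flipped to pi
        track = _track([(f, 100 - 3 * f, 50, 0.0) for f in range(5)])
        samples = compute_kinematics(track, CAL)
        assert samples[0].theta == pytest.approx(np.pi)

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_kinematics(_track([(0, 1, 1, 0.0)]), CAL)


class TestSummarize:
    def test_constant_speed_track(self):
        track = _track([(f, 10.0 + f, 20, 0.0) for f in range(6)])
        samples = compute_kinematics(track, CAL)
        summaries, hists = summarize([samples])
        s = summaries[0]
        assert s.mean_v == pytest.approx(1.53 * 7.0)
        assert s.sd_v == pytest.approx(0.0, abs=1e-9)
        assert s.n_samples == len(track) - 1

    def test_pooled_mean_of_two_tracks(self):
        t1 = _track([(f, 10 + 1 * f, 20, 0.0) for f in range(6)], 0)
        t2 = _track([(f, 10 + 3 * f, 60, 0.0) for f in range(6)], 1)
        s1 = compute_kinematics(t1, CAL)
        s2 = compute_kinematics(t2, CAL)
        summaries, hists = summarize([s1, s2])
        pooled = [v for s in (s1, s2) for v in [x.v for x in s]]
        assert np.mean(pooled) == pytest.approx(2.0 * 1.53 * 7.0)

    def test_histogram_conserves_samples(self):
        tracks = [_track([(f, 10 + k * f, 20 + 30 * k, 0.0)
                          for f in range(6)], k) for k in range(1, 4)]
        samples = [compute_kinematics(t, CAL) for t in tracks]
        _, hists = summarize(samples)
        counts, _ = hists["v_pooled"]
        assert counts.sum() == sum(len(s) for s in samples)
        counts_m, _ = hists["v_track_means"]
        assert counts_m.sum() == len(tracks)

    def test_path_length_and_duration(self):
        track = _track([(f, 10.0 + 2 * f, 20, 0.0) for f in range(8)])
        summaries, _ = summarize([compute_kinematics(track, CAL)])
        s = summaries[0]
        assert s.path_length == pytest.approx(7 * 2 * 1.53)
        assert s.duration == pytest.approx(7 / 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
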