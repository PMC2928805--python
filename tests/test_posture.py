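"""Posture pipeline: segmentation, midline, 13 points, first angle, head ID."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from nemaphene import posture
from nemaphene.errors import (AnalysisWindowError, CoiledWormError,
                              SegmentationError, ValidationError)
from nemaphene.posture import (PostureConfig, PosturePoints, assign_body_points,
                               assign_head, extract_midline,
                               first_supplementary_angle,
                               max_extension_first_angle, segment_worm)
from nemaphene.synthetic import WormSpec, random_midline, render_movie


def _dense_arc_positions(polyline, query_points, n_dense=100_000):
    """Arc-length positions of query points on a densely resampled polyline."""
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0, cum[-1], n_dense)
    dense = np.stack([np.interp(s, cum, polyline[:, 0]),
                      np.interp(s, cum, polyline[:, 1])], axis=1)
    from scipy.spatial import cKDTree
    _, idx = cKDTree(dense).query(query_points)
    return s[idx]


class TestSegmentation:
    def test_uniform_frame_fails(self):
        with pytest.raises(SegmentationError, match="uniform"):
            segment_worm(np.full((64, 64), 100.0))

    def test_noiseless_roundtrip_equals_renderer_mask(self, bent_movie):
        spec, mv = bent_movie
        m = segment_worm(mv.frames[0])
        assert np.array_equal(m.mask, mv.masks[0])

    def test_noisy_mask_area_within_5pct_of_analytic(self, noisy_movie):
        spec, mv = noisy_movie
        m = segment_worm(mv.frames[0])
        assert m.area * spec.pixel_size ** 2 == \
            pytest.approx(mv.truth["body_area_um2"], rel=0.05)

    def test_dark_worm_polarity_autodetect(self, bent_movie):
        spec, mv = bent_movie
        inverted = 600.0 - mv.frames[0].astype(float)
        m = segment_worm(inverted)
        assert np.array_equal(m.mask, mv.masks[0])


class TestMidline:
    def test_straight_rectangle(self):
        mask = np.zeros((40, 140), dtype=bool)
        mask[15:25, 10:130] = True
        mid = extract_midline(posture.BinaryMask(mask, 0.5, int(mask.sum())))
        assert mid.arc_length == pytest.approx(120.0, abs=5.0)
        assert np.abs(mid.points[:, 1] - 19.5).max() < 1.5

    def test_rendered_worm_rms_below_1px(self, bent_movie):
        from scipy.spatial import cKDTree
        from nemaphene.synthetic.worm import make_centerline
        spec, mv = bent_movie
        m = segment_worm(mv.frames[0])
        mid = extract_midline(m, image=mv.frames[0])
        analytic = (make_centerline(spec, 0.0) - mv.origin) / spec.pixel_size
        d, _ = cKDTree(analytic).query(mid.points)
        assert np.sqrt((d ** 2).mean()) < 1.0

    def test_coiled_worm_rejected(self):
        # annulus: the skeleton is a closed loop with no endpoints
        yy, xx = np.mgrid[:80, :80]
        r = np.hypot(yy - 40, xx - 40)
        mask = (r > 20) & (r < 32)
        with pytest.raises(CoiledWormError, match="coiled"):
            extract_midline(posture.BinaryMask(mask, 0.5, int(mask.sum())))

    def test_expected_length_bounds_enforced(self, bent_movie):
        spec, mv = bent_movie
        m = segment_worm(mv.frames[0])
        cfg = PostureConfig(expected_length_px=500.0)
        with pytest.raises(SegmentationError, match="arc length"):
            extract_midline(m, cfg, image=mv.frames[0])


class TestBodyPoints:
    def test_straight_midline_equal_spacing(self):
        pts = np.stack([np.linspace(0, 120, 300), np.zeros(300)], axis=1)
        mid = posture.Midline(pts, 120.0)
        bp = assign_body_points(mid, 13)
        assert bp.points[:, 0] == pytest.approx(np.arange(13) * 10.0, abs=1e-9)

    def test_default_is_13_points(self):
        pts = np.stack([np.linspace(0, 100, 200), np.zeros(200)], axis=1)
        bp = assign_body_points(posture.Midline(pts, 100.0))
        assert len(bp.points) == 13

    def test_too_few_points_rejected(self):
        pts = np.stack([np.linspace(0, 100, 200), np.zeros(200)], axis=1)
        with pytest.raises(ValidationError, match="n"):
            assign_body_points(posture.Midline(pts, 100.0), n=2)

    @pytest.mark.parametrize("seed", range(8))
    def test_equidistance_vs_dense_arc_oracle(self, seed):
        rng = np.random.default_rng(seed)
        poly = random_midline(rng)
        arc = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
        bp = assign_body_points(posture.Midline(poly, arc), 13)
        s = _dense_arc_positions(poly, bp.points)
        spacings = np.diff(s)
        assert np.abs(spacings - arc / 12).max() / (arc / 12) < 0.02


class TestFirstAngle:
    def test_collinear_zero(self):
        bp = PosturePoints(np.array([[0, 0], [10, 0], [20, 0]], float), 10.0)
        assert first_supplementary_angle(bp) == pytest.approx(0.0, abs=1e-12)

    def test_right_diagonal_45(self):
        bp = PosturePoints(np.array([[0, 0], [10, 0], [20, 10]], float), 10.0)
        assert first_supplementary_angle(bp) == pytest.approx(45.0, abs=1e-9)

    def test_coincident_points_rejected(self):
        bp = PosturePoints(np.array([[0, 0], [0, 0], [20, 10]], float), 10.0)
        with pytest.raises(ValidationError, match="coincident"):
            first_supplementary_angle(bp)

    def test_signed_angle_magnitude_matches(self):
        bp = PosturePoints(np.array([[0, 0], [10, 0], [20, -10]], float), 10.0)
        assert first_supplementary_angle(bp, signed=True) == pytest.approx(-45.0)
        assert first_supplementary_angle(bp) == pytest.approx(45.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hst.floats(-300, 300), hst.floats(-300, 300),
           hst.floats(0, 2 * np.pi), hst.floats(0.1, 10.0))
    def test_rigid_motion_and_scale_invariance(self, tx, ty, rot, scale):
        pts = np.array([[0, 0], [10, 2], [18, 9]], float)
        base = first_supplementary_angle(PosturePoints(pts, 10.0))
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        moved = scale * pts @ R.T + np.array([tx, ty])
        assert first_supplementary_angle(PosturePoints(moved, 10.0)) == \
            pytest.approx(base, abs=0.5)

    def test_frame_rotation_invariance_end_to_end(self, bent_movie):
        spec, mv = bent_movie
        W = mv.frames[0].shape[1]
        nose = np.array(mv.truth["per_frame"][0]["points13_px"][0])

        def measure(frame, nose_xy):
            m = segment_worm(frame)
            mid = extract_midline(m, image=frame)
            if np.linalg.norm(mid.points[0] - nose_xy) > \
                    np.linalg.norm(mid.points[-1] - nose_xy):
                mid = mid.flipped()
            return first_supplementary_angle(assign_body_points(mid))

        a = measure(mv.frames[0], nose)
        # rot90 maps (x, y) -> (y, W-1-x)
        b = measure(np.rot90(mv.frames[0]), np.array([nose[1], W - 1 - nose[0]]))
        assert a == pytest.approx(b, abs=0.5)


class TestHeadAssignment:
    def test_forward_worm_nose_leads(self, bent_movie):
        spec, mv = bent_movie
        res = posture.analyze_movie(mv.frames, spec.frame_interval,
                                    window=(0.0, 1e9))
        nose_truth = np.array(mv.truth["per_frame"][0]["points13_px"][0])
        nose = res.midlines[0].points[0]
        assert np.linalg.norm(nose - nose_truth) < 5.0
        assert res.midlines[0].head_confidence == "motion"

    def test_reversed_frames_swap_labels(self, bent_movie):
        spec, mv = bent_movie
        fwd = posture.analyze_movie(mv.frames, spec.frame_interval,
                                    window=(0.0, 1e9))
        rev = posture.analyze_movie(mv.frames[::-1], spec.frame_interval,
                                    window=(0.0, 1e9))
        assert np.linalg.norm(fwd.midlines[0].points[0]
                              - rev.midlines[-1].points[-1]) < 5.0

    def test_stationary_worm_unassigned_then_override(self):
        spec = WormSpec(speed=0.0, n_frames=3, noise_sd=0.0)
        mv = render_movie(spec)
        res = posture.analyze_movie(mv.frames, spec.frame_interval,
                                    window=(0.0, 1e9))
        assert res.midlines[0].head_confidence == "unassigned"
        res2 = posture.analyze_movie(mv.frames, spec.frame_interval,
                                     window=(0.0, 1e9), head_override="first")
        assert res2.midlines[0].head_confidence == "user"


class TestMaxExtension:
    @staticmethod
    def _series(angles, dt=0.5):
        return pd.DataFrame({
            "frame": np.arange(len(angles)),
            "time_s": np.arange(len(angles)) * dt,
            "angle_deg": angles,
            "ok": [not np.isnan(a) for a in angles],
            "failure_reason": [None] * len(angles)}).set_index("frame")

    def test_constant_series(self):
        res = max_extension_first_angle(self._series([20.0, 20.0, 20.0]),
                                        window=(0.0, 10.0))
        assert res.angle == 20.0

    def test_argmax_with_frame_index(self):
        res = max_extension_first_angle(self._series([10.0, 25.0, 40.0, 33.0]),
                                        window=(0.0, 10.0))
        assert res.angle == 40.0 and res.frame_index == 2

    def test_window_is_respected(self):
        res = max_extension_first_angle(self._series([90.0, 5.0, 7.0, 6.0]),
                                        window=(0.4, 10.0))
        assert res.angle == 7.0

    def test_empty_window_raises(self):
        with pytest.raises(AnalysisWindowError, match="window"):
            max_extension_first_angle(self._series([10.0, 20.0]), window=(50.0, 60.0))


class TestRecovery:
    @pytest.mark.parametrize("theta", [10.0, 30.0, 60.0])
    def test_head_bend_recovered_within_2deg_noiseless(self, theta):
        spec = WormSpec(head_bend_angle=theta, n_frames=3, noise_sd=0.0,
                        speed=100.0, seed=0)
        mv = render_movie(spec)
        res = posture.analyze_movie(mv.frames, spec.frame_interval,
                                    window=(0.0, 1e9))
        med = res.result.series.loc[res.result.series["ok"], "angle_deg"].median()
        assert med == pytest.approx(theta, abs=3.0)

    def test_oscillating_head_bend_peak_recovered(self):
        # head swings sinusoidally; the windowed max should hit the peak
        spec = WormSpec(head_bend_angle=35.0, head_bend_frequency=0.25,
                        head_bend_phase=0.0, n_frames=9, noise_sd=0.0,
                        speed=60.0, seed=0)
        mv = render_movie(spec)
        truth_peak = max(f["first_angle_deg"] for f in mv.truth["per_frame"])
        res = posture.analyze_movie(mv.frames, spec.frame_interval,
                                    window=(0.0, 1e9))
        assert res.result.angle == pytest.approx(truth_peak, abs=2.0)

    def test_corrupt_frame_skipped_not_fatal(self, bent_movie):
        spec, mv = bent_movie
        frames = mv.frames.copy()
        frames[1] = 100
        res = posture.analyze_movie(frames, spec.frame_interval, window=(0.0, 1e9))
        assert not res.result.series["ok"].iloc[1]
        assert res.result.series["ok"].sum() == len(frames) - 1
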