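"""Generator contracts: analytic ground truth, conservation laws, determinism."""

import numpy as np
import pytest

from nemaphene import posture
from nemaphene.errors import FieldOfViewError, ValidationError
from nemaphene.synthetic import (PunctaSpec, TraceSpec, WormSpec,
                                 analytic_half_decay, analytic_posture_points,
                                 kernel_peak_time, make_centerline, make_trace,
                                 render_movie, render_puncta)


class TestCenterline:
    def test_degenerate_spec_is_straight(self):
        spec = WormSpec(head_bend_angle=0.0, undulation_amplitude=0.0, n_frames=1)
        pts = make_centerline(spec)
        d = pts[-1] - pts[0]
        assert np.linalg.norm(d) == pytest.approx(spec.body_length, rel=1e-9)
        # all points collinear
        t = d / np.linalg.norm(d)
        off = (pts - pts[0]) @ np.array([-t[1], t[0]])
        assert np.abs(off).max() < 1e-9

    @pytest.mark.parametrize("theta", [10.0, 30.0, 60.0])
    def test_first_angle_of_analytic_points_matches_spec(self, theta):
        spec = WormSpec(head_bend_angle=theta, undulation_amplitude=0.0, n_frames=1)
        p13 = analytic_posture_points(spec)
        ang = posture.first_supplementary_angle(posture.PosturePoints(p13, 0.0))
        assert ang == pytest.approx(theta, abs=0.5)

    @pytest.mark.parametrize("t", [0.0, 0.5, 7.25])
    def test_arc_length_conserved(self, t):
        spec = WormSpec(body_length=1000.0, head_bend_angle=40.0, n_frames=20)
        pts = make_centerline(spec, t)
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arc == pytest.approx(1000.0, abs=1.0)

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValidationError, match="body_length"):
            WormSpec(body_length=-5)
        with pytest.raises(ValidationError, match="undulation_amplitude"):
            WormSpec(undulation_amplitude=95)
        with pytest.raises(ValidationError, match="n_frames"):
            WormSpec(n_frames=0)


class TestRenderMovie:
    def test_stationary_worm_centroid_fixed(self):
        spec = WormSpec(speed=0.0, n_frames=4, noise_sd=0.0)
        mv = render_movie(spec)
        cents = np.array([np.argwhere(m).mean(axis=0) for m in mv.masks])
        assert np.abs(cents - cents.mean(axis=0)).max() < 0.5

    def test_ground_truth_displacement_unit_conversion(self):
        spec = WormSpec(speed=100.0, frame_interval=0.5, pixel_size=5.0,
                        n_frames=3, noise_sd=0.0)
        mv = render_movie(spec)
        assert mv.truth["displacement_px_per_frame"] == pytest.approx(10.0)
        pf = mv.truth["per_frame"]
        d = np.diff([f["centroid_px"] for f in pf], axis=0)
        assert np.linalg.norm(d, axis=1) == pytest.approx(10.0, abs=1e-9)

    def test_mask_area_matches_analytic_body_area(self, bent_movie):
        spec, mv = bent_movie
        area_px = mv.masks[0].sum() * spec.pixel_size ** 2
        assert area_px == pytest.approx(mv.truth["body_area_um2"], rel=0.03)

    def test_fixed_canvas_too_small_raises(self):
        spec = WormSpec(n_frames=2, canvas_shape=(20, 20))
        with pytest.raises(FieldOfViewError, match="larger canvas"):
            render_movie(spec)

    def test_seed_determinism_bit_identical(self):
        spec = WormSpec(n_frames=2, noise_sd=8.0, seed=7)
        a, b = render_movie(spec), render_movie(spec)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.masks, b.masks)


class TestRenderPuncta:
    def test_empty_spec_is_background(self):
        res = render_puncta(PunctaSpec(n_puncta=0, noise_sd=3.0, seed=0))
        assert res.image.mean() == pytest.approx(100.0, abs=3.0)

    def test_single_punctum_peak_closed_form(self):
        res = render_puncta(PunctaSpec(n_puncta=1, peak_heights=[150.0],
                                       background_level=100.0, noise_sd=0.0))
        assert res.image.max() == pytest.approx(250.0, abs=1e-6)

    def test_overlapping_puncta_rejected(self):
        with pytest.raises(ValidationError, match="spacing"):
            PunctaSpec(n_puncta=3, spacing=6.0, psf_sigma=2.0)

    def test_truth_lists_centers_and_heights(self):
        spec = PunctaSpec(n_puncta=4, peak_heights=[50, 100, 150, 200])
        res = render_puncta(spec)
        assert np.asarray(res.truth["centers_px"]).shape == (4, 2)
        assert list(res.truth["net_heights"]) == [50, 100, 150, 200]

    def test_seed_determinism(self):
        spec = PunctaSpec(seed=3)
        assert np.array_equal(render_puncta(spec).image, render_puncta(spec).image)


class TestMakeTrace:
    def test_monoexponential_closed_forms(self):
        spec = TraceSpec(tau_rise=0.0, tau_decay=5.0, amplitude=2.0, noise_sd=0.0)
        trace, truth = make_trace(spec)
        assert truth["charge_pC"] == pytest.approx(10.0)          # A*tau
        assert truth["half_decay_ms"] == pytest.approx(5 * np.log(2), abs=1e-9)
        # baseline before onset, peak deviation = amplitude at onset
        pre = trace.current_na[trace.time_ms < spec.onset]
        assert np.allclose(pre, spec.baseline_current)
        assert np.abs(trace.current_na - spec.baseline_current).max() == \
            pytest.approx(2.0, abs=1e-9)

    def test_difference_of_exponentials_peak_time(self):
        # root of the kernel derivative: ln(taud/taur) * taud*taur/(taud-taur)
        assert kernel_peak_time(1.0, 5.0) == pytest.approx(
            np.log(5.0) * 5.0 / 4.0, abs=1e-12)
        spec = TraceSpec(tau_rise=1.0, tau_decay=5.0, amplitude=2.0, noise_sd=0.0)
        trace, truth = make_trace(spec)
        assert truth["peak_time_ms"] == pytest.approx(spec.onset + 2.0118, abs=1e-3)
        # rescaled kernel peaks at the amplitude
        dev = np.abs(trace.current_na - spec.baseline_current)
        assert dev.max() == pytest.approx(2.0, abs=2e-3)

    def test_half_decay_consistent_with_numeric_kernel(self):
        # independent dense-grid oracle for the difference of exponentials
        tr, td = 1.0, 5.0
        t = np.linspace(0, 100, 2_000_001)
        k = np.exp(-t / td) - np.exp(-t / tr)
        ip = np.argmax(k)
        below = np.where(k[ip:] <= 0.5 * k[ip])[0][0]
        oracle = t[ip + below] - t[ip]
        assert analytic_half_decay(tr, td) == pytest.approx(oracle, abs=1e-4)

    def test_polarity_and_sign(self):
        ti, _ = make_trace(TraceSpec(polarity="inward", noise_sd=0.0))
        to, _ = make_trace(TraceSpec(polarity="outward", noise_sd=0.0))
        assert ti.current_na.min() < ti.current_na[0]
        assert to.current_na.max() > to.current_na[0]

    def test_short_duration_warns_in_truth(self):
        _, truth = make_trace(TraceSpec(tau_rise=0.0, tau_decay=40.0,
                                        duration=50.0, onset=20.0, noise_sd=0.0))
        assert any("decay" in w for w in truth.warnings)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValidationError, match="tau_decay"):
            TraceSpec(tau_rise=5.0, tau_decay=5.0)

    def test_seed_determinism(self):
        a, _ = make_trace(TraceSpec(seed=11))
        b, _ = make_trace(TraceSpec(seed=11))
        assert np.array_equal(a.current_na, b.current_na)
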