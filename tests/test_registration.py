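import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from ehtkit import (SyntheticVideoSpec, brute_force_shift, generate_pillar_video,
                    poc_shift, track_stack)


def textured_frame(seed, shape=(96, 96)):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.normal(size=shape), 1.5, mode="wrap")
    return (img - img.min()) / np.ptp(img)


def fourier_shifted(frame, dy, dx):
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(frame),
                                                      (dy, dx))))


class TestPocShift:
    def test_identity_gives_zero_shift_and_unit_peak(self):
        f = textured_frame(0)
        est = poc_shift(f, f)
        assert abs(est.dy) < 1e-9 and abs(est.dx) < 1e-9
        assert est.peak_value == pytest.approx(1.0, abs=1e-6)
        assert not est.low_confidence

    def test_integer_circular_shift_recovered_exactly(self):
        f = textured_frame(1)
        moved = np.roll(f, (3, -2), axis=(0, 1))
        # a circular shift keeps the phase relation exact, so unwindowed
        # POC recovers it to machine precision
        est = poc_shift(f, moved, apodize=False)
        assert est.dy == pytest.approx(3.0, abs=1e-6)
        assert est.dx == pytest.approx(-2.0, abs=1e-6)
        # the default (Hann-windowed) estimator stays within subpixel noise
        est_w = poc_shift(f, moved)
        assert est_w.dy == pytest.approx(3.0, abs=0.01)
        assert est_w.dx == pytest.approx(-2.0, abs=0.01)

    def test_brightness_scaling_leaves_estimate_unchanged(self):
        f = textured_frame(2)
        moved = fourier_shifted(f, 1.3, -2.7)
        base = poc_shift(f, moved)
        for gain in (0.5, 1.8, 3.0):
            scaled = poc_shift(f, gain * moved)
            assert abs(scaled.dy - base.dy) < 1e-6
            assert abs(scaled.dx - base.dx) < 1e-6

    def test_antisymmetry(self):
        f = textured_frame(3)
        moved = fourier_shifted(f, -2.4, 3.1)
        fwd = poc_shift(f, moved)
        rev = poc_shift(moved, f)
        assert fwd.dy == pytest.approx(-rev.dy, abs=0.02)
        assert fwd.dx == pytest.approx(-rev.dx, abs=0.02)

    def test_subpixel_accuracy_noiseless(self):
        rng = np.random.default_rng(42)
        for i in range(10):
            f = textured_frame(100 + i)
            dy, dx = rng.uniform(-5, 5, 2)
            est = poc_shift(f, fourier_shifted(f, dy, dx))
            assert abs(est.dy - dy) < 0.05
            assert abs(est.dx - dx) < 0.05

    def test_constant_frame_rejected(self):
        flat = np.ones((64, 64))
        with pytest.raises(ValueError, match="ill-posed"):
            poc_shift(flat, flat)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            poc_shift(np.zeros((64, 64)), np.zeros((64, 32)))


class TestBruteForceOracle:
    def test_identity(self):
        f = textured_frame(5)
        est = brute_force_shift(f, f, search_radius=4)
        assert abs(est.dy) < 1e-3 and abs(est.dx) < 1e-3

    def test_known_integer_circular_shift(self):
        f = textured_frame(6)
        est = brute_force_shift(f, np.roll(f, (2, -3), axis=(0, 1)),
                                search_radius=5)
        assert est.dy == pytest.approx(2.0, abs=0.02)
        assert est.dx == pytest.approx(-3.0, abs=0.02)

    def test_agreement_with_poc_on_random_shifts(self):
        rng = np.random.default_rng(7)
        for i in range(10):
            f = textured_frame(200 + i)
            dy, dx = rng.uniform(-4, 4, 2)
            moved = fourier_shifted(f, dy, dx)
            poc = poc_shift(f, moved)
            bf = brute_force_shift(f, moved, search_radius=6)
            assert abs(poc.dy - bf.dy) < 0.1
            assert abs(poc.dx - bf.dx) < 0.1

    def test_oversized_search_radius_rejected(self):
        f = textured_frame(8, shape=(32, 32))
        with pytest.raises(ValueError):
            brute_force_shift(f, f, search_radius=20)


class TestTrackStack:
    def test_static_stack_gives_zero_displacement(self, clean_video_spec):
        spec = dataclasses.replace(clean_video_spec, peak_force_n=0.0,
                                   n_frames=10, frame_shape=(96, 96))
        stack, _ = generate_pillar_video(spec)
        trace = track_stack(stack)
        assert np.allclose(trace.displacement_um, 0.0, atol=1e-6)

    def test_tracks_known_displacement_within_tolerance(self, clean_video_spec):
        stack, truth = generate_pillar_video(clean_video_spec)
        trace = track_stack(stack)
        err_px = np.max(np.abs(trace.displacement_um - truth.displacement_um)
                        ) / stack.pixel_scale_um
        assert err_px < 0.05
        assert trace.displacement_um[0] == 0.0

    def test_modes_agree_on_noiseless_rigid_motion(self, clean_video_spec):
        stack, _ = generate_pillar_video(clean_video_spec)
        cum = track_stack(stack, mode="frame_to_frame_cumulative")
        fixed = track_stack(stack, mode="fixed_reference")
        diff_px = np.max(np.abs(cum.displacement_um - fixed.displacement_um)
                         ) / stack.pixel_scale_um
        assert diff_px < 1e-2

    def test_axis_estimate_matches_prescribed_axis(self):
        spec = SyntheticVideoSpec(n_frames=100, peak_force_n=20e-6,
                                  noise_sd=0.0, texture_seed=3,
                                  displacement_axis=(0.6, 0.8))
        stack, truth = generate_pillar_video(spec)
        trace = track_stack(stack)
        assert abs(abs(np.dot(trace.axis, truth.axis)) - 1.0) < 1e-3
        # sign convention: contraction (the prescribed deflection) is positive
        assert trace.displacement_um.max() == pytest.approx(
            truth.displacement_um.max(), rel=0.02)

    def test_brightness_drift_does_not_break_tracking(self, clean_video_spec):
        spec = dataclasses.replace(clean_video_spec, brightness_drift=0.002)
        stack, truth = generate_pillar_video(spec)
        trace = track_stack(stack)
        err_px = np.max(np.abs(trace.displacement_um - truth.displacement_um)
                        ) / stack.pixel_scale_um
        assert err_px < 0.05
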