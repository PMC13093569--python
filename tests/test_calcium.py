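import dataclasses
import math

import numpy as np
import pytest

from ehtkit import (FluorescenceTrace, SyntheticTraceSpec, aggregate_roi,
                    analyze_trace, generate_calcium_trace, normalize_dff,
                    segment_beats, transient_features)

from conftest import make_beat_window


def uniform_trace(intensity, fs=100.0, **kw):
    n = len(intensity)
    return FluorescenceTrace(time_s=np.arange(n) / fs,
                             intensity=np.asarray(intensity, float), **kw)


class TestNormalizeDff:
    def test_constant_trace_normalizes_to_zero(self):
        out = normalize_dff(uniform_trace(np.full(1000, 42.0)))
        assert np.allclose(out.intensity, 0.0, atol=1e-12)

    def test_peak_over_baseline_gives_expected_dff(self):
        spec = SyntheticTraceSpec(baseline=100.0, amplitude=50.0, noise_sd=0.0,
                                  drift_slope=0.0)
        trace, _ = generate_calcium_trace(spec)
        out = normalize_dff(trace)
        # (150 - 100) / 100 = 0.5
        assert out.intensity.max() == pytest.approx(0.5, rel=0.01)

    def test_linear_drift_detrended_away(self):
        t = np.arange(1200) / 100.0
        out = normalize_dff(uniform_trace(100.0 + 2.0 * t))
        assert np.max(np.abs(out.intensity)) < 0.01

    def test_scale_invariance_of_dff(self):
        spec = SyntheticTraceSpec(noise_sd=0.0, drift_slope=0.0)
        trace, _ = generate_calcium_trace(spec)
        a = normalize_dff(trace).intensity
        scaled = uniform_trace(3.7 * trace.intensity)
        b = normalize_dff(scaled).intensity
        assert np.allclose(a, b, atol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            normalize_dff(uniform_trace(np.linspace(-10, -5, 500)))


class TestSegmentBeats:
    def test_twelve_second_trace_yields_complete_windows(self, clean_trace_spec):
        trace, _ = generate_calcium_trace(clean_trace_spec)
        windows = segment_beats(normalize_dff(trace))
        assert 10 <= len(windows) <= 11    # first/last partial discarded

    def test_flat_trace_yields_no_windows(self):
        with pytest.warns(UserWarning, match="no upstrokes"):
            windows = segment_beats(uniform_trace(np.full(2000, 7.0),
                                                  pacing_rate_hz=1.0))
        assert windows == []

    def test_half_hertz_pacing_gives_two_second_windows(self):
        spec = SyntheticTraceSpec(duration_s=20.0, pacing_rate_hz=0.5,
                                  noise_sd=0.0, decay_rate_per_s=8.0)
        trace, _ = generate_calcium_trace(spec)
        windows = segment_beats(normalize_dff(trace))
        assert windows
        span = windows[0].time_s[-1] - windows[0].time_s[0]
        assert span == pytest.approx(2.0, abs=0.05)


class TestTransientFeatures:
    def test_noiseless_features_match_construction(self):
        f = transient_features(make_beat_window(amplitude=1.0, rise_s=0.1,
                                                decay_rate=8.0))
        assert f.valid
        assert f.amplitude == pytest.approx(1.0, rel=0.01)
        assert f.time_to_peak_s == pytest.approx(0.1, abs=0.01)
        assert f.decay80_s == pytest.approx(math.log(5) / 8, abs=0.01)

    @pytest.mark.parametrize("lam", [2.0, 4.0, 8.0, 16.0])
    def test_decay80_closed_form_across_rates(self, lam):
        # pure exponential falling phase: decay80 = ln(5)/lambda, within
        # one sample interval (fs = 100 Hz)
        w = make_beat_window(decay_rate=lam, post_s=2.5)
        f = transient_features(w)
        assert f.valid
        assert abs(f.decay80_s - math.log(5) / lam) < 0.01
        # the secondary exponential-fit tau recovers 1/lambda
        assert f.tau_exp_s == pytest.approx(1.0 / lam, rel=0.05)

    def test_amplitude_scaling_leaves_decay80_unchanged(self):
        f1 = transient_features(make_beat_window(amplitude=1.0))
        f2 = transient_features(make_beat_window(amplitude=2.0))
        assert f2.amplitude == pytest.approx(2 * f1.amplitude, rel=0.01)
        assert f2.decay80_s == pytest.approx(f1.decay80_s, abs=0.002)
        assert f2.time_to_peak_s == pytest.approx(f1.time_to_peak_s, abs=0.002)

    def test_never_decaying_beat_flagged_invalid(self):
        w = make_beat_window(decay_rate=0.3, post_s=0.8)   # 20% level unreachable
        f = transient_features(w)
        assert not f.valid
        assert math.isnan(f.decay80_s)

    def test_garbage_window_flagged_invalid(self):
        rng = np.random.default_rng(0)
        from ehtkit.calcium import BeatWindow
        w = BeatWindow(time_s=np.arange(100) / 100.0,
                       signal=rng.normal(0, 1e-4, 100), beat_index=0)
        assert not transient_features(w).valid


class TestAggregateRoi:
    def test_identical_beats_average_to_single_beat(self):
        feats = [transient_features(make_beat_window()) for _ in range(10)]
        s = aggregate_roi(feats, target_n=10)
        assert s.n_beats == 10
        assert s.amplitude == pytest.approx(feats[0].amplitude)
        assert s.decay80_s == pytest.approx(feats[0].decay80_s)

    def test_partial_validity_recorded(self):
        good = [transient_features(make_beat_window(seed=i)) for i in range(7)]
        bad = [transient_features(make_beat_window(decay_rate=0.3, post_s=0.8))
               for _ in range(3)]
        s = aggregate_roi(good + bad, target_n=10)
        assert s.n_beats == 7
        assert any("invalid" in w for w in s.warnings)

    def test_zero_valid_beats_gives_empty_summary(self):
        bad = [transient_features(make_beat_window(decay_rate=0.3, post_s=0.8))]
        s = aggregate_roi(bad)
        assert s.n_beats == 0 and math.isnan(s.amplitude)

    def test_averaging_shrinks_sd_like_sqrt_n(self):
        # per-beat noise averages down ~1/sqrt(10) across simulated ROIs
        rng = np.random.default_rng(1)
        singles, tens = [], []
        for r in range(200):
            feats = [transient_features(
                make_beat_window(noise_sd=0.05, seed=int(rng.integers(2**31))))
                for _ in range(10)]
            amps = [f.amplitude for f in feats if f.valid]
            if len(amps) == 10:
                singles.append(amps[0])
                tens.append(np.mean(amps))
        ratio = np.std(tens) / np.std(singles)
        assert ratio == pytest.approx(1 / math.sqrt(10), rel=0.35)


class TestAnalyzeTrace:
    def test_full_pipeline_recovers_ground_truth(self, clean_trace_spec):
        trace, truth = generate_calcium_trace(clean_trace_spec)
        table, summary = analyze_trace(trace)
        gt = truth.beats.iloc[0]
        assert summary.n_beats == 10
        assert summary.amplitude == pytest.approx(gt["amplitude_dff"], rel=0.01)
        assert summary.time_to_peak_s == pytest.approx(gt["time_to_peak_s"],
                                                       abs=0.01)
        assert summary.decay80_s == pytest.approx(gt["decay80_s"], abs=0.01)
        assert table["valid"].all()

    def test_noisy_recovery_with_averaging(self):
        spec = SyntheticTraceSpec(noise_sd=2.5, drift_slope=0.5, seed=9)
        trace, truth = generate_calcium_trace(spec)
        _, summary = analyze_trace(trace)
        gt = truth.beats.iloc[0]
        assert summary.amplitude == pytest.approx(gt["amplitude_dff"], rel=0.1)
        assert summary.decay80_s == pytest.approx(gt["decay80_s"], rel=0.1)
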