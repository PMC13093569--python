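import numpy as np
import pytest

from ehtkit import PillarGeometry, SyntheticTraceSpec, SyntheticVideoSpec


@pytest.fixture
def geometry():
    """Fabricated pillar: L=12 mm, E=1.7 MPa, d=1.2 mm."""
    return PillarGeometry()


@pytest.fixture
def clean_video_spec():
    """Short noiseless 1 Hz-paced video, 25 μN beats."""
    return SyntheticVideoSpec(n_frames=100, frame_rate_hz=50.0,
                              peak_force_n=25e-6, noise_sd=0.0, texture_seed=7)


@pytest.fixture
def clean_trace_spec():
    """Noiseless 12 s paced trace (ΔF/F₀ amplitude 0.5, λ = 8/s)."""
    return SyntheticTraceSpec(noise_sd=0.0, drift_slope=0.0)


def make_beat_window(amplitude=1.0, rise_s=0.1, decay_rate=8.0, fs=100.0,
                     pre_s=0.3, post_s=1.2, baseline=0.0, noise_sd=0.0,
                     seed=0):
    """Standalone single-transient window in ΔF/F₀ units.

    Quarter-sine rise to ``baseline + amplitude`` followed by a pure
    exponential decay — the closed-form reference for decay80 = ln(5)/λ.
    """
    from ehtkit.calcium import BeatWindow

    t = np.arange(int(round((pre_s + post_s) * fs))) / fs
    s = t - pre_s
    x = np.full_like(t, baseline)
    rise = (s >= 0) & (s < rise_s)
    x[rise] += amplitude * np.sin(np.pi * s[rise] / (2 * rise_s))
    dec = s >= rise_s
    x[dec] += amplitude * np.exp(-decay_rate * (s[dec] - rise_s))
    if noise_sd:
        x += np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return BeatWindow(time_s=t, signal=x, beat_index=0)
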