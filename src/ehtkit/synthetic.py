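"""Synthetic recordings with known ground truth.

Two generators emulate the two kinds of raw data the pipeline consumes:

* pillar-deflection videos — a textured pillar head rigidly translated
  along one axis by the deflection that a prescribed force waveform
  produces through the cantilever model (1 Hz paced beats, 3.79 μm/px),
  with additive Gaussian noise and multiplicative brightness drift;
* paced fluorescence traces — per-beat Ca²⁺ transients (quarter-sine
  rise to ``baseline + amplitude``, then single-exponential decay) on a
  linearly drifting baseline with Gaussian noise.

Every recording is returned together with its exact ground truth
(displacements in μm, or a per-beat feature table), which is what makes
each downstream stage testable without any real recording.

Translations are rendered by Fourier-domain (band-limited) resampling,
never integer pixel shifts, because the tracker under test claims
subpixel accuracy.  The rise shape is a quarter sine — zero slope at the
peak but a finite slope at onset — so the upstroke onset remains
identifiable from the trace alone; the decay is the single exponential
whose 80%-reduction time is ln(5)/decay_rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import PillarGeometry
from .io import VideoStack

__all__ = [
    "SyntheticVideoSpec",
    "SyntheticTraceSpec",
    "VideoGroundTruth",
    "TraceGroundTruth",
    "Cohort",
    "CohortMember",
    "generate_pillar_video",
    "generate_calcium_trace",
    "generate_cohort",
]

#: fraction of the next stimulus' amplitude still present at which the
#: generator records a transient-overlap warning
OVERLAP_TOLERANCE = 0.05


@dataclass
class SyntheticVideoSpec:
    """Parameters of one synthetic pillar-deflection video.

    ``peak_force_n`` is the per-beat peak force in newtons (scalar, or a
    sequence with one entry per beat); the beat waveform is a raised-
    cosine pulse of ``beat_duration_s`` within each pacing period.
    """

    frame_shape: tuple[int, int] = (192, 192)
    n_frames: int = 200
    frame_rate_hz: float = 50.0
    pixel_scale_um: float = 3.79
    pacing_rate_hz: float = 1.0
    peak_force_n: float | np.ndarray = 30e-6
    geometry: PillarGeometry = field(default_factory=PillarGeometry)
    texture_seed: int = 0
    noise_sd: float = 0.02
    brightness_drift: float = 0.0
    displacement_axis: tuple[float, float] = (0.0, 1.0)
    beat_duration_s: float = 0.4

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_rate_hz <= 2 * self.pacing_rate_hz:
            raise ValueError("frame_rate_hz must exceed 2x the pacing rate")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")
        if np.any(np.asarray(self.peak_force_n) < 0):
            raise ValueError("peak_force_n must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.beat_duration_s <= 1.0 / self.pacing_rate_hz):
            raise ValueError("beat_duration_s must fit within one pacing period")
        ax = np.asarray(self.displacement_axis, float)
        n = math.hypot(*ax)
        if ax.shape != (2,) or n == 0:
            raise ValueError("displacement_axis must be a non-zero 2-vector")
        self.displacement_axis = tuple(ax / n)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class SyntheticTraceSpec:
    """Parameters of one synthetic paced fluorescence trace.

    ``decay_rate_per_s`` is the exponential rate λ of the falling phase,
    so the ground-truth 80%-decay time is ln(5)/λ.  Intensities are in
    arbitrary camera units; the implied ΔF/F₀ amplitude is
    ``amplitude / baseline``.
    """

    duration_s: float = 12.0
    sample_rate_hz: float = 100.0
    pacing_rate_hz: float = 1.0
    baseline: float = 100.0
    amplitude: float = 50.0
    rise_time_s: float = 0.15
    decay_rate_per_s: float = 8.0
    noise_sd: float = 0.0
    drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rise_time_s >= 1.0 / self.pacing_rate_hz:
            raise ValueError("rise_time_s must be shorter than the pacing period")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sample_rate_hz < 20 * self.pacing_rate_hz:
            raise ValueError("sample_rate_hz must be >= 20x the pacing rate")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.decay_rate_per_s <= 0:
            raise ValueError("decay_rate_per_s must be positive")


@dataclass
class VideoGroundTruth:
    """Exact per-frame truth stored alongside a generated video."""

    time_s: np.ndarray
    force_n: np.ndarray
    displacement_um: np.ndarray
    shift_px: np.ndarray            # (n, 2) applied (dy, dx)
    axis: np.ndarray
    n_beats: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s, "force_n": self.force_n,
            "displacement_um": self.displacement_um,
            "dy_px": self.shift_px[:, 0], "dx_px": self.shift_px[:, 1],
        })


@dataclass
class TraceGroundTruth:
    """Per-beat truth stored alongside a generated fluorescence trace."""

    beats: pd.DataFrame             # beat, amplitude, amplitude_dff, time_to_peak_s, decay80_s
    warnings: list[str] = field(default_factory=list)

    @property
    def n_beats(self) -> int:
        return len(self.beats)


def _beat_force_waveform(t: np.ndarray, spec: SyntheticVideoSpec,
                         peaks: np.ndarray) -> np.ndarray:
    """Sum of raised-cosine force pulses, one per pacing period."""
    force = np.zeros_like(t)
    period = 1.0 / spec.pacing_rate_hz
    w = spec.beat_duration_s
    for k, pk in enumerate(peaks):
        s = t - k * period
        m = (s >= 0) & (s < w)
        force[m] += pk * 0.5 * (1.0 - np.cos(2.0 * np.pi * s[m] / w))
    return force


def generate_pillar_video(spec: SyntheticVideoSpec):
    """Render a pillar-deflection video and its exact ground truth.

    The pillar head is a high-contrast textured disk on a darker
    background (texture from a seeded, band-limited Gaussian random
    field, guaranteeing a well-conditioned phase spectrum).  Each frame
    is the base image translated by the ground-truth shift via Fourier
    resampling, then scaled by the per-frame brightness-drift factor and
    degraded with additive Gaussian noise.

    Returns
    -------
    (VideoStack, VideoGroundTruth)
    """
    t = np.arange(spec.n_frames) / spec.frame_rate_hz
    n_beats = int(np.floor(spec.duration_s * spec.pacing_rate_hz))
    peaks = np.broadcast_to(np.atleast_1d(np.asarray(spec.peak_force_n, float)),
                            (n_beats,)) if np.ndim(spec.peak_force_n) == 0 \
        else np.asarray(spec.peak_force_n, float)
    if peaks.shape != (n_beats,):
        raise ValueError(
            f"peak_force_n must be scalar or length {n_beats} (one per beat)")
    force = _beat_force_waveform(t, spec, peaks)
    disp_um = spec.geometry.deflection_for_force(force) * 1e6
    ax = np.asarray(spec.displacement_axis)
    shift_px = disp_um[:, None] / spec.pixel_scale_um * ax[None, :]
    limit = min(spec.frame_shape) / 4
    if np.abs(shift_px).max() > limit:
        raise ValueError(
            f"peak displacement {np.abs(shift_px).max():.1f} px exceeds the "
            f"usable frame bound {limit:.1f} px; enlarge frame_shape or lower "
            "peak_force_n")

    ss = np.random.SeedSequence(spec.texture_seed)
    rng_tex, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    h, w = spec.frame_shape
    tex = ndimage.gaussian_filter(rng_tex.normal(size=(h, w)), 1.5, mode="wrap")
    tex = (tex - tex.min()) / np.ptp(tex)
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - h / 2, xx - w / 2)
    disk = 1.0 / (1.0 + np.exp((rr - 0.3 * min(h, w)) / 2.0))
    base = 0.2 + 0.8 * tex * disk
    if np.ptp(base) < 1e-6:
        raise ValueError("degenerate flat texture; registration would be ill-posed")

    frames = np.empty((spec.n_frames, h, w))
    base_f = np.fft.fft2(base)
    for i in range(spec.n_frames):
        moved = np.real(np.fft.ifft2(ndimage.fourier_shift(base_f, shift_px[i])))
        frames[i] = moved * (1.0 + spec.brightness_drift) ** i
    if spec.noise_sd > 0:
        frames += rng_noise.normal(0.0, spec.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)
    stack = VideoStack(frames, frame_rate_hz=spec.frame_rate_hz,
                       pixel_scale_um=spec.pixel_scale_um)
    truth = VideoGroundTruth(time_s=t, force_n=force, displacement_um=disp_um,
                             shift_px=shift_px, axis=ax, n_beats=n_beats)
    return stack, truth


def generate_calcium_trace(spec: SyntheticTraceSpec):
    """Render a paced fluorescence trace and its per-beat ground truth.

    Each beat k (stimulus at k/pacing_rate) contributes a quarter-sine
    rise over ``rise_time_s`` to ``baseline + amplitude`` followed by an
    exponential decay with rate ``decay_rate_per_s``; contributions
    superpose, a linear drift and Gaussian noise are added on top.  A
    warning is recorded when more than 5% of a transient remains at the
    next stimulus.

    Returns
    -------
    (FluorescenceTrace, TraceGroundTruth)
    """
    from .calcium import FluorescenceTrace

    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    period = 1.0 / spec.pacing_rate_hz
    n_beats = int(np.floor(spec.duration_s * spec.pacing_rate_hz))
    x = np.full(n, spec.baseline, dtype=float)
    for k in range(n_beats):
        s = t - k * period
        rise = (s >= 0) & (s < spec.rise_time_s)
        x[rise] += spec.amplitude * np.sin(np.pi * s[rise] / (2 * spec.rise_time_s))
        dec = s >= spec.rise_time_s
        x[dec] += spec.amplitude * np.exp(-spec.decay_rate_per_s * (s[dec] - spec.rise_time_s))
    x += spec.drift_slope * t
    if spec.noise_sd > 0:
        x += np.random.default_rng(spec.seed).normal(0.0, spec.noise_sd, n)

    warnings_ = []
    residual = math.exp(-spec.decay_rate_per_s * (period - spec.rise_time_s))
    if spec.amplitude > 0 and residual > OVERLAP_TOLERANCE:
        warnings_.append(
            f"transient overlaps the next stimulus: {residual:.1%} of the "
            f"amplitude remains after one pacing period (tolerance "
            f"{OVERLAP_TOLERANCE:.0%})")
    beats = pd.DataFrame({
        "beat": np.arange(n_beats),
        "amplitude": np.full(n_beats, spec.amplitude),
        "amplitude_dff": np.full(n_beats, spec.amplitude / spec.baseline),
        "time_to_peak_s": np.full(n_beats, spec.rise_time_s),
        "decay80_s": np.full(n_beats, math.log(5.0) / spec.decay_rate_per_s),
    })
    trace = FluorescenceTrace(time_s=t, intensity=x, roi_id="synthetic",
                              pacing_rate_hz=spec.pacing_rate_hz)
    return trace, TraceGroundTruth(beats=beats, warnings=warnings_)


@dataclass
class CohortMember:
    group: str
    index: int
    spec: object
    recording: object
    ground_truth: object
    scale: float                     # drawn per-recording effect multiplier


@dataclass
class Cohort:
    members: list[CohortMember]
    prescribed_effects: dict
    seed: int

    def group(self, label: str):
        return [m for m in self.members if m.group == label]


def _scaled_spec(spec, scale: float, seed: int):
    """Copy of a spec with its headline magnitude scaled and seed replaced."""
    import dataclasses

    if isinstance(spec, SyntheticVideoSpec):
        return dataclasses.replace(
            spec, peak_force_n=np.asarray(spec.peak_force_n) * scale,
            texture_seed=seed)
    if isinstance(spec, SyntheticTraceSpec):
        return dataclasses.replace(spec, amplitude=spec.amplitude * scale,
                                   seed=seed)
    raise TypeError(f"unsupported spec type {type(spec).__name__}")


def generate_cohort(spec_control, spec_disease, n_per_group: int, seed: int,
                    between_sample_cv: float = 0.1) -> Cohort:
    """Generate a labelled two-group cohort of recordings.

    Each recording draws an independent multiplicative scale
    ``Normal(1, between_sample_cv)`` (clipped at 0.2) applied to the
    group spec's headline magnitude (peak force for videos, amplitude
    for traces); sub-seeds are derived deterministically from ``seed``,
    so the same seed reproduces the cohort bit for bit.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    ss = np.random.SeedSequence(seed)
    draws_rng = np.random.default_rng(ss.spawn(1)[0])
    member_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_per_group)]
    members = []
    for g, spec in (("control", spec_control), ("disease", spec_disease)):
        for i in range(n_per_group):
            scale = float(np.clip(draws_rng.normal(1.0, between_sample_cv), 0.2, None))
            sub = _scaled_spec(spec, scale, member_seeds[len(members)])
            if isinstance(sub, SyntheticVideoSpec):
                rec, truth = generate_pillar_video(sub)
            else:
                rec, truth = generate_calcium_trace(sub)
            members.append(CohortMember(group=g, index=i, spec=sub,
                                        recording=rec, ground_truth=truth,
                                        scale=scale))
    effects = {}
    if isinstance(spec_control, SyntheticVideoSpec):
        c = float(np.max(np.atleast_1d(spec_control.peak_force_n)))
        d = float(np.max(np.atleast_1d(spec_disease.peak_force_n)))
        effects["force_ratio"] = d / c if c else float("nan")
    else:
        effects["amplitude_ratio"] = (spec_disease.amplitude / spec_control.amplitude
                                      if spec_control.amplitude else float("nan"))
        effects["time_to_peak_ratio"] = spec_disease.rise_time_s / spec_control.rise_time_s
        effects["decay80_ratio"] = (spec_control.decay_rate_per_s
                                    / spec_disease.decay_rate_per_s)
    return Cohort(members=members, prescribed_effects=effects, seed=seed)
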