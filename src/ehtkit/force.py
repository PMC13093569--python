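"""Displacement-to-force conversion and per-beat contractile metrics.

The tracked pillar-head displacement δ(t) maps to force through the
cantilever stiffness, P(t) = k·δ(t) with k = 3EI/L³.  The resting
(diastolic) level of the displacement trace is estimated as the median
of its lowest decile and subtracted first, so the reported force is the
active contractile force above baseline; the unsubtracted conversion is
kept alongside.  Force is reported for the tracked pillar only — the
beam formula describes a single cantilever.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import PillarGeometry
from .registration import DisplacementTrace

__all__ = ["ForceTrace", "BeatMetrics", "displacement_to_force", "beat_metrics"]


@dataclass
class ForceTrace:
    """Force time series derived from a displacement trace."""

    time_s: np.ndarray
    force_n: np.ndarray             # baseline-subtracted (headline)
    force_absolute_n: np.ndarray    # without baseline subtraction
    baseline_um: float
    geometry: PillarGeometry

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.time_s, "force_n": self.force_n,
                             "force_absolute_n": self.force_absolute_n})


@dataclass
class BeatMetrics:
    """Per-beat contraction summary of a force trace.

    ``max_force_n`` is the force at maximum pillar deflection over the
    whole recording; ``peak_forces_n`` holds one peak per detected beat.
    A recording with no beats above the prominence threshold yields
    ``n_beats = 0`` with empty arrays — an explicit "no beats" result.
    """

    peak_forces_n: np.ndarray
    beat_times_s: np.ndarray
    max_force_n: float
    mean_peak_force_n: float
    baseline_force_n: float
    n_beats: int
    no_beats: bool = False
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_beats": self.n_beats,
            "no_beats": self.no_beats,
            "mean_peak_force_n": None if self.no_beats else self.mean_peak_force_n,
            "max_force_n": None if self.no_beats else self.max_force_n,
            "baseline_force_n": self.baseline_force_n,
            "peak_forces_n": self.peak_forces_n.tolist(),
            "beat_times_s": self.beat_times_s.tolist(),
        }


def displacement_to_force(trace: DisplacementTrace,
                          geometry: PillarGeometry) -> ForceTrace:
    """Convert a displacement trace (μm) to force (N) via P = k·δ.

    The diastolic baseline — the median of the lowest decile of the
    displacement samples — is subtracted before conversion; a warning is
    emitted when deflections leave the small-deflection regime (>10% of
    the pillar length), where the linear beam formula loses accuracy.
    """
    disp = np.asarray(trace.displacement_um, float)
    if disp.shape != np.asarray(trace.time_s).shape:
        raise ValueError("displacement and time arrays have mismatched lengths")
    k = geometry.stiffness_n_per_m
    lowest = np.sort(disp)[:max(1, disp.size // 10)]
    baseline = float(np.median(lowest))
    if np.max(np.abs(disp)) * 1e-6 > 0.1 * geometry.length_m:
        warnings.warn("deflection exceeds 10% of pillar length; the linear "
                      "cantilever formula is inaccurate there", stacklevel=2)
    return ForceTrace(
        time_s=np.asarray(trace.time_s, float),
        force_n=k * (disp - baseline) * 1e-6,
        force_absolute_n=k * disp * 1e-6,
        baseline_um=baseline,
        geometry=geometry,
    )


def beat_metrics(force: ForceTrace, pacing_rate_hz: float = 1.0,
                 min_prominence_n: float | None = None) -> BeatMetrics:
    """Segment a force trace into pacing periods and summarise the beats.

    The stimulus phase is anchored to the global force maximum (no
    stimulus log is assumed); each full pacing period centred on that
    phase contributes one beat whose peak is the window maximum.  Beats
    must exceed ``min_prominence_n`` above the window baseline —
    default 3× the baseline noise SD estimated from first differences —
    otherwise they are not counted.
    """
    if pacing_rate_hz <= 0:
        raise ValueError("pacing_rate_hz must be positive")
    t = np.asarray(force.time_s, float)
    f = np.asarray(force.force_n, float)
    n = t.size
    if n < 3:
        raise ValueError("force trace too short")
    dt = float(np.mean(np.diff(t)))
    period = 1.0 / pacing_rate_hz
    # noise SD from first differences: flat diastolic segments dominate the
    # median absolute difference, so smooth contraction ramps barely inflate it
    d = np.diff(f)
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)
    span = float(np.max(f) - np.min(f))
    if min_prominence_n is not None:
        prom = min_prominence_n
    else:
        # 3x the diastolic noise, but never below 5% of the force span so a
        # noiseless flat window cannot promote numerical ripple into a beat
        prom = max(3.0 * sigma, 0.05 * span)
    if span <= 0 or (prom > 0 and span < prom):
        return BeatMetrics(np.array([]), np.array([]), math.nan, math.nan,
                           float(np.median(f)) if n else math.nan, 0,
                           no_beats=True,
                           diagnostics={"prominence_n": prom, "noise_sd_n": sigma})
    i_max = int(np.argmax(f))
    phase = t[i_max] % period
    start = t[0] + ((phase - period / 2.0) - t[0]) % period
    if start > t[0]:
        start -= period               # include a clipped leading window
    peaks, times = [], []
    w0 = start
    while w0 < t[-1]:
        m = (t >= w0) & (t < w0 + period)
        w0 += period
        if m.sum() < 3:
            continue
        seg = f[m]
        ts = t[m]
        base_w = float(np.median(np.sort(seg)[:max(1, seg.size // 4)]))
        j = int(np.argmax(seg))
        # a clipped edge window only counts when its peak is interior to the
        # recording, i.e. the beat itself is complete
        if ts[j] <= t[0] + dt / 2 or ts[j] >= t[-1] - dt / 2:
            continue
        if seg[j] - base_w < prom:
            continue
        peaks.append(float(seg[j]))
        times.append(float(ts[j]))
    if not peaks:
        return BeatMetrics(np.array([]), np.array([]), math.nan, math.nan,
                           float(np.median(f)), 0, no_beats=True,
                           diagnostics={"prominence_n": prom, "noise_sd_n": sigma})
    peaks_a = np.array(peaks)
    return BeatMetrics(
        peak_forces_n=peaks_a,
        beat_times_s=np.array(times),
        max_force_n=float(np.max(f)),
        mean_peak_force_n=float(peaks_a.mean()),
        baseline_force_n=float(np.median(np.sort(f)[:max(1, n // 10)])),
        n_beats=len(peaks),
        diagnostics={"prominence_n": prom, "noise_sd_n": sigma},
    )
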