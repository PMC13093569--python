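"""Ca²⁺ transient kinetics from paced fluorescence traces.

For cardiomyocytes paced at 1 Hz and loaded with a calcium indicator,
each beat produces one fluorescence transient.  Three per-beat features
summarise Ca²⁺ handling:

* **amplitude** — peak ΔF/F₀ above the pre-beat baseline;
* **time to peak** — upstroke onset to transient peak (s); the onset is
  the 10%-amplitude departure from baseline, estimated by a line fit to
  the low-amplitude rising segment, because stimulus timestamps are not
  recorded in the trace files;
* **decay80** — the time from the peak until the signal has fallen by
  80% of the amplitude (the decay "tau" of the force-of-habit naming;
  for a pure exponential with rate λ it equals ln(5)/λ).  The crossing
  is localised by linear interpolation between samples, stabilised by a
  short local line fit.

Feature means are aggregated per region of interest (ROI) over up to 10
consecutive valid beats.

Estimator notes (all model-light, tuned for unbiasedness at ~5% noise):
baselines are means over smoothed pre-onset samples rather than order
statistics (a lower-decile minimum is biased low under noise); the peak
*time* is anchored on a log-linear fit of the exponential decay branch
extrapolated back to the amplitude level, which is exact in the
noiseless limit and, unlike an argmax at the rise/decay kink, not
systematically early under noise; the log fit carries a delta-method
noise-bias correction.  A true exponential-fit time constant
(``tau_exp_s`` = 1/λ̂) is reported alongside decay80 as a clearly
separate secondary output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "FluorescenceTrace",
    "BeatWindow",
    "TransientFeatures",
    "RoiSummary",
    "normalize_dff",
    "segment_beats",
    "transient_features",
    "aggregate_roi",
    "analyze_trace",
]

#: onset detection uses the rising segment between these amplitude fractions
ONSET_BAND = (0.05, 0.25)

#: minimum transient amplitude, in units of the noise SD, for beat detection
MIN_SNR = 5.0


@dataclass
class FluorescenceTrace:
    """One ROI's intensity time series under electrical pacing."""

    time_s: np.ndarray
    intensity: np.ndarray
    roi_id: str = "roi0"
    pacing_rate_hz: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.intensity.shape:
            raise ValueError("time_s and intensity must be equal-length 1-D arrays")
        if len(self.time_s) < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        if np.ptp(dt) > 0.01 * dt.mean():
            raise ValueError("sampling must be uniform to within 1% jitter")
        if not (np.all(np.isfinite(self.intensity)) and np.all(np.isfinite(self.time_s))):
            raise ValueError("trace contains non-finite values")
        if self.pacing_rate_hz <= 0:
            raise ValueError("pacing_rate_hz must be positive")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time_s)))


@dataclass
class BeatWindow:
    """One pacing window around a detected transient.

    The window is anchored to the detected upstroke onset with a
    pre-onset baseline margin (~0.2 pacing periods) and runs to ~0.8
    periods after the onset, so it holds one full transient plus enough
    flat baseline to reference amplitude against.
    """

    time_s: np.ndarray
    signal: np.ndarray              # ΔF/F₀
    beat_index: int = 0
    onset_time_s: float | None = None


@dataclass
class TransientFeatures:
    """Per-beat transient summary; invalid beats carry NaNs, never guesses."""

    beat_index: int
    amplitude: float
    time_to_peak_s: float
    decay80_s: float
    tau_exp_s: float = math.nan     # secondary: fitted exponential 1/λ
    valid: bool = True
    reason: str = ""


@dataclass
class RoiSummary:
    """Feature means over up to ``target_n`` consecutive valid beats."""

    roi_id: str
    amplitude: float
    time_to_peak_s: float
    decay80_s: float
    n_beats: int
    warnings: list[str] = field(default_factory=list)


def _smooth(x: np.ndarray, fs: float, width_s: float = 0.05) -> np.ndarray:
    w = max(5, int(round(fs * width_s)) | 1)
    if w >= len(x):
        w = (len(x) - 1) | 1
        if w < 3:
            return x.copy()
    return savgol_filter(x, w, 2)


def _noise_sd(x: np.ndarray, sm: np.ndarray) -> float:
    r = x - sm
    return 1.4826 * float(np.median(np.abs(r - np.median(r))))


def normalize_dff(trace: FluorescenceTrace, f0_percentile: float = 10.0,
                  detrend: bool = True) -> FluorescenceTrace:
    """Convert raw intensity to ΔF/F₀.

    A linear baseline drift is first removed by fitting a line through
    inter-beat baseline points (the lowest quartile of each pacing-period
    chunk); F₀ is then the ``f0_percentile``-th percentile of the
    detrended trace and the output is (F − F₀)/F₀.
    """
    t, x = trace.time_s, trace.intensity.copy()
    if detrend:
        n_chunks = max(2, int(round((t[-1] - t[0]) * trace.pacing_rate_hz)))
        bt, bv = [], []
        for c in np.array_split(np.arange(t.size), n_chunks):
            thr = np.percentile(x[c], 25)
            m = c[x[c] <= thr]
            if m.size:
                bt.append(t[m].mean())
                bv.append(x[m].mean())
        if len(bt) >= 2:
            line = np.polyval(np.polyfit(bt, bv, 1), t)
            x = x - line + line.mean()
    f0 = float(np.percentile(x, f0_percentile))
    if f0 <= 0:
        raise ValueError(f"non-positive baseline estimate F0={f0:.3g}; "
                         "ΔF/F₀ is undefined")
    return FluorescenceTrace(time_s=t, intensity=(x - f0) / f0,
                             roi_id=trace.roi_id,
                             pacing_rate_hz=trace.pacing_rate_hz,
                             normalized=True)


def segment_beats(trace: FluorescenceTrace,
                  pacing_rate_hz: float | None = None) -> list[BeatWindow]:
    """Split a normalized trace into per-beat windows.

    Transient peaks are detected on a smoothed copy with a minimum
    spacing of 0.7 pacing periods and a prominence of half the global
    transient amplitude; windows without a complete pre-margin or tail
    (first/last partial beats) are discarded.  Returns an empty list,
    with a warning, when no upstrokes rise above the noise.
    """
    if not trace.normalized:
        trace = normalize_dff(trace)
    rate = pacing_rate_hz or trace.pacing_rate_hz
    t, x = trace.time_s, trace.intensity
    fs = trace.sample_rate_hz
    period = 1.0 / rate
    sm7 = _smooth(x, fs, 0.07)
    sm5 = _smooth(x, fs, 0.05)
    amp_global = float(np.percentile(sm7, 98) - np.percentile(sm7, 5))
    sigma = _noise_sd(x, sm5)
    if amp_global < 1e-9 or amp_global < MIN_SNR * sigma:
        warnings.warn(f"no upstrokes detected on ROI {trace.roi_id!r} "
                      f"(amplitude {amp_global:.3g} vs noise {sigma:.3g})",
                      stacklevel=2)
        return []
    peaks, _ = find_peaks(sm7, distance=max(1, int(0.7 * period * fs)),
                          prominence=0.5 * amp_global)
    pre = int(round(0.35 * period * fs))
    post = int(round(0.65 * period * fs))
    windows = []
    for b, p in enumerate(peaks):
        i0, i1 = p - pre, p + post
        if i0 < 0 or i1 > t.size:
            continue
        windows.append(BeatWindow(time_s=t[i0:i1], signal=x[i0:i1],
                                  beat_index=b))
    if not windows:
        warnings.warn(f"all {len(peaks)} detected beats were partial windows "
                      f"on ROI {trace.roi_id!r}", stacklevel=2)
    return windows


def _onset_time(t, sm, base, amp, p, fs) -> float | None:
    """Upstroke onset: line through the low-amplitude rising run, solved
    for the baseline crossing."""
    lev = (sm[:p + 1] - base) / amp
    above = np.where(lev >= ONSET_BAND[1])[0]
    if above.size == 0:
        return None
    j = above[0]
    lo = j
    while lo > 0 and lev[lo - 1] >= ONSET_BAND[0]:
        lo -= 1
    sel = np.arange(lo, j + 1)
    if sel.size >= 2:
        slope, icpt = np.polyfit(t[sel], sm[sel], 1)
        if slope > 0:
            return float((base - icpt) / slope)
    return float(t[j])


def transient_features(window: BeatWindow) -> TransientFeatures:
    """Measure amplitude, time to peak and decay80 of one beat window.

    The window must contain a single transient with some flat baseline
    before the upstroke.  Beats whose signal never falls to 20% of the
    amplitude within the window are flagged invalid, as are windows with
    no identifiable rise; invalid beats carry NaN features.
    """
    t, x = np.asarray(window.time_s, float), np.asarray(window.signal, float)
    bad = lambda why: TransientFeatures(window.beat_index, math.nan, math.nan,
                                        math.nan, valid=False, reason=why)
    if t.size < 10:
        return bad("window too short")
    fs = 1.0 / float(np.mean(np.diff(t)))
    sm = _smooth(x, fs, 0.05)
    sigma = _noise_sd(x, sm)
    p = int(np.argmax(sm))
    if p < 3 or p > t.size - 4:
        return bad("peak at window edge")
    base = float(np.mean(sm[:max(3, int(round(0.4 * p)))]))
    amp = float(np.max(sm[max(0, p - 2):p + 3]) - base)
    if amp <= 0 or (sigma > 0 and amp < MIN_SNR * sigma):
        return bad("no transient above noise")

    onset = _onset_time(t, sm, base, amp, p, fs)
    if onset is None or onset >= t[p]:
        return bad("no upstroke onset found")

    # decay branch between the 90% and 25% amplitude levels (indices from
    # smoothed crossings: stable under noise)
    dec = np.arange(p, t.size)
    s90 = dec[sm[dec] <= base + 0.90 * amp]
    s25 = dec[sm[dec] <= base + 0.25 * amp]
    t_peak = float(t[p])
    tau_exp = math.nan
    if s90.size and s25.size and s25[0] - s90[0] >= 4:
        di = np.arange(s90[0], s25[0] + 1)
        y = np.maximum(x[di] - base, 1e-9 * amp)
        ylog = np.log(y) + sigma**2 / (2.0 * y**2)   # delta-method bias correction
        slope, icpt = np.polyfit(t[di], ylog, 1)
        if slope < 0:
            tau_exp = -1.0 / slope
            # back-extrapolate the decay line to the amplitude level: in the
            # noiseless limit this is exactly the transient peak time
            tp = (math.log(amp) - icpt) / slope
            t_peak = float(np.clip(tp, t[p] - 0.06, t[p] + 0.06))

    thr = base + 0.2 * amp
    below = dec[sm[dec] <= thr]
    if below.size == 0 or below[0] == p:
        return bad("signal never decays to the 80% level inside the window")
    b = int(below[0])
    w = np.arange(max(p + 1, b - 3), min(t.size, b + 4))
    slope, icpt = np.polyfit(t[w], sm[w], 1)
    if slope < 0:
        t_cross = float(np.clip((thr - icpt) / slope, t[w[0]], t[w[-1]]))
    else:                                            # fall back to sample interpolation
        frac = (sm[b - 1] - thr) / (sm[b - 1] - sm[b]) if sm[b - 1] != sm[b] else 0.0
        t_cross = float(t[b - 1] + frac / fs)
    decay80 = t_cross - t_peak
    ttp = t_peak - onset
    if decay80 <= 0 or ttp <= 0:
        return bad("inconsistent kinetics (non-monotonic window)")
    return TransientFeatures(beat_index=window.beat_index, amplitude=amp,
                             time_to_peak_s=ttp, decay80_s=decay80,
                             tau_exp_s=tau_exp)


def aggregate_roi(features: list[TransientFeatures], roi_id: str = "roi0",
                  target_n: int = 10) -> RoiSummary:
    """Average up to ``target_n`` consecutive valid beats into one summary."""
    valid = [f for f in features if f.valid][:target_n]
    notes = []
    n_invalid = sum(not f.valid for f in features)
    if n_invalid:
        notes.append(f"{n_invalid} invalid beats excluded")
    if not valid:
        return RoiSummary(roi_id=roi_id, amplitude=math.nan,
                          time_to_peak_s=math.nan, decay80_s=math.nan,
                          n_beats=0, warnings=notes + ["no valid beats"])
    return RoiSummary(
        roi_id=roi_id,
        amplitude=float(np.mean([f.amplitude for f in valid])),
        time_to_peak_s=float(np.mean([f.time_to_peak_s for f in valid])),
        decay80_s=float(np.mean([f.decay80_s for f in valid])),
        n_beats=len(valid), warnings=notes,
    )


def analyze_trace(trace: FluorescenceTrace, target_n: int = 10):
    """Full per-ROI pipeline: normalize, segment, measure, aggregate.

    Returns a tidy per-beat DataFrame (roi_id, beat, amplitude,
    time_to_peak_s, decay80_s, tau_exp_s, valid) and the RoiSummary.
    """
    dff = normalize_dff(trace) if not trace.normalized else trace
    windows = segment_beats(dff)
    feats = [transient_features(w) for w in windows]
    table = pd.DataFrame({
        "roi_id": trace.roi_id,
        "beat": [f.beat_index for f in feats],
        "amplitude": [f.amplitude for f in feats],
        "time_to_peak_s": [f.time_to_peak_s for f in feats],
        "decay80_s": [f.decay80_s for f in feats],
        "tau_exp_s": [f.tau_exp_s for f in feats],
        "valid": [f.valid for f in feats],
    })
    return table, aggregate_roi(feats, roi_id=trace.roi_id, target_n=target_n)
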