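"""File I/O and run configuration.

Video input is a multi-page grayscale TIFF or a directory of ordered
single-frame images; fluorescence traces are delimited text tables
(``time_s`` plus one intensity column per ROI).  Frame rate and pixel
scale are acquisition metadata, not image content, so they are carried
in the config and stamped into the TIFF description on write.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import PillarGeometry

__all__ = [
    "VideoStack",
    "RunConfig",
    "read_video",
    "write_video",
    "read_trace_table",
    "write_trace_table",
]

#: fixed intensity quantisation used when writing float frames to 16-bit TIFF
_UINT16_SCALE = 10000.0

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


@dataclass
class VideoStack:
    """Ordered grayscale frames with acquisition metadata.

    ``frames`` has shape (n_frames, height, width); intensities are
    floats in arbitrary units.  ``frame_rate_hz`` and ``pixel_scale_um``
    (μm per pixel) come from the acquisition config.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_scale_um: float = 3.79

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n, h, w), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a video stack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_rate_hz <= 0 or self.pixel_scale_um <= 0:
            raise ValueError("frame_rate_hz and pixel_scale_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def _to_grayscale(frame: np.ndarray, index: int) -> np.ndarray:
    if frame.ndim == 2:
        return frame.astype(float)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., :3].mean(axis=-1)
    raise ValueError(f"frame {index}: cannot interpret shape {frame.shape} as grayscale")


def read_video(path, frame_rate_hz: float | None = None,
               pixel_scale_um: float = 3.79) -> VideoStack:
    """Load a multi-page TIFF or a lexicographically ordered image directory.

    ``frame_rate_hz`` must be supplied unless the file was written by
    :func:`write_video` (which stores it in the TIFF description).
    """
    path = Path(path)
    meta: dict = {}
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if len(files) < 2:
            raise ValueError(f"{path}: found {len(files)} frame images, need at least 2")
        frames = []
        for i, f in enumerate(files):
            g = _to_grayscale(np.asarray(iio.imread(f)), i)
            if frames and g.shape != frames[0].shape:
                raise ValueError(
                    f"inconsistent frame shapes: {f.name} is {g.shape}, "
                    f"expected {frames[0].shape}")
            frames.append(g)
        arr = np.stack(frames)
    else:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if arr.ndim == 2:
            raise ValueError(f"{path}: single-frame file; a video needs at least 2 frames")
        arr = np.stack([_to_grayscale(arr[i], i) for i in range(arr.shape[0])])
        if "intensity_scale" in meta:
            arr = arr / float(meta["intensity_scale"])
    rate = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if rate is None:
        raise ValueError(
            "frame rate not found in file metadata; pass frame_rate_hz explicitly "
            "(it is acquisition metadata the image files do not carry)")
    scale = meta.get("pixel_scale_um", pixel_scale_um)
    return VideoStack(arr, frame_rate_hz=float(rate), pixel_scale_um=float(scale))


def write_video(stack: VideoStack, path) -> Path:
    """Write a stack as 16-bit grayscale multi-page TIFF.

    Float intensities are quantised with a fixed scale factor recorded in
    the TIFF description together with frame rate and pixel scale, so a
    round trip through :func:`read_video` restores values to within the
    quantisation step (1e-4 intensity units).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lo = stack.frames.min()
    if lo < 0:
        raise ValueError("frames must be non-negative for 16-bit export")
    data = np.clip(stack.frames * _UINT16_SCALE, 0, 65535).round().astype(np.uint16)
    desc = json.dumps({
        "frame_rate_hz": stack.frame_rate_hz,
        "pixel_scale_um": stack.pixel_scale_um,
        "intensity_scale": _UINT16_SCALE,
    })
    tifffile.imwrite(path, data, photometric="minisblack", description=desc)
    return path


def read_trace_table(path, pacing_rate_hz: float = 1.0):
    """Read per-ROI fluorescence traces from a delimited text table.

    The table must have a ``time_s`` column; every other column is one
    ROI's intensity trace.  Returns a list of FluorescenceTrace.
    """
    from .calcium import FluorescenceTrace

    df = pd.read_csv(path)
    if df.empty or len(df) < 2:
        raise ValueError(f"{path}: empty or single-row trace table")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    roi_cols = [c for c in df.columns if c != "time_s"]
    if not roi_cols:
        raise ValueError(f"{path}: no intensity columns")
    t = df["time_s"].to_numpy(float)
    return [
        FluorescenceTrace(time_s=t, intensity=df[c].to_numpy(float),
                          roi_id=str(c), pacing_rate_hz=pacing_rate_hz)
        for c in roi_cols
    ]


def write_trace_table(traces, path) -> Path:
    """Write traces sharing one time base as a wide CSV (time_s, one col/ROI)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = {"time_s": traces[0].time_s}
    for tr in traces:
        if tr.time_s.shape != traces[0].time_s.shape:
            raise ValueError("traces must share one time base for a wide table")
        out[tr.roi_id] = tr.intensity
    pd.DataFrame(out).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# run configuration

_GEOMETRY_KEYS = {"length_m", "youngs_modulus_pa", "diameter_m"}


@dataclass
class RunConfig:
    """Validated configuration for the analysis pipelines.

    Unknown keys in the config file are rejected outright rather than
    ignored, so typos fail fast instead of silently running defaults.
    """

    input_path: str | None = None
    output_dir: str = "ehtkit_run"
    pixel_scale_um: float = 3.79
    frame_rate_hz: float | None = None
    pacing_rate_hz: float = 1.0
    geometry: PillarGeometry = field(default_factory=PillarGeometry)
    tracking_mode: str = "frame_to_frame_cumulative"
    roi: tuple[int, int, int, int] | None = None   # (row0, col0, height, width)
    displacement_axis: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")
        if self.frame_rate_hz is not None and self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pacing_rate_hz <= 0:
            raise ValueError("pacing_rate_hz must be positive")
        if self.tracking_mode not in ("fixed_reference", "frame_to_frame_cumulative"):
            raise ValueError(f"unknown tracking_mode {self.tracking_mode!r}")
        if self.roi is not None:
            self.roi = tuple(int(v) for v in self.roi)
            if len(self.roi) != 4 or self.roi[2] < 16 or self.roi[3] < 16:
                raise ValueError("roi must be (row0, col0, height, width) with size >= 16x16")
        if self.displacement_axis is not None:
            ax = np.asarray(self.displacement_axis, float)
            n = math.hypot(*ax)
            if ax.shape != (2,) or n == 0:
                raise ValueError("displacement_axis must be a non-zero 2-vector")
            self.displacement_axis = tuple(ax / n)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        geom = kwargs.get("geometry")
        if isinstance(geom, dict):
            bad = set(geom) - _GEOMETRY_KEYS
            if bad:
                raise ValueError(f"unknown geometry keys: {sorted(bad)}")
            kwargs["geometry"] = PillarGeometry(**geom)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = {
            "length_m": self.geometry.length_m,
            "youngs_modulus_pa": self.geometry.youngs_modulus_pa,
            "diameter_m": self.geometry.diameter_m,
        }
        return d
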