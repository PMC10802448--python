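"""Preprocessing of in-vitro fluorescence voltage/calcium recordings.

Optical recordings (e.g. 125 samples/s plate-imager output) enter the
calibration pipeline through a fixed chain -- baseline-drift subtraction by
grayscale morphological erosion, median filtering, final-window extraction,
resampling to the 0.1 ms grid and min-max normalization -- after which they
are indistinguishable from synthetic normalized recordings and can be fed
straight to the GA fitness.

Input dialect: comma-separated text with a header row containing columns
``time`` (seconds), ``v`` and ``ca`` (arbitrary fluorescence units), decimal
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import grey_dilation, grey_erosion, median_filter

from .model_core import StimulusSpec
from .protocols import DegenerateSignalError, Recording

__all__ = [
    "RawRecording", "ParseError", "read_raw", "write_raw",
    "subtract_baseline", "denoise", "to_recording", "process_chain",
    "is_validation_condition",
]

#: native sampling rate of the supported plate imager (samples/s)
DEFAULT_RATE_HZ = 125.0


class ParseError(ValueError):
    pass


@dataclass
class RawRecording:
    """Native-rate fluorescence traces with condition metadata."""

    t_s: np.ndarray
    v: np.ndarray
    ca: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if not (self.t_s.shape == self.v.shape == self.ca.shape):
            raise ValueError("time and channels must have identical length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_s)))

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


def read_raw(path, metadata: dict | None = None) -> RawRecording:
    """Parse a delimited recording; units are preserved as-is.

    Missing columns or a non-monotone time axis raise :class:`ParseError`
    carrying the offending line number (1-based, counting the header).
    """
    df = pd.read_csv(path)
    missing = {"time", "v", "ca"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    t = df["time"].to_numpy(dtype=float)
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        line = int(bad[0]) + 3  # header + 1-based + offending second sample
        raise ParseError(f"{path}: time not strictly increasing at line {line}")
    return RawRecording(t, df["v"].to_numpy(dtype=float),
                        df["ca"].to_numpy(dtype=float),
                        metadata=dict(metadata or {}))


def write_raw(raw: RawRecording, path) -> None:
    pd.DataFrame({"time": raw.t_s, "v": raw.v, "ca": raw.ca}).to_csv(
        path, index=False)


def subtract_baseline(signal: np.ndarray, structure_width_s: float,
                      rate_hz: float = DEFAULT_RATE_HZ,
                      smooth: bool = True) -> np.ndarray:
    """Remove slow drift: estimate the running baseline as the grayscale
    erosion (sliding minimum) of the signal with the given structuring
    width, optionally smoothed, and subtract it.

    The structure width must exceed the beat period, otherwise beats are
    eaten into the baseline.  The inter-beat baseline of the output is ~0.
    """
    signal = np.asarray(signal, dtype=float)
    width = int(round(structure_width_s * rate_hz))
    if width >= signal.size:
        raise ValueError(
            f"structuring width ({width} samples) exceeds the record "
            f"({signal.size} samples)")
    width = max(width, 1)
    base = grey_erosion(signal, size=width, mode="nearest")
    if smooth:
        # closing the erosion with a dilation of the same width (a
        # morphological opening) tracks a drifting baseline without the
        # half-window bias of the bare sliding minimum
        base = grey_dilation(base, size=width, mode="nearest")
        base = np.minimum(base, signal)
    return signal - base


def denoise(signal: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Sliding-window median filter (odd kernel, reflected edges)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be an odd positive count")
    if kernel == 1:
        return np.asarray(signal, dtype=float).copy()
    return median_filter(np.asarray(signal, dtype=float), size=kernel,
                         mode="reflect")


def to_recording(raw: RawRecording, window_s: float = 5.0,
                 dt_ms: float = 0.1) -> Recording:
    """Final window of a (processed) raw recording, resampled to the
    uniform grid by linear interpolation and min-max normalized per channel.

    The output is interchangeable with synthetic normalized recordings in
    the GA fitness.
    """
    if raw.duration_s + 1e-12 < window_s:
        raise ValueError(
            f"recording ({raw.duration_s:.2f} s) shorter than the "
            f"{window_s:.2f} s window")
    t_ms = raw.t_s * 1000.0
    t_end = t_ms[-1]
    n = int(round(window_s * 1000.0 / dt_ms))
    grid = t_end - window_s * 1000.0 + np.arange(n + 1) * dt_ms
    channels = []
    for name, x in (("v", raw.v), ("ca", raw.ca)):
        xi = np.interp(grid, t_ms, x)
        lo, hi = float(xi.min()), float(xi.max())
        if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
            raise DegenerateSignalError(
                f"channel {name} constant in the final window")
        channels.append((xi - lo) / (hi - lo))
    hz = float(raw.metadata.get("pacing_hz") or 0.0)
    pacing = StimulusSpec.paced(hz) if hz > 0 else None
    label = str(raw.metadata.get("label", "in-vitro"))
    return Recording(label, grid - grid[0], channels[0], channels[1],
                     normalized=True, pacing=pacing)


def process_chain(raw: RawRecording, structure_width_s: float | None = None,
                  kernel: int = 5, window_s: float = 5.0,
                  dt_ms: float = 0.1) -> Recording:
    """The order-fixed chain: baseline -> median -> window -> normalize.

    The default structuring width is 1.5x the expected beat period from the
    metadata pacing rate (1.5 s if unpaced).
    """
    if structure_width_s is None:
        hz = float(raw.metadata.get("pacing_hz") or 1.0)
        structure_width_s = 1.5 / hz
    rate = raw.rate_hz
    v = denoise(subtract_baseline(raw.v, structure_width_s, rate), kernel)
    ca = denoise(subtract_baseline(raw.ca, structure_width_s, rate), kernel)
    cleaned = RawRecording(raw.t_s, v, ca, metadata=raw.metadata)
    return to_recording(cleaned, window_s=window_s, dt_ms=dt_ms)


def is_validation_condition(metadata: dict) -> bool:
    """The (1.0 mM Ca2+, 2 Hz) condition is held out from calibration and
    reserved for validating model predictions."""
    return (abs(float(metadata.get("cao_mM", 1.8)) - 1.0) < 1e-9
            and abs(float(metadata.get("pacing_hz", 0.0)) - 2.0) < 1e-9)
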