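"""Preprocessing of skin-conductance signals.

The stages mirror the usual wearable-EDA pipeline: optional down-sampling
(with anti-alias filtering), moving-average smoothing against motion
artifacts, amplitude normalization, and a zero-phase low-pass Butterworth
filter that is applied to the phasic component after decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .io import EdaRecording, round_half_away

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "downsample",
    "smooth_moving_average",
    "normalize",
    "lowpass_butterworth",
    "preprocess_recording",
]


@dataclass
class PreprocessConfig:
    """Parameters for the preprocessing stage.

    ``target_fs`` only takes effect when it is below the native rate; wrist
    devices sampling at 4 Hz are left untouched.
    """

    target_fs: float = 20.0
    smooth_window_s: float = 1.0
    butter_order: int = 2
    butter_cutoff_hz: float = 1.0
    normalization: str = "zscore"  # zscore | minmax | none

    def __post_init__(self) -> None:
        if self.smooth_window_s <= 0:
            raise ValueError("smooth_window_s must be positive")
        if self.normalization not in ("zscore", "minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def downsample(rec: EdaRecording, target_fs: float) -> EdaRecording:
    """Resample to ``target_fs`` if it is below the native rate, else no-op.

    Uses polyphase resampling with a built-in anti-alias FIR; edge samples
    are extended linearly so constant and slowly drifting signals survive
    the filter edges.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs >= rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator,
                               padtype="line")
    new_fs = rec.fs * frac.numerator / frac.denominator
    logger.info("down-sampled %g Hz -> %g Hz (%d -> %d samples)",
                rec.fs, new_fs, len(rec.samples), len(out))
    return rec.with_samples(out, fs=new_fs)


def smooth_moving_average(samples: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Centred moving average; windows shrink at the edges instead of padding."""
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty signal")
    w = max(1, round_half_away(window_s * fs))
    if w == 1 or x.size == 1:
        return x.copy()
    kernel = np.ones(w)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def normalize(samples: np.ndarray, method: str = "zscore") -> np.ndarray:
    """Normalize amplitude: z-score (population SD), min-max to [0, 1], or none.

    Degenerate constant inputs normalize to the zero vector with a warning.
    """
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty signal")
    if method == "none":
        return x.copy()
    if method == "zscore":
        sd = float(np.std(x))
        if sd == 0.0:
            warnings.warn("constant signal: z-score undefined, returning zeros")
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    if method == "minmax":
        rng = float(x.max() - x.min())
        if rng == 0.0:
            warnings.warn("constant signal: min-max undefined, returning zeros")
            return np.zeros_like(x)
        return (x - x.min()) / rng
    raise ValueError(f"unknown normalization {method!r}")


def lowpass_butterworth(samples: np.ndarray, fs: float, order: int = 2,
                        cutoff_hz: float = 1.0) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter; DC gain 1."""
    x = np.asarray(samples, float)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, fs/2={fs / 2})")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = min(3 * (2 * order + 1), x.size - 1)
    if padlen < 1:
        return x.copy()
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def preprocess_recording(rec: EdaRecording, cfg: PreprocessConfig) -> EdaRecording:
    """Down-sample, smooth, and normalize a recording (in that order)."""
    rec = downsample(rec, cfg.target_fs)
    out = smooth_moving_average(rec.samples, rec.fs, cfg.smooth_window_s)
    out = normalize(out, cfg.normalization)
    return rec.with_samples(out)
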