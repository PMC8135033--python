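"""SCR peak detection and the 11 per-window statistical features.

Peak-derived features (``n_peaks``, ``max_peak``) are computed on the
filtered phasic component, where skin-conductance responses live; the nine
remaining statistics are computed on the preprocessed signal window.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "REFERENCE_FEATURES",
    "Peak",
    "FeatureVector",
    "detect_peaks",
    "mavfd",
    "mavsd",
    "compute_features",
]

FEATURE_NAMES = (
    "n_peaks", "mean", "max_peak", "range", "std", "iqr", "rms",
    "mean_minima", "mean_maxima", "mavfd", "mavsd",
)

#: The nine features of the heat-pain reference study: peak-shape and
#: dispersion statistics without the peak count and signal mean.
REFERENCE_FEATURES = (
    "max_peak", "range", "std", "iqr", "rms",
    "mean_minima", "mean_maxima", "mavfd", "mavsd",
)


@dataclass(frozen=True)
class Peak:
    index: int
    time: float
    amplitude: float


@dataclass(frozen=True)
class FeatureVector:
    n_peaks: float
    mean: float
    max_peak: float
    range: float
    std: float
    iqr: float
    rms: float
    mean_minima: float
    mean_maxima: float
    mavfd: float
    mavsd: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _local_extrema(x: np.ndarray, kind: str) -> list[int]:
    """Indices of strict interior local maxima/minima; plateaus take the
    first index of the run and count only when strictly interior."""
    sign = 1.0 if kind == "max" else -1.0
    v = sign * np.asarray(x, float)
    out: list[int] = []
    i = 1
    n = len(v)
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[i] > v[j + 1]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def detect_peaks(phasic: np.ndarray, fs: float, min_amplitude: float = 0.01) -> list[Peak]:
    """Strict local maxima of the phasic series with amplitude >= threshold.

    Amplitude is the phasic value at the peak. Series shorter than 3
    samples have no interior maxima and yield an empty list.
    """
    x = np.asarray(phasic, float)
    if x.size < 3:
        return []
    return [Peak(i, i / fs, float(x[i]))
            for i in _local_extrema(x, "max") if x[i] >= min_amplitude]


def mavfd(samples: np.ndarray) -> float:
    """Mean absolute value of the first (lag-1) differences."""
    x = np.asarray(samples, float)
    if x.size < 2:
        raise ValueError("mavfd needs at least 2 samples")
    return float(np.mean(np.abs(np.diff(x))))


def mavsd(samples: np.ndarray) -> float:
    """Mean absolute value of the second (lag-2) differences."""
    x = np.asarray(samples, float)
    if x.size < 3:
        raise ValueError("mavsd needs at least 3 samples")
    return float(np.mean(np.abs(x[2:] - x[:-2])))


def compute_features(win_preprocessed: np.ndarray, win_phasic: np.ndarray,
                     fs: float, min_amplitude: float = 0.01) -> FeatureVector:
    """The 11 statistics for one labeled window.

    ``std`` is the population standard deviation; quartiles use linear
    interpolation; mean of local minima/maxima falls back to the global
    extremum when a window has no strict interior extremum.
    """
    x = np.asarray(win_preprocessed, float)
    p = np.asarray(win_phasic, float)
    if x.size != p.size:
        raise ValueError(f"window length mismatch: {x.size} vs {p.size}")
    if x.size < 3:
        raise ValueError("window must hold at least 3 samples")

    peaks = detect_peaks(p, fs, min_amplitude)
    maxima = _local_extrema(x, "max")
    minima = _local_extrema(x, "min")
    q75, q25 = np.percentile(x, [75, 25])
    return FeatureVector(
        n_peaks=float(len(peaks)),
        mean=float(x.mean()),
        max_peak=float(max((pk.amplitude for pk in peaks), default=0.0)),
        range=float(x.max() - x.min()),
        std=float(x.std()),
        iqr=float(q75 - q25),
        rms=float(np.sqrt(np.mean(x ** 2))),
        mean_minima=float(np.mean(x[minima]) if minima else x.min()),
        mean_maxima=float(np.mean(x[maxima]) if maxima else x.max()),
        mavfd=mavfd(x),
        mavsd=mavsd(x),
    )
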