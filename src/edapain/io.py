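"""Reading, writing and windowing of electrodermal activity (EDA) recordings.

Two fixed CSV dialects are supported:

* the Empatica-E4 export dialect: line 1 is the Unix start timestamp, line 2
  the sampling rate in Hz, and every following line one skin-conductance
  sample in microsiemens;
* a label-event dialect with header ``timestamp,nrs`` (optionally a third
  ``origin`` column) carrying numeric-rating-scale pain self-reports.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EdaRecording",
    "LabelEvent",
    "LabelOrigin",
    "Window",
    "FormatError",
    "read_eda_csv",
    "write_eda_csv",
    "read_generic_csv",
    "read_label_events",
    "write_label_events",
    "extract_windows",
]


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


class LabelOrigin(str, Enum):
    REPORTED = "reported"
    AUGMENTED = "augmented"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties going away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class EdaRecording:
    """One subject's uniformly sampled skin-conductance time series.

    Sample ``i`` occurs at ``start_time + i / fs`` seconds since the epoch;
    conductance is in microsiemens.
    """

    subject_id: str
    start_time: float
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "EdaRecording":
        return replace(self, samples=np.asarray(samples, float),
                       fs=self.fs if fs is None else fs)


@dataclass(frozen=True)
class LabelEvent:
    """A timestamped numeric-rating-scale (NRS) pain self-report.

    ``origin`` distinguishes patient-reported events from baseline events
    added by the augmentation step (which are always NRS 0).
    """

    timestamp: float
    nrs: int
    origin: LabelOrigin = LabelOrigin.REPORTED

    def __post_init__(self) -> None:
        if not (0 <= self.nrs <= 10):
            raise ValueError(f"NRS must be in 0..10, got {self.nrs}")
        if self.origin is LabelOrigin.AUGMENTED and self.nrs != 0:
            raise ValueError("augmented events must carry NRS 0")


@dataclass(frozen=True)
class Window:
    """A fixed-duration slice of a recording centred on a label event."""

    subject_id: str
    center_time: float
    samples: np.ndarray
    fs: float
    label: LabelEvent
    start_index: int = field(default=0)

    @property
    def stop_index(self) -> int:
        return self.start_index + len(self.samples)


def read_eda_csv(path: str | Path, subject_id: str | None = None) -> EdaRecording:
    """Read a recording in the E4 dialect (two header lines, one sample per line)."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.strip() for ln in fh]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected at least 2 header lines, found {len(lines)}")
    try:
        start_time = float(lines[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1 is not a timestamp: {lines[0]!r}") from exc
    try:
        fs = float(lines[1])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2 is not a sampling rate: {lines[1]!r}") from exc
    samples = np.empty(len(lines) - 2)
    for i, raw in enumerate(lines[2:], start=3):
        try:
            samples[i - 3] = float(raw)
        except ValueError as exc:
            raise FormatError(f"{path}: line {i} is not a number: {raw!r}") from exc
    rec = EdaRecording(subject_id or path.stem, start_time, fs, samples)
    logger.info("read %d samples at %g Hz from %s", len(samples), fs, path)
    return rec


def write_eda_csv(rec: EdaRecording, path: str | Path) -> None:
    """Write a recording in the E4 dialect; round-trips bit-faithfully."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{rec.start_time!r}\n{rec.fs!r}\n")
        for v in rec.samples:
            fh.write(f"{float(v)!r}\n")
    logger.info("wrote %d samples to %s", len(rec.samples), path)


def read_generic_csv(path: str | Path, fs: float, subject_id: str | None = None) -> EdaRecording:
    """Read a two-column ``time,value`` CSV from a non-E4 source.

    The stated ``fs`` must match the median time step to within 1%.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file")
        rows = [(float(t), float(v)) for t, v in reader]
    if not rows:
        raise FormatError(f"{path}: no data rows")
    times = np.array([t for t, _ in rows])
    if len(times) > 1:
        step = float(np.median(np.diff(times)))
        if abs(step - 1.0 / fs) > 0.01 / fs:
            raise FormatError(f"{path}: time step {step:.4g}s inconsistent with fs={fs} Hz")
    return EdaRecording(subject_id or path.stem, float(times[0]), fs,
                        np.array([v for _, v in rows]))


def read_label_events(path: str | Path) -> list[LabelEvent]:
    """Read label events (``timestamp,nrs[,origin]``), returned sorted by time."""
    path = Path(path)
    events: list[LabelEvent] = []
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[0].strip().lower() != "timestamp":
            raise FormatError(f"{path}: expected header starting with 'timestamp'")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                ts = float(row[0])
                nrs = int(row[1])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: row {row_no} malformed: {row!r}") from exc
            if not (0 <= nrs <= 10):
                raise FormatError(f"{path}: row {row_no}: NRS {nrs} outside 0..10")
            origin = LabelOrigin(row[2]) if len(row) > 2 and row[2] else LabelOrigin.REPORTED
            events.append(LabelEvent(ts, nrs, origin))
    events.sort(key=lambda e: e.timestamp)
    logger.info("read %d label events from %s", len(events), path)
    return events


def write_label_events(events: Iterable[LabelEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp", "nrs", "origin"])
        for ev in events:
            writer.writerow([repr(ev.timestamp), ev.nrs, ev.origin.value])


def window_sample_count(fs: float, half_width_s: float) -> int:
    return round_half_away(2.0 * half_width_s * fs)


def extract_windows(
    rec: EdaRecording,
    events: Sequence[LabelEvent],
    half_width_s: float = 2.75,
) -> list[Window]:
    """Slice one fixed-length window per label event.

    Each window spans ``[t - half_width_s, t + half_width_s]`` around the event
    timestamp; events whose span would leave the recording are skipped with a
    warning. All returned windows contain exactly
    ``round(2 * half_width_s * fs)`` samples.
    """
    if half_width_s <= 0:
        raise ValueError(f"half_width_s must be positive, got {half_width_s}")
    if len(rec.samples) == 0:
        raise ValueError("cannot window an empty recording")
    n_win = window_sample_count(rec.fs, half_width_s)
    windows: list[Window] = []
    skipped = 0
    for ev in events:
        if ev.timestamp - half_width_s < rec.start_time or \
                ev.timestamp + half_width_s > rec.end_time:
            skipped += 1
            continue
        center_idx = round_half_away((ev.timestamp - rec.start_time) * rec.fs)
        start = center_idx - n_win // 2
        stop = start + n_win
        if start < 0 or stop > len(rec.samples):
            skipped += 1
            continue
        windows.append(Window(rec.subject_id, ev.timestamp,
                              rec.samples[start:stop].copy(), rec.fs, ev, start))
    if skipped:
        logger.warning("skipped %d events whose window leaves recording bounds", skipped)
    logger.info("extracted %d windows of %d samples", len(windows), n_win)
    return windows
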