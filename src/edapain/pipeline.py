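"""End-to-end feature extraction: recordings + labels -> feature table.

Per subject: preprocess the recording (down-sample, smooth, normalize),
decompose the whole preprocessed signal into tonic/phasic, low-pass filter
the phasic series, augment baseline labels, slice the 5.5-second windows
around each label, and compute the 11 statistical features per window.
Decomposition runs on whole recordings (better tonic-spline conditioning
than per-window fits) and windows are sliced afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .decomposition import DecompositionParams, cvxeda_decompose
from .features import FEATURE_NAMES, compute_features
from .io import EdaRecording, LabelEvent, extract_windows, read_eda_csv, read_label_events
from .labeling import augment_baseline, merge_pain_levels
from .preprocess import PreprocessConfig, lowpass_butterworth, preprocess_recording

logger = logging.getLogger(__name__)

__all__ = ["ExtractionConfig", "extract_subject_features", "extract_cohort_features"]

FEATURE_TABLE_COLUMNS = ["subject_id", "center_time", "label", *FEATURE_NAMES]


@dataclass
class ExtractionConfig:
    half_width_s: float = 2.75
    max_gap_s: float = 10.0
    augment: bool = True
    min_peak_amplitude: float = 0.01
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    decomposition: DecompositionParams = field(default_factory=DecompositionParams)


def extract_subject_features(rec: EdaRecording, events: list[LabelEvent],
                             cfg: ExtractionConfig | None = None) -> pd.DataFrame:
    """Feature rows (one per usable labeled window) for one subject."""
    cfg = cfg or ExtractionConfig()
    pre = preprocess_recording(rec, cfg.preprocess)
    decomp = cvxeda_decompose(pre.samples, pre.fs, cfg.decomposition)
    phasic = lowpass_butterworth(decomp.phasic, pre.fs,
                                 cfg.preprocess.butter_order,
                                 cfg.preprocess.butter_cutoff_hz)
    if cfg.augment:
        events = augment_baseline(events, pre, cfg.half_width_s, cfg.max_gap_s)
    windows = extract_windows(pre, events, cfg.half_width_s)
    rows = []
    for win in windows:
        fv = compute_features(win.samples,
                              phasic[win.start_index:win.stop_index],
                              pre.fs, cfg.min_peak_amplitude)
        rows.append({"subject_id": win.subject_id,
                     "center_time": win.center_time,
                     "label": merge_pain_levels(win.label.nrs),
                     **fv.as_dict()})
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)


def extract_cohort_features(cohort_dir: str | Path,
                            cfg: ExtractionConfig | None = None) -> pd.DataFrame:
    """Run extraction over every ``*_eda.csv`` / ``*_labels.csv`` pair."""
    cohort_dir = Path(cohort_dir)
    eda_files = sorted(cohort_dir.glob("*_eda.csv"))
    if not eda_files:
        raise FileNotFoundError(f"no *_eda.csv recordings under {cohort_dir}")
    tables = []
    for eda_path in eda_files:
        subject = eda_path.name[: -len("_eda.csv")]
        rec = read_eda_csv(eda_path, subject_id=subject)
        events = read_label_events(cohort_dir / f"{subject}_labels.csv")
        tables.append(extract_subject_features(rec, events, cfg))
        logger.info("subject %s: %d feature rows", subject, len(tables[-1]))
    return pd.concat(tables, ignore_index=True)
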