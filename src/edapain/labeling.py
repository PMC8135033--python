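"""NRS label re-binning and baseline augmentation.

The 11-point numeric rating scale is merged into 5 classes — baseline (BL)
plus four pain levels — so class sizes stay workable: NRS 1-3 -> PL1,
4 -> PL2, 5-7 -> PL3, 8-10 -> PL4. Baseline events, which patients report
rarely, are augmented with extra NRS-0 events placed close to reported
baselines in stretches of signal that no other labeled window touches.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Sequence

from .io import EdaRecording, LabelEvent, LabelOrigin

logger = logging.getLogger(__name__)

__all__ = [
    "N_CLASSES",
    "merge_pain_levels",
    "rebin_distribution",
    "augment_baseline",
]

N_CLASSES = 5

_MERGE = {0: 0, 1: 1, 2: 1, 3: 1, 4: 2, 5: 3, 6: 3, 7: 3, 8: 4, 9: 4, 10: 4}


def merge_pain_levels(nrs: int) -> int:
    """Map an NRS self-report (0-10) onto the merged 5-class scale (0-4)."""
    if nrs not in _MERGE:
        raise ValueError(f"NRS must be an integer in 0..10, got {nrs!r}")
    return _MERGE[nrs]


def rebin_distribution(counts: Mapping[int, int]) -> dict[int, int]:
    """Re-bin a per-NRS-level histogram onto the merged 5-class scale."""
    out = {c: 0 for c in range(N_CLASSES)}
    for level, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count {n} for level {level}")
        out[merge_pain_levels(level)] += n
    return out


def _windows_overlap(t1: float, t2: float, half_width_s: float) -> bool:
    return abs(t1 - t2) < 2.0 * half_width_s


def augment_baseline(
    events: Sequence[LabelEvent],
    rec: EdaRecording,
    half_width_s: float = 2.75,
    max_gap_s: float = 10.0,
    max_per_event: int | None = None,
) -> list[LabelEvent]:
    """Add synthetic baseline (NRS 0) events near reported baselines.

    Candidates are scanned earliest-first on a 1-sample grid strictly
    within ``max_gap_s`` of each reported NRS-0 event. A candidate is kept
    only if its window lies inside the recording and overlaps no other
    event's window — reported or already augmented — so no signal sample
    feeds two baseline windows. Deterministic; returns the input events
    plus the additions, sorted by time.
    """
    step = 1.0 / rec.fs
    out = list(events)
    n_added = 0
    for anchor in [e for e in events if e.nrs == 0 and e.origin is LabelOrigin.REPORTED]:
        added_here = 0
        # earliest-first grid over (anchor - max_gap, anchor + max_gap)
        n_steps = int(max_gap_s / step)
        candidates = [anchor.timestamp + i * step
                      for i in range(-n_steps, n_steps + 1)]
        for t in candidates:
            if max_per_event is not None and added_here >= max_per_event:
                break
            if not abs(t - anchor.timestamp) < max_gap_s or t == anchor.timestamp:
                continue
            if t - half_width_s < rec.start_time or t + half_width_s > rec.end_time:
                continue
            if any(_windows_overlap(t, e.timestamp, half_width_s) for e in out):
                continue
            out.append(LabelEvent(t, 0, LabelOrigin.AUGMENTED))
            added_here += 1
            n_added += 1
    out.sort(key=lambda e: e.timestamp)
    if n_added:
        logger.info("augmented baseline: %d -> %d NRS-0 events",
                    sum(1 for e in events if e.nrs == 0),
                    sum(1 for e in out if e.nrs == 0))
    return out


def class_distribution(events: Sequence[LabelEvent]) -> dict[int, int]:
    """Histogram of merged classes over a set of label events."""
    c = Counter(merge_pain_levels(e.nrs) for e in events)
    return {k: c.get(k, 0) for k in range(N_CLASSES)}
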