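"""Synthetic postoperative EDA cohorts with planted pain effects.

The unavailable patient recordings are emulated per subject as ~30 minutes
of 4 Hz skin conductance: a tonic level with a bounded random-walk drift,
skin-conductance responses (SCRs) rendered as Bateman pulses whose rate and
amplitude grow with the planted pain class, Gaussian sensor noise, sparse
biphasic motion-artifact spikes, and sparse NRS-labeled timestamps whose
level histogram is imbalanced like real self-report data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .decomposition import bateman_kernel
from .io import EdaRecording, LabelEvent, write_eda_csv, write_label_events
from .labeling import merge_pain_levels

logger = logging.getLogger(__name__)

__all__ = ["CohortSimConfig", "simulate_subject", "simulate_cohort"]

#: Cohort-wide event counts per NRS level, imbalanced the way sparse
#: self-reports from postoperative patients are (most reports mid-scale,
#: very few at the top of the scale).
DEFAULT_EVENTS_PER_LEVEL = {0: 37, 1: 52, 2: 37, 3: 61, 4: 83,
                            5: 44, 6: 32, 7: 16, 8: 46, 9: 26, 10: 4}


@dataclass
class CohortSimConfig:
    """Study conditions for the simulated cohort.

    SCR rates (per minute, near a label event) and mean SCR amplitudes
    (microsiemens) are per merged pain class 0-4 and must increase strictly
    with class, the planted direction of the pain effect.
    """

    n_subjects: int = 20
    duration_s: float = 1800.0
    fs: float = 4.0
    events_per_level: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_EVENTS_PER_LEVEL))
    scr_rate_per_min: dict[int, float] = field(
        default_factory=lambda: {0: 2.0, 1: 6.0, 2: 10.0, 3: 16.0, 4: 24.0})
    scr_amp_mean: dict[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.15, 2: 0.30, 3: 0.50, 4: 0.80})
    scr_amp_sigma: float = 0.4  # lognormal shape
    background_scr_rate_per_min: float = 1.0
    tonic_level: float = 2.0
    tonic_drift_sd: float = 0.15
    noise_sd: float = 0.02
    artifact_rate_per_min: float = 0.3
    event_half_width_s: float = 2.75
    min_event_spacing_s: float = 12.0
    edge_margin_s: float = 20.0
    tau0: float = 2.0
    tau1: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mapping in (("scr_rate_per_min", self.scr_rate_per_min),
                              ("scr_amp_mean", self.scr_amp_mean)):
            vals = [mapping[c] for c in sorted(mapping)]
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.events_per_level.values()):
            raise ValueError("event counts must be non-negative")
        if self.n_subjects < 1 or self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("invalid cohort geometry")

    def has_planted_effect(self) -> bool:
        rates = [self.scr_rate_per_min[c] for c in sorted(self.scr_rate_per_min)]
        amps = [self.scr_amp_mean[c] for c in sorted(self.scr_amp_mean)]
        return any(b > a for a, b in zip(rates, rates[1:])) or \
            any(b > a for a, b in zip(amps, amps[1:]))


def levels_for_subject(config: CohortSimConfig, subject_index: int) -> list[int]:
    """Deterministic round-robin split of the cohort event totals."""
    flat: list[int] = []
    for level in sorted(config.events_per_level):
        flat.extend([level] * config.events_per_level[level])
    return [lvl for i, lvl in enumerate(flat) if i % config.n_subjects == subject_index]


def _place_event_times(rng: np.random.Generator, n_events: int,
                       config: CohortSimConfig) -> np.ndarray:
    lo = config.edge_margin_s
    hi = config.duration_s - config.edge_margin_s
    times: list[float] = []
    for _ in range(50 * n_events + 50):
        if len(times) >= n_events:
            break
        t = float(rng.uniform(lo, hi))
        if all(abs(t - u) >= config.min_event_spacing_s for u in times):
            times.append(t)
    # snap to the sample grid so labels align with recorded samples
    return np.sort(np.round(np.array(times) * config.fs) / config.fs)


def simulate_subject(config: CohortSimConfig, subject_index: int,
                     ) -> tuple[EdaRecording, list[LabelEvent]]:
    """One subject's recording and its NRS label events, reproducible per
    (config.seed, subject_index)."""
    rng = np.random.default_rng([config.seed % (2 ** 31), subject_index])
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    # tonic: baseline + bounded smooth random walk
    walk = np.cumsum(rng.normal(0.0, 1.0, n))
    walk -= np.linspace(walk[0], walk[-1], n)  # pin ends: bounded excursion
    sd = walk.std()
    tonic = config.tonic_level + (config.tonic_drift_sd / sd * walk if sd > 0 else 0.0)

    levels = levels_for_subject(config, subject_index)
    event_times = _place_event_times(rng, len(levels), config)
    rng.shuffle(levels)
    levels = levels[:len(event_times)]
    events = [LabelEvent(float(ts), int(lvl)) for ts, lvl in zip(event_times, levels)]

    # sudomotor driver: per-event Poisson bursts + sparse background SCRs
    driver = np.zeros(n)
    hw = config.event_half_width_s
    for ev in events:
        cls = merge_pain_levels(ev.nrs)
        lam = config.scr_rate_per_min[cls] / 60.0 * (2 * hw)
        for _ in range(rng.poisson(lam)):
            idx = int(round((ev.timestamp + rng.uniform(-hw, hw)) * config.fs))
            if 0 <= idx < n:
                mean_amp = config.scr_amp_mean[cls]
                mu = np.log(mean_amp) - config.scr_amp_sigma ** 2 / 2
                driver[idx] += rng.lognormal(mu, config.scr_amp_sigma)
    n_bg = rng.poisson(config.background_scr_rate_per_min / 60.0 * config.duration_s)
    for idx in rng.integers(0, n, n_bg):
        mu = np.log(config.scr_amp_mean[0]) - config.scr_amp_sigma ** 2 / 2
        driver[idx] += rng.lognormal(mu, config.scr_amp_sigma)

    kernel = bateman_kernel(config.tau0, config.tau1, config.fs,
                            min(config.duration_s, 30.0))
    phasic = np.convolve(driver, kernel)[:n]

    # motion artifacts: brief biphasic spikes
    artifact = np.zeros(n)
    n_art = rng.poisson(config.artifact_rate_per_min / 60.0 * config.duration_s)
    half = max(1, int(round(0.375 * config.fs)))
    for idx in rng.integers(half, max(half + 1, n - half), max(n_art, 0)):
        amp = rng.uniform(0.5, 2.0)
        artifact[idx - half:idx] += amp
        artifact[idx:idx + half] -= amp

    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
    samples = np.maximum(tonic + phasic + artifact + noise, 1e-3)
    rec = EdaRecording(f"S{subject_index:03d}", 1_600_000_000.0, config.fs, samples)
    events = [LabelEvent(rec.start_time + ev.timestamp, ev.nrs, ev.origin)
              for ev in events]
    return rec, events


def simulate_cohort(config: CohortSimConfig, out_dir: str | Path) -> dict:
    """Write one EDA CSV + label CSV pair per subject, plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "n_subjects": config.n_subjects,
                      "files": [], "config": asdict(config)}
    for i in range(config.n_subjects):
        rec, events = simulate_subject(config, i)
        eda_path = out_dir / f"{rec.subject_id}_eda.csv"
        lbl_path = out_dir / f"{rec.subject_id}_labels.csv"
        write_eda_csv(rec, eda_path)
        write_label_events(events, lbl_path)
        manifest["files"].append({"subject_id": rec.subject_id,
                                  "eda": eda_path.name, "labels": lbl_path.name,
                                  "n_events": len(events)})
    cfg_json = json.dumps(asdict(config), sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("simulated cohort of %d subjects in %s", config.n_subjects, out_dir)
    return manifest
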