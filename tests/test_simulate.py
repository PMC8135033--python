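import json
from collections import Counter

import numpy as np
import pytest

from edapain.io import read_eda_csv, read_label_events
from edapain.labeling import merge_pain_levels
from edapain.simulate import (CohortSimConfig, levels_for_subject,
                              simulate_cohort, simulate_subject)


def _small_cfg(**kw):
    defaults = dict(n_subjects=3, duration_s=300.0, seed=7,
                    events_per_level={0: 3, 2: 3, 4: 3, 7: 3, 10: 3})
    defaults.update(kw)
    return CohortSimConfig(**defaults)


class TestSimulateSubject:
    def test_equal_seeds_identical_output(self):
        cfg = _small_cfg()
        rec_a, ev_a = simulate_subject(cfg, 1)
        rec_b, ev_b = simulate_subject(cfg, 1)
        np.testing.assert_array_equal(rec_a.samples, rec_b.samples)
        assert ev_a == ev_b

    def test_different_subjects_differ(self):
        cfg = _small_cfg()
        rec_a, _ = simulate_subject(cfg, 0)
        rec_b, _ = simulate_subject(cfg, 1)
        assert not np.array_equal(rec_a.samples, rec_b.samples)

    def test_flat_noiseless_config_is_constant(self):
        cfg = _small_cfg(noise_sd=0.0, tonic_drift_sd=0.0,
                         artifact_rate_per_min=0.0,
                         background_scr_rate_per_min=0.0,
                         events_per_level={})
        rec, events = simulate_subject(cfg, 0)
        assert events == []
        np.testing.assert_allclose(rec.samples, cfg.tonic_level, atol=1e-9)

    def test_round_robin_split_covers_all_events(self):
        cfg = _small_cfg()
        all_levels = []
        for i in range(cfg.n_subjects):
            all_levels.extend(levels_for_subject(cfg, i))
        assert Counter(all_levels) == Counter(
            {lvl: n for lvl, n in cfg.events_per_level.items() if n})

    def test_windowed_energy_increases_with_pain_class(self):
        """Planted monotone effect: mean within-window signal variance grows
        with the merged pain class (pooled over subjects)."""
        cfg = _small_cfg(n_subjects=8, duration_s=600.0,
                         artifact_rate_per_min=0.0,  # isolate the SCR effect
                         events_per_level={0: 16, 2: 16, 4: 16, 6: 16, 9: 16})
        by_class: dict[int, list[float]] = {}
        for i in range(cfg.n_subjects):
            rec, events = simulate_subject(cfg, i)
            for ev in events:
                idx = int((ev.timestamp - rec.start_time) * cfg.fs)
                win = rec.samples[max(idx - 11, 0): idx + 11]
                by_class.setdefault(merge_pain_levels(ev.nrs), []).append(win.var())
        means = [np.mean(by_class[c]) for c in sorted(by_class)]
        assert len(means) == 5
        assert all(b > a for a, b in zip(means, means[1:]))


class TestSimulateCohort:
    def test_files_and_manifest(self, tmp_path):
        cfg = _small_cfg()
        manifest = simulate_cohort(cfg, tmp_path)
        assert len(manifest["files"]) == 3
        assert (tmp_path / "manifest.json").exists()
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert on_disk["config_hash"] == manifest["config_hash"]

    def test_label_histogram_matches_config(self, tmp_path):
        cfg = _small_cfg()
        simulate_cohort(cfg, tmp_path)
        counts: Counter = Counter()
        for f in tmp_path.glob("*_labels.csv"):
            counts.update(e.nrs for e in read_label_events(f))
        assert counts == Counter(
            {lvl: n for lvl, n in cfg.events_per_level.items() if n})

    def test_output_parses_losslessly(self, tmp_path):
        cfg = _small_cfg(n_subjects=1)
        simulate_cohort(cfg, tmp_path)
        rec, _ = simulate_subject(cfg, 0)
        back = read_eda_csv(tmp_path / "S000_eda.csv")
        np.testing.assert_array_equal(back.samples, rec.samples)
        assert back.fs == cfg.fs

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortSimConfig(n_subjects=0)
        with pytest.raises(ValueError):
            CohortSimConfig(events_per_level={3: -1})


def test_noiseless_decomposition_recovers_event_times():
    """On a clean simulated signal the recovered sudomotor driver puts mass
    within one sample of each planted SCR."""
    from edapain.decomposition import cvxeda_decompose

    cfg = _small_cfg(n_subjects=1, duration_s=120.0, noise_sd=0.0,
                     tonic_drift_sd=0.0, artifact_rate_per_min=0.0,
                     background_scr_rate_per_min=0.0,
                     scr_rate_per_min={0: 2.0, 1: 6.0, 2: 10.0, 3: 16.0, 4: 60.0},
                     events_per_level={10: 3}, min_event_spacing_s=25.0)
    rec, events = simulate_subject(cfg, 0)
    d = cvxeda_decompose(rec.samples, cfg.fs)
    support = np.flatnonzero(d.driver > 0.25 * d.driver.max())
    for ev in events:
        idx = int(round((ev.timestamp - rec.start_time) * cfg.fs))
        # at least one SCR was planted near the event; driver mass within ±1
        # sample of some planted impulse implies mass near the event window
        assert np.any(np.abs(support - idx) <= cfg.event_half_width_s * cfg.fs + 1)
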