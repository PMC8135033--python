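import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _synthetic_feature_table(rng, n_subjects=6, rows_per_class=8, effect=2.0,
                             classes=(0, 1, 2, 3, 4)):
    """Gaussian feature rows with a per-class mean shift on two features.

    A fast stand-in for an extracted feature table, used by modeling unit
    tests that do not need the signal pipeline.
    """
    from edapain.features import FEATURE_NAMES

    rows = []
    for s in range(n_subjects):
        for cls in classes:
            for _ in range(rows_per_class):
                base = rng.normal(0, 1, len(FEATURE_NAMES))
                base[1] += effect * cls   # "mean" carries the effect
                base[6] += effect * cls   # so does "rms"
                rows.append({"subject_id": f"S{s:03d}",
                             "center_time": float(rng.uniform(0, 1800)),
                             "label": cls,
                             **dict(zip(FEATURE_NAMES, base))})
    return pd.DataFrame(rows)


@pytest.fixture
def feature_table(rng):
    return _synthetic_feature_table(rng)


@pytest.fixture(scope="session")
def cohort_features():
    """Feature table extracted end-to-end from a 10-subject simulated cohort
    with the default (strong, monotone) planted pain effect. Shared across
    tests because the decomposition stage dominates runtime."""
    from edapain.pipeline import extract_subject_features
    from edapain.simulate import CohortSimConfig, simulate_subject

    cfg = CohortSimConfig(n_subjects=10, seed=1)
    tables = []
    for i in range(cfg.n_subjects):
        rec, events = simulate_subject(cfg, i)
        tables.append(extract_subject_features(rec, events))
    return pd.concat(tables, ignore_index=True)
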