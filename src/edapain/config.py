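"""YAML run configuration shared by the CLI commands."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .decomposition import DecompositionParams
from .modeling import ClassifierConfig
from .pipeline import ExtractionConfig
from .preprocess import PreprocessConfig
from .simulate import CohortSimConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    cohort_dir: str = "cohort"
    features_csv: str = "features.csv"
    report_dir: str = "reports"
    seed: int = 0
    simulate: CohortSimConfig = field(default_factory=CohortSimConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; missing sections use defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = _build(CohortSimConfig, raw.pop("simulate", {}))
    clf = _build(ClassifierConfig, raw.pop("classifier", {}))
    ext_raw = raw.pop("extraction", {})
    pre = _build(PreprocessConfig, ext_raw.pop("preprocess", {}))
    dec = _build(DecompositionParams, ext_raw.pop("decomposition", {}))
    ext = _build(ExtractionConfig, {**ext_raw, "preprocess": pre, "decomposition": dec})
    cfg = _build(RunConfig, {**raw, "simulate": sim, "extraction": ext,
                             "classifier": clf})
    # top-level seed flows into sub-configs left at their default
    if cfg.simulate.seed == 0:
        cfg.simulate.seed = cfg.seed
    if cfg.classifier.seed == 0:
        cfg.classifier.seed = cfg.seed
    return cfg
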