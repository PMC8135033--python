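"""Binary pain models: feature selection and leave-one-subject-out evaluation.

Four binary tasks are evaluated — baseline vs each merged pain level (BL vs
PL1..PL4) — with k-nearest-neighbour and random-forest classifiers. All
model choices (feature subset via Gini importance top-k sweep, classifier
hyperparameters) are made inside each training fold by an inner
leave-one-subject-out loop, so the held-out subject never influences the
model that scores it.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

from .features import FEATURE_NAMES, REFERENCE_FEATURES

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "FeatureRanking",
    "CvReport",
    "make_binary_task",
    "gini_importance",
    "select_features_per_fold",
    "consolidate_feature_sets",
    "loso_cross_validate",
    "run_all_pain_models",
    "report_table",
]

MODEL_NAMES = {1: "BLvPL1", 2: "BLvPL2", 3: "BLvPL3", 4: "BLvPL4"}


@dataclass
class ClassifierConfig:
    """Classifier family and hyperparameters.

    ``knn_k`` / ``rf_depth`` of ``None`` mean "search the grid (k 1-20,
    depth 1-10) by inner leave-one-subject-out accuracy on the training
    fold"; an integer pins the value.
    """

    kind: str = "rf"  # rf | knn
    knn_k: int | None = None
    rf_depth: int | None = None
    rf_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "knn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k is not None and not 1 <= self.knn_k <= 20:
            raise ValueError("knn_k must be in 1..20")
        if self.rf_depth is not None and not 1 <= self.rf_depth <= 10:
            raise ValueError("rf_depth must be in 1..10")


@dataclass
class FeatureRanking:
    importance: dict[str, float]
    order: list[str]


@dataclass
class CvReport:
    """Per-fold and averaged leave-one-subject-out results for one task."""

    model: str
    classifier: str
    per_fold_accuracy: dict[str, float]
    mean_accuracy: float
    selected_features: dict[str, list[str]]
    consolidated_features: list[str]
    hyperparameters: dict[str, int | None] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def make_binary_task(dataset: pd.DataFrame, pain_level: int) -> pd.DataFrame:
    """Keep baseline (class 0, negative) and one pain class (positive) rows."""
    if pain_level not in (1, 2, 3, 4):
        raise ValueError(f"pain_level must be 1..4, got {pain_level}")
    present = set(dataset["label"].unique())
    for needed in (0, pain_level):
        if needed not in present:
            raise ValueError(f"class {needed} absent from dataset")
    return dataset[dataset["label"].isin([0, pain_level])].copy()


def _make_classifier(cfg: ClassifierConfig, knn_k: int | None = None,
                     rf_depth: int | None = None):
    if cfg.kind == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k or cfg.knn_k or 5)
    return RandomForestClassifier(n_estimators=cfg.rf_trees,
                                  max_depth=rf_depth or cfg.rf_depth,
                                  random_state=cfg.seed)


def gini_importance(features: pd.DataFrame, labels: np.ndarray,
                    config: ClassifierConfig | None = None) -> FeatureRanking:
    """Mean-decrease-impurity feature ranking from a random-forest fit.

    Each feature's importance is the impurity decrease it produces at its
    split nodes, weighted by node sample fraction and averaged over trees,
    normalized to sum 1. Ties are broken alphabetically so the ranking is
    deterministic given the seed.
    """
    config = config or ClassifierConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("Gini importance needs at least two classes")
    rf = RandomForestClassifier(n_estimators=config.rf_trees,
                                max_depth=config.rf_depth,
                                random_state=config.seed)
    rf.fit(features.to_numpy(), labels)
    imp = dict(zip(features.columns, rf.feature_importances_))
    order = sorted(imp, key=lambda f: (-imp[f], f))
    return FeatureRanking(importance=imp, order=order)


def _inner_loso_accuracy(train: pd.DataFrame, feats: Sequence[str],
                         cfg: ClassifierConfig, knn_k=None, rf_depth=None) -> float:
    """Unweighted-mean LOSO accuracy inside a training fold."""
    accs = []
    for subj in sorted(train["subject_id"].unique()):
        tr = train[train["subject_id"] != subj]
        te = train[train["subject_id"] == subj]
        y_tr = (tr["label"] > 0).astype(int)
        if y_tr.nunique() < 2:
            continue
        clf = _make_classifier(cfg, knn_k=knn_k, rf_depth=rf_depth)
        k_eff = getattr(clf, "n_neighbors", 0)
        if k_eff and k_eff > len(tr):
            continue
        clf.fit(tr[list(feats)].to_numpy(), y_tr)
        pred = clf.predict(te[list(feats)].to_numpy())
        accs.append(float(np.mean(pred == (te["label"] > 0).astype(int))))
    return float(np.mean(accs)) if accs else 0.0


def select_features_per_fold(train: pd.DataFrame,
                             k_range: Iterable[int] = range(2, 12),
                             config: ClassifierConfig | None = None,
                             ) -> tuple[list[str], float]:
    """Top-k feature subset chosen by inner LOSO accuracy on one fold.

    Features are ranked by Gini importance on the whole training fold; each
    top-k prefix (k in 2..11 by default) is scored by inner
    leave-one-subject-out random-forest accuracy; the best k wins, ties
    going to the smaller subset. Returns (subset, inner accuracy).
    """
    config = config or ClassifierConfig()
    feat_cols = [c for c in train.columns if c in FEATURE_NAMES]
    ranking = gini_importance(train[feat_cols], (train["label"] > 0).astype(int), config)
    best: tuple[float, int] | None = None
    best_feats: list[str] = []
    for k in sorted(k_range):
        feats = ranking.order[:k]
        acc = _inner_loso_accuracy(train, feats, config)
        if best is None or acc > best[0] + 1e-12:
            best = (acc, k)
            best_feats = feats
    return best_feats, best[0]


def consolidate_feature_sets(per_fold_subsets: Sequence[Sequence[str]],
                             inner_accuracies: Sequence[float] | None = None,
                             ) -> list[str]:
    """The modal feature subset across folds.

    Ties break by higher mean inner accuracy, then smaller cardinality,
    then lexicographically, so consolidation is deterministic.
    """
    if not per_fold_subsets:
        raise ValueError("no per-fold subsets to consolidate")
    keys = [tuple(sorted(s)) for s in per_fold_subsets]
    counts = Counter(keys)
    if inner_accuracies is None:
        inner_accuracies = [0.0] * len(keys)
    mean_acc: dict[tuple, float] = {}
    for key in counts:
        accs = [a for k, a in zip(keys, inner_accuracies) if k == key]
        mean_acc[key] = float(np.mean(accs))
    best = min(counts, key=lambda k: (-counts[k], -mean_acc[k], len(k), k))
    return list(best)


def _tune_hyperparameter(train: pd.DataFrame, feats: Sequence[str],
                         cfg: ClassifierConfig) -> int:
    """Grid-search k (KNN, 1-20) or depth (RF, 1-10) by inner LOSO accuracy."""
    grid = range(1, 21) if cfg.kind == "knn" else range(1, 11)
    best_val, best_acc = grid[0], -1.0
    for val in grid:
        kwargs = {"knn_k": val} if cfg.kind == "knn" else {"rf_depth": val}
        acc = _inner_loso_accuracy(train, feats, cfg, **kwargs)
        if acc > best_acc + 1e-12:
            best_val, best_acc = val, acc
    return best_val


def loso_cross_validate(dataset: pd.DataFrame, pain_level: int,
                        config: ClassifierConfig | None = None,
                        features: Sequence[str] | str = "select",
                        k_range: Iterable[int] = range(2, 12),
                        return_models: bool = False):
    """Leave-one-subject-out evaluation of one binary pain model.

    One fold per subject; the model — feature subset included when
    ``features == "select"`` — is built from scratch on the remaining
    subjects each fold. Fold accuracy is the proportion of the held-out
    subject's rows classified correctly; the reported accuracy is the
    unweighted mean over folds.
    """
    config = config or ClassifierConfig()
    task = make_binary_task(dataset, pain_level)
    subjects = sorted(task["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")

    per_fold_acc: dict[str, float] = {}
    per_fold_feats: dict[str, list[str]] = {}
    inner_accs: list[float] = []
    hyper: dict[str, int | None] = {}
    models: dict[str, object] = {}
    for subj in subjects:
        train = task[task["subject_id"] != subj]
        test = task[task["subject_id"] == subj]
        y_train = (train["label"] > 0).astype(int)
        if y_train.nunique() < 2:
            raise ValueError(f"training fold for subject {subj} has a single class")
        if features == "select":
            feats, inner = select_features_per_fold(train, k_range, config)
        else:
            feats, inner = list(features), float("nan")
        if (config.kind == "knn" and config.knn_k is None) or \
                (config.kind == "rf" and config.rf_depth is None):
            best = _tune_hyperparameter(train, feats, config)
        else:
            best = config.knn_k if config.kind == "knn" else config.rf_depth
        kwargs = {"knn_k": best} if config.kind == "knn" else {"rf_depth": best}
        clf = _make_classifier(config, **kwargs)
        clf.fit(train[feats].to_numpy(), y_train)
        pred = clf.predict(test[feats].to_numpy())
        per_fold_acc[subj] = float(np.mean(pred == (test["label"] > 0).astype(int)))
        per_fold_feats[subj] = feats
        if not np.isnan(inner):
            inner_accs.append(inner)
        hyper[subj] = int(best)
        if return_models:
            models[subj] = (clf, feats)

    consolidated = consolidate_feature_sets(
        list(per_fold_feats.values()),
        inner_accs if len(inner_accs) == len(per_fold_feats) else None)
    report = CvReport(
        model=MODEL_NAMES[pain_level],
        classifier=config.kind,
        per_fold_accuracy=per_fold_acc,
        mean_accuracy=float(np.mean(list(per_fold_acc.values()))),
        selected_features={s: list(f) for s, f in per_fold_feats.items()},
        consolidated_features=consolidated,
        hyperparameters=hyper,
    )
    logger.info("%s (%s): mean LOSO accuracy %.3f over %d folds",
                report.model, config.kind, report.mean_accuracy, len(subjects))
    if return_models:
        return report, models
    return report


def run_all_pain_models(dataset: pd.DataFrame,
                        config: ClassifierConfig | None = None,
                        mode: str = "select") -> dict[tuple[str, str], CvReport]:
    """Evaluate BL vs PL1..PL4 with both classifier families.

    ``mode="select"`` runs per-fold Gini top-k feature selection;
    ``mode="fixed"`` uses the fixed nine-feature reference set (no peak
    count, no mean).
    """
    base = config or ClassifierConfig()
    features: Sequence[str] | str = "select" if mode == "select" else list(REFERENCE_FEATURES)
    out: dict[tuple[str, str], CvReport] = {}
    for level in (1, 2, 3, 4):
        for kind in ("rf", "knn"):
            cfg = ClassifierConfig(kind=kind, knn_k=base.knn_k, rf_depth=base.rf_depth,
                                   rf_trees=base.rf_trees, seed=base.seed)
            out[(MODEL_NAMES[level], kind)] = loso_cross_validate(
                dataset, level, cfg, features=features)
    return out


def report_table(reports: dict[tuple[str, str], CvReport]) -> str:
    """Plain-text accuracy table (rows BL vs PL1..PL4; columns RF, KNN)."""
    lines = [f"{'Binary classification':<24}{'RF':>8}{'KNN':>8}"]
    for level in (1, 2, 3, 4):
        name = MODEL_NAMES[level]
        rf = reports.get((name, "rf"))
        knn = reports.get((name, "knn"))
        lines.append(f"{'BL vs PL' + str(level):<24}"
                     f"{100 * rf.mean_accuracy if rf else float('nan'):>8.1f}"
                     f"{100 * knn.mean_accuracy if knn else float('nan'):>8.1f}")
    return "\n".join(lines)
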