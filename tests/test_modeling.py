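import numpy as np
import pandas as pd
import pytest

from edapain.features import FEATURE_NAMES, REFERENCE_FEATURES
from edapain.modeling import (ClassifierConfig, consolidate_feature_sets,
                              gini_importance, loso_cross_validate,
                              make_binary_task, run_all_pain_models,
                              select_features_per_fold)

from conftest import _synthetic_feature_table


class TestBinaryTask:
    def test_only_requested_classes_kept(self, feature_table):
        task = make_binary_task(feature_table, 3)
        assert set(task["label"].unique()) == {0, 3}
        for cls in (0, 3):
            assert (task["label"] == cls).sum() == (feature_table["label"] == cls).sum()

    def test_missing_class_named_in_error(self, feature_table):
        no_baseline = feature_table[feature_table["label"] != 0]
        with pytest.raises(ValueError, match="class 0"):
            make_binary_task(no_baseline, 2)

    def test_invalid_level_rejected(self, feature_table):
        with pytest.raises(ValueError):
            make_binary_task(feature_table, 5)


def _planted_matrix(rng, n=80, noise=1e-3):
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(rng.normal(size=(n, 10)),
                     columns=[f"f{i:02d}" for i in range(10)])
    X["f04"] = y + rng.normal(0, noise, n)
    return X, y


class TestGiniImportance:
    def test_planted_feature_ranks_first(self, rng):
        hits = 0
        for seed in range(20):
            X, y = _planted_matrix(rng)
            ranking = gini_importance(X, y, ClassifierConfig(seed=seed))
            hits += ranking.order[0] == "f04"
        assert hits >= 19

    def test_importances_sum_to_one_and_constant_gets_zero(self, rng):
        X, y = _planted_matrix(rng)
        X["f00"] = 1.0
        ranking = gini_importance(X, y)
        assert sum(ranking.importance.values()) == pytest.approx(1.0)
        assert ranking.importance["f00"] == 0.0

    def test_single_class_rejected(self, rng):
        X, _ = _planted_matrix(rng)
        with pytest.raises(ValueError):
            gini_importance(X, np.zeros(len(X)))


class TestFeatureSelection:
    def test_informative_features_recovered(self, rng):
        # two informative features ("mean", "rms" carry the effect)
        hits = 0
        for seed in range(10):
            table = _synthetic_feature_table(np.random.default_rng(seed),
                                             n_subjects=5, rows_per_class=6,
                                             effect=3.0, classes=(0, 4))
            feats, _ = select_features_per_fold(
                table, config=ClassifierConfig(seed=seed, rf_depth=3, rf_trees=50))
            hits += {"mean", "rms"} <= set(feats)
        assert hits >= 9

    def test_full_range_returns_all_features(self, feature_table):
        feats, _ = select_features_per_fold(
            feature_table, k_range=[11],
            config=ClassifierConfig(seed=0, rf_depth=3, rf_trees=20))
        assert sorted(feats) == sorted(FEATURE_NAMES)


class TestConsolidate:
    def test_identical_subsets(self):
        assert consolidate_feature_sets([["a", "b"]] * 3) == ["a", "b"]

    def test_modal_subset_wins(self):
        out = consolidate_feature_sets([["a", "b"], ["a", "b"], ["a", "c"]])
        assert out == ["a", "b"]

    def test_tie_breaks_by_accuracy_then_size_then_lex(self):
        out = consolidate_feature_sets([["a", "b"], ["a", "c"]], [0.5, 0.9])
        assert out == ["a", "c"]
        out = consolidate_feature_sets([["a", "b"], ["c"]], [0.5, 0.5])
        assert out == ["c"]
        out = consolidate_feature_sets([["b"], ["a"]], [0.5, 0.5])
        assert out == ["a"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consolidate_feature_sets([])


class TestLoso:
    def test_separable_features_give_perfect_accuracy(self, rng):
        table = _synthetic_feature_table(rng, n_subjects=4, rows_per_class=6,
                                         effect=50.0, classes=(0, 2))
        rep = loso_cross_validate(table, 2,
                                  ClassifierConfig(kind="knn", knn_k=3),
                                  features=list(REFERENCE_FEATURES))
        assert rep.mean_accuracy == 1.0
        assert rep.mean_accuracy == pytest.approx(
            np.mean(list(rep.per_fold_accuracy.values())))

    def test_folds_partition_subjects(self, feature_table):
        rep = loso_cross_validate(feature_table, 1,
                                  ClassifierConfig(kind="knn", knn_k=5),
                                  features=list(FEATURE_NAMES))
        assert sorted(rep.per_fold_accuracy) == \
            sorted(feature_table["subject_id"].unique())

    def test_trained_models_ignore_held_out_subject(self, rng):
        table = _synthetic_feature_table(rng, n_subjects=4, rows_per_class=6,
                                         effect=2.0, classes=(0, 1))
        cfg = ClassifierConfig(kind="rf", rf_depth=3, rf_trees=25, seed=0)
        _, models = loso_cross_validate(table, 1, cfg, features="select",
                                        return_models=True)
        subj = sorted(table["subject_id"].unique())[0]
        perturbed = table.copy()
        mask = perturbed["subject_id"] == subj
        perturbed.loc[mask, list(FEATURE_NAMES)] += rng.normal(0, 100, (mask.sum(), 11))
        _, models_p = loso_cross_validate(perturbed, 1, cfg, features="select",
                                          return_models=True)
        clf, feats = models[subj]
        clf_p, feats_p = models_p[subj]
        assert feats == feats_p
        orig_rows = table.loc[mask, feats].to_numpy()
        np.testing.assert_array_equal(clf.predict(orig_rows), clf_p.predict(orig_rows))

    def test_identical_seeds_identical_reports(self, rng):
        table = _synthetic_feature_table(rng, n_subjects=4, rows_per_class=5,
                                         effect=1.0, classes=(0, 3))
        cfg = ClassifierConfig(kind="rf", rf_trees=25, seed=3)
        a = loso_cross_validate(table, 3, cfg, features="select")
        b = loso_cross_validate(table, 3, cfg, features="select")
        assert a.to_json() == b.to_json()

    def test_single_subject_rejected(self, rng):
        table = _synthetic_feature_table(rng, n_subjects=1, classes=(0, 1))
        with pytest.raises(ValueError):
            loso_cross_validate(table, 1, features=list(FEATURE_NAMES))

    def test_null_labels_track_majority_rate(self, rng):
        """With labels shuffled within subjects the LOSO accuracy stays near
        the majority-class proportion (calibration, scaled-down replicate)."""
        table = _synthetic_feature_table(rng, n_subjects=5, rows_per_class=6,
                                         effect=2.0, classes=(0, 2))
        task = make_binary_task(table, 2)
        p0 = max((task["label"] == 0).mean(), (task["label"] == 2).mean())
        cfg = ClassifierConfig(kind="rf", rf_depth=3, rf_trees=25, seed=0)
        accs = []
        for rep in range(20):
            shuffled = task.copy()
            shuffled["label"] = shuffled.groupby("subject_id")["label"] \
                .transform(lambda s: s.sample(frac=1, random_state=rep).to_numpy())
            accs.append(loso_cross_validate(shuffled, 2, cfg,
                                            features=list(REFERENCE_FEATURES)).mean_accuracy)
        band = 1.96 * np.sqrt(p0 * (1 - p0) / len(task))
        assert abs(np.mean(accs) - p0) < band


def test_run_all_pain_models_structure(rng):
    table = _synthetic_feature_table(rng, n_subjects=4, rows_per_class=4,
                                     effect=1.5)
    cfg = ClassifierConfig(rf_trees=20, rf_depth=3, knn_k=5, seed=0)
    reports = run_all_pain_models(table, cfg, mode="fixed")
    assert len(reports) == 8
    for rep in reports.values():
        assert 0.0 <= rep.mean_accuracy <= 1.0
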