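"""KNN cross-validation, standardization, and the JVA-style threshold tree."""

import numpy as np
import pandas as pd
import pytest

from vagkit import (
    FEATURE_NAMES,
    compare_classifiers,
    cross_validate,
    default_jva_thresholds,
    jva_tree_classify,
    knn_predict,
    standardize,
)
from vagkit.classify import (
    JvaThresholds,
    load_jva_thresholds_from_text,
    report_from_predictions,
)

POS, NEG = "symptomatic", "asymptomatic"


def gaussian_feature_table(n_per_class, separation=0.0, seed=0):
    """Balanced two-class table with all seven features; classes differ by
    `separation` SDs on every feature."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, len(FEATURE_NAMES)))
    X[:n_per_class] += separation
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    df.insert(0, "subject_id", [f"P{i:04d}" for i in range(len(df))])
    df.insert(1, "group", [POS] * n_per_class + [NEG] * n_per_class)
    df.insert(2, "side", "left")
    df.insert(3, "session", 1)
    return df


class TestStandardize:
    def test_two_point_column(self):
        df = gaussian_feature_table(1).iloc[:2].copy()
        df["ti"] = [0.0, 2.0]
        params = standardize(df, ["ti"])
        assert params.means[0] == pytest.approx(1.0)
        assert params.sds[0] == pytest.approx(np.sqrt(2.0))  # ddof=1

    def test_training_set_becomes_zero_mean_unit_sd(self):
        df = gaussian_feature_table(25, seed=3)
        params = standardize(df)
        Z = params.apply(df)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_feature_dropped_with_warning(self):
        df = gaussian_feature_table(10)
        df["pa"] = 3.14
        with pytest.warns(UserWarning, match="zero-variance"):
            params = standardize(df)
        assert "pa" in params.dropped
        assert "pa" not in params.feature_names


class TestKnnPredict:
    def test_separated_clusters_classified_perfectly(self):
        rng = np.random.default_rng(0)
        train = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(10, 1, (30, 3))])
        y = np.array([NEG] * 30 + [POS] * 30)
        query = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(10, 1, (10, 3))])
        pred = knn_predict(train, y, query, k=10)
        assert list(pred) == [NEG] * 10 + [POS] * 10

    def test_duplicated_training_point_wins(self):
        train = np.vstack([np.zeros((10, 2)), np.ones((5, 2)) * 50])
        y = np.array([POS] * 10 + [NEG] * 5)
        assert knn_predict(train, y, np.zeros((1, 2)), k=10)[0] == POS

    def test_tie_broken_by_nearest_neighbor(self):
        # 5 positives slightly nearer than 5 negatives: 5-5 vote, nearest wins
        train = np.concatenate([np.linspace(1.0, 1.4, 5),
                                np.linspace(2.0, 2.4, 5)])[:, None]
        y = np.array([POS] * 5 + [NEG] * 5)
        assert knn_predict(train, y, [[0.0]], k=10)[0] == POS

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError):
            knn_predict(np.zeros((5, 2)), np.array([POS] * 5), np.zeros((1, 2)), k=10)


class TestCrossValidate:
    def test_fold_sizes_and_stratification(self):
        df = gaussian_feature_table(47, separation=1.0, seed=1)
        rep = cross_validate(df, folds=10, seed=0)
        folds = pd.Series(rep.fold_assignments)
        sizes = folds.value_counts()
        assert sizes.max() - sizes.min() <= 1
        by_class = df.set_index("subject_id")["group"].loc[folds.index]
        per_fold_pos = pd.crosstab(folds, by_class)[POS]
        assert per_fold_pos.max() - per_fold_pos.min() <= 1

    def test_separable_classes_fully_recovered(self):
        df = gaussian_feature_table(20, separation=10.0, seed=2)
        assert cross_validate(df, folds=10, seed=0).acc == 1.0

    def test_deterministic_for_fixed_seed(self):
        df = gaussian_feature_table(20, separation=1.0, seed=3)
        a = cross_validate(df, folds=10, seed=5)
        b = cross_validate(df, folds=10, seed=5)
        assert a == b

    def test_null_labels_score_at_chance(self):
        """Uninformative features: pooled CV accuracy sits at 0.5."""
        accs = []
        for seed in range(50):
            df = gaussian_feature_table(100, separation=0.0, seed=seed)
            accs.append(cross_validate(df, folds=10, seed=seed).acc)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_too_few_samples_per_class_rejected(self):
        df = gaussian_feature_table(5)
        with pytest.raises(ValueError):
            cross_validate(df, folds=10)

    def test_global_standardization_option(self):
        df = gaussian_feature_table(20, separation=3.0, seed=4)
        rep = cross_validate(df, folds=10, seed=0, global_standardize=True)
        assert rep.total == 40


class TestClassificationReport:
    def test_confusion_matrix_conservation_and_rates(self):
        y = np.array([POS] * 6 + [NEG] * 6)
        pred = np.array([POS] * 4 + [NEG] * 2 + [NEG] * 5 + [POS])
        rep = report_from_predictions(y, pred)
        assert rep.total == 12
        assert rep.tpr == pytest.approx(4 / 6)
        assert rep.tnr == pytest.approx(5 / 6)
        assert rep.acc == pytest.approx(9 / 12)

    def test_balanced_accuracy_identity(self):
        """On balanced classes acc = (tpr + tnr) / 2 exactly."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = np.array([POS] * 25 + [NEG] * 25)
            pred = rng.choice([POS, NEG], size=50)
            rep = report_from_predictions(y, pred)
            assert rep.acc == pytest.approx((rep.tpr + rep.tnr) / 2, rel=1e-12)

    def test_all_negative_classifier_structure(self):
        """Predicting everything asymptomatic: TPR 0, TNR 1, ACC 0.5."""
        y = np.array([POS] * 30 + [NEG] * 30)
        rep = report_from_predictions(y, np.array([NEG] * 60))
        assert (rep.tpr, rep.tnr, rep.acc) == (0.0, 1.0, 0.5)


class TestJvaTree:
    def test_all_zero_features_are_asymptomatic(self):
        fv = dict.fromkeys(FEATURE_NAMES, 0.0)
        assert jva_tree_classify(fv) == NEG

    def test_high_energy_low_frequency_click_is_symptomatic(self):
        fv = dict.fromkeys(FEATURE_NAMES, 0.0)
        fv.update(ti=120.0, ib3=90.0, ia3=30.0, ibar=3.0, pa=2.0, pf=150.0, mf=200.0)
        assert jva_tree_classify(fv) == POS

    def test_every_leaf_is_reachable(self):
        tree = default_jva_thresholds()
        paths = tree.paths()
        leaves = {path[-1][0] for path in paths}
        assert leaves == {POS, NEG}
        # construct a witness vector per path and check it lands on that leaf
        for path in paths:
            fv = dict.fromkeys(FEATURE_NAMES, 0.0)
            for name, branch in path[:-1]:
                node = tree.nodes[name]
                t = node["threshold"]
                want_true = branch
                satisfies = {"gt": t + 1, "ge": t, "lt": t - 1, "le": t}
                violates = {"gt": t - 1, "ge": t - 1, "lt": t + 1, "le": t + 1}
                fv[node["feature"]] = (satisfies if want_true else
                                       violates)[node["comparator"]]
            assert jva_tree_classify(fv, tree) == path[-1][0]

    def test_infinite_ibar_exceeds_any_threshold(self):
        fv = dict.fromkeys(FEATURE_NAMES, 0.0)
        fv.update(ti=120.0, ibar=float("inf"))
        assert jva_tree_classify(fv) == POS

    def test_missing_feature_rejected(self):
        tree = default_jva_thresholds()
        with pytest.raises(KeyError):
            jva_tree_classify({"pa": 1.0}, tree)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            JvaThresholds(root="a", nodes={
                "a": {"feature": "ti", "comparator": "gt", "threshold": 1.0,
                      "if_true": "a", "if_false": "asymptomatic"}})

    def test_scale_converts_units(self):
        text = ("scale: 100.0\nroot: r\nnodes:\n  r:\n    feature: ti\n"
                "    comparator: gt\n    threshold: 80.0\n"
                "    if_true: symptomatic\n    if_false: asymptomatic\n")
        tree = load_jva_thresholds_from_text(text)
        fv = dict.fromkeys(FEATURE_NAMES, 0.0)
        fv["ti"] = 1.0  # 1 local unit -> 100 device units > 80
        assert jva_tree_classify(fv, tree) == POS


class TestCompareClassifiers:
    def test_eight_setups_for_standard_configuration(self, small_cohort):
        manifest, recordings = small_cohort
        table = compare_classifiers(manifest, recordings, seed=0)
        assert len(table) == 8
        assert (table["classifier"] == "jva").sum() == 6  # 3 norms x 2 sessions
        assert (table["classifier"] == "knn").sum() == 2  # raw x 2 sessions

    def test_knn_beats_default_jva_on_separated_cohort(self, small_cohort):
        """The default JVA thresholds target another device's units, so the
        adaptive KNN should dominate on a cohort with a clear group effect."""
        manifest, recordings = small_cohort
        table = compare_classifiers(manifest, recordings, seed=0)
        knn_acc = table[table["classifier"] == "knn"]["acc"].mean()
        jva_acc = table[table["classifier"] == "jva"]["acc"].mean()
        assert knn_acc >= jva_acc
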