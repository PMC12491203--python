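"""Classifier harness: feature sets, fold preprocessing, selection,
nested CV, importances, bootstrap AUC and the LDA baseline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gaitfusion.matrix import (
    ALL_FEATURES,
    CYCLOGRAM_FEATURES,
    ENTROPY_FEATURES,
    SPATIOTEMPORAL_FEATURES,
    FeatureMatrix,
)
from gaitfusion.ml import (
    assemble_feature_sets,
    bootstrap_auc,
    compute_importances,
    lda_baseline,
    nested_cv_evaluate,
    preprocess_fold,
    select_top_features,
)

pytestmark = pytest.mark.filterwarnings("ignore::FutureWarning")


def _random_matrix(rng, n_per_group=10, separation=0.0):
    """Feature matrix with optional group separation on every feature."""
    groups = (["Healthy"] * n_per_group + ["KOA"] * n_per_group
              + ["TKA"] * n_per_group)
    n = len(groups)
    shift = np.repeat([0.0, separation, 2 * separation], n_per_group)
    rows = []
    for i in range(n):
        row = {"subject_id": f"S{i:02d}", "group": groups[i],
               "age": 60.0, "sex": "F", "bmi": 25.0, "side_category": "none"}
        row.update({f: float(rng.normal() + shift[i]) for f in ALL_FEATURES})
        rows.append(row)
    return FeatureMatrix.from_rows(rows)


class TestAssembleFeatureSets:
    def test_views_and_fused_union(self, rng):
        views = assemble_feature_sets(_random_matrix(rng))
        assert views["fused"].shape[1] == 13
        assert views["cyclogram"].shape[1] == 10
        assert set(views["entropy"].columns) == {"se_hip", "se_knee", "se_ankle"}
        assert views["spatiotemporal"].shape[1] == 5
        assert list(views["fused"].columns) == (
            list(views["cyclogram"].columns) + list(views["entropy"].columns)
        )
        assert views["fused"].columns.is_unique

    def test_empty_category_errors(self, rng):
        m = _random_matrix(rng)
        m.data.drop(columns=list(ENTROPY_FEATURES), inplace=True)
        with pytest.raises(ValueError, match="entropy"):
            assemble_feature_sets(m)


class TestPreprocessFold:
    def test_median_imputation_from_train_only(self):
        train = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0], "b": [1, 2, 3, 4.0]})
        test = pd.DataFrame({"a": [np.nan], "b": [2.5]})
        tr, te = preprocess_fold(train, test)
        # the imputed train cell equals the train median of the column
        filled = train["a"].fillna(train["a"].median())
        expected = (2.0 - filled.mean()) / filled.std(ddof=0)
        assert te["a"].iloc[0] == pytest.approx(expected)

    def test_train_columns_standardized(self, rng):
        train = pd.DataFrame(rng.normal(5, 3, size=(30, 4)),
                             columns=list("abcd"))
        tr, _ = preprocess_fold(train, train.iloc[:2])
        np.testing.assert_allclose(tr.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(tr.std(ddof=0), 1, atol=1e-12)

    def test_train_mean_maps_to_zero_on_test(self, rng):
        train = pd.DataFrame({"a": rng.normal(size=20)})
        test = pd.DataFrame({"a": [train["a"].mean()]})
        _, te = preprocess_fold(train, test)
        assert te["a"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_leakage_from_test(self, rng):
        train = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        test1 = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        test2 = test1 + 1000.0  # wildly perturbed test data
        tr1, _ = preprocess_fold(train, test1)
        tr2, _ = preprocess_fold(train, test2)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_zero_variance_column_dropped(self, rng):
        train = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        tr, te = preprocess_fold(train, train.iloc[:3])
        assert list(tr.columns) == ["a"]


class TestSelectTopFeatures:
    def test_informative_columns_selected(self, rng):
        n = 60
        y = np.repeat([0, 1, 2], 20)
        X = pd.DataFrame(rng.normal(size=(n, 12)),
                         columns=[f"f{i}" for i in range(12)])
        X["f3"] += 5.0 * y  # 5-SD separations
        X["f7"] += 5.0 * y
        cols = select_top_features(X, y, k=10)
        assert {"f3", "f7"} <= set(cols)
        assert len(cols) == 10

    def test_fewer_columns_than_k_keeps_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = np.repeat([0, 1, 2], 10)
        assert len(select_top_features(X, y, k=10)) == 3

    def test_constant_column_ranks_last(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        X["const"] = 1.0
        y = np.repeat([0, 1, 2], 10)
        cols = select_top_features(X, y, k=3)
        assert "const" not in cols

    def test_single_class_errors(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError, match="two classes"):
            select_top_features(X, np.zeros(10, int), k=1)


class TestNestedCV:
    def test_separable_cohort_high_accuracy_all_models(self, rng):
        m = _random_matrix(rng, n_per_group=24, separation=5.0)
        views = assemble_feature_sets(m)
        for model in ("RF", "SVM", "DT", "KNN"):
            res = nested_cv_evaluate(views["fused"], m.groups, model, seed=0)
            assert res.accuracy >= 0.95, model

    def test_permuted_labels_give_chance_accuracy(self, rng):
        m = _random_matrix(rng, n_per_group=24, separation=5.0)
        views = assemble_feature_sets(m)
        for model in ("DT", "KNN"):
            accs = []
            for rep in range(2):
                y = pd.Series(rng.permutation(m.groups.to_numpy()),
                              index=m.data.index)
                res = nested_cv_evaluate(views["fused"], y, model, seed=rep)
                accs.append(res.accuracy)
            assert abs(np.mean(accs) - 1 / 3) < 0.12, (model, accs)

    def test_bit_identical_reports_under_same_seed(self, rng):
        m = _random_matrix(rng, n_per_group=10, separation=1.0)
        views = assemble_feature_sets(m)
        for model in ("SVM", "DT"):
            a = nested_cv_evaluate(views["fused"], m.groups, model, seed=7)
            b = nested_cv_evaluate(views["fused"], m.groups, model, seed=7)
            assert a.accuracy == b.accuracy
            assert a.chosen_params == b.chosen_params
            pd.testing.assert_frame_equal(a.oof_proba, b.oof_proba)

    def test_outer_folds_are_stratified(self, rng):
        from sklearn.model_selection import StratifiedKFold

        m = _random_matrix(rng, n_per_group=10)
        y = m.groups
        outer = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        proportions = y.value_counts(normalize=True)
        for _, test_idx in outer.split(m.data[list(ALL_FEATURES)], y):
            counts = y.iloc[test_idx].value_counts()
            for g, frac in proportions.items():
                expected = frac * len(test_idx)
                assert abs(counts.get(g, 0) - expected) <= 1

    def test_unknown_model_errors(self, rng):
        m = _random_matrix(rng)
        views = assemble_feature_sets(m)
        with pytest.raises(ValueError, match="RF"):
            nested_cv_evaluate(views["fused"], m.groups, "MLP", seed=0)

    def test_hyperparameters_stay_in_stated_ranges(self, rng):
        m = _random_matrix(rng, n_per_group=10, separation=1.0)
        views = assemble_feature_sets(m)
        res = nested_cv_evaluate(views["entropy"], m.groups, "RF", seed=3)
        for params in res.chosen_params:
            assert 50 <= params["n_estimators"] <= 100
            assert params["max_depth"] in (3, 4, 5)


class TestImportances:
    def test_single_informative_feature_ranks_first(self, rng):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.svm import SVC

        n = 90
        y = np.repeat([0, 1, 2], 30)
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"f{i}" for i in range(6)])
        X["f2"] = X["f2"] + 4.0 * y
        rf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        svm = SVC(kernel="rbf").fit(X, y)
        for model in (rf, svm):
            top = compute_importances(model, X, y, seed=0)
            assert top[0][0] == "f2"

    def test_impurity_importances_normalized(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = (X["f0"] > 0).astype(int)
        dt = DecisionTreeClassifier(max_depth=3, random_state=0).fit(X, y)
        top = compute_importances(dt, X, y, top_k=5)
        scores = [s for _, s in top]
        assert all(s >= 0 for s in scores)
        assert sum(scores) == pytest.approx(1.0)

    def test_unused_feature_has_near_zero_permutation_importance(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        X = pd.DataFrame({"used": rng.normal(size=60),
                          "unused": rng.normal(size=60)})
        y = (X["used"] > 0).astype(int)
        X["unused"] = 0.0 * X["unused"]  # constant: model cannot use it
        knn = KNeighborsClassifier(3).fit(X, y)
        top = dict(compute_importances(knn, X, y, seed=0))
        assert abs(top.get("unused", 0.0)) < 1e-12


class TestBootstrapAUC:
    def test_perfect_separation_degenerate_ci(self, rng):
        m = _random_matrix(rng, n_per_group=12, separation=8.0)
        views = assemble_feature_sets(m)
        res = nested_cv_evaluate(views["fused"], m.groups, "KNN", seed=0)
        out = bootstrap_auc(res, B=100, seed=0)
        assert out["auc_macro"] == pytest.approx(1.0)
        assert out["ci_low"] == pytest.approx(1.0)
        assert out["ci_high"] == pytest.approx(1.0)

    def test_random_predictions_cover_half(self, rng):
        m = _random_matrix(rng, n_per_group=20, separation=0.0)
        views = assemble_feature_sets(m)
        res = nested_cv_evaluate(views["entropy"], m.groups, "KNN", seed=0)
        out = bootstrap_auc(res, B=300, seed=0)
        assert out["ci_low"] <= 0.5 <= out["ci_high"]
        assert abs(out["auc_macro"] - 0.5) < 0.15

    def test_ci_width_shrinks_with_n(self, rng):
        widths = []
        for n_per in (12, 120):
            m = _random_matrix(rng, n_per_group=n_per, separation=1.0)
            views = assemble_feature_sets(m)
            res = nested_cv_evaluate(views["fused"], m.groups, "DT", seed=0)
            out = bootstrap_auc(res, B=200, seed=0)
            widths.append(out["ci_high"] - out["ci_low"])
        assert widths[1] < widths[0]


class TestLDABaseline:
    def test_separable_cohort_near_perfect(self, rng):
        m = _random_matrix(rng, n_per_group=20, separation=5.0)
        views = assemble_feature_sets(m)
        assert lda_baseline(views["fused"], m.groups, seed=0) >= 95.0

    def test_permuted_labels_chance_level(self, rng):
        m = _random_matrix(rng, n_per_group=20, separation=5.0)
        views = assemble_feature_sets(m)
        y = pd.Series(rng.permutation(m.groups.to_numpy()), index=m.data.index)
        assert abs(lda_baseline(views["fused"], y, seed=0) - 33.3) < 15.0

    def test_fused_beats_spatiotemporal_on_default_cohorts(self):
        # direction of the linear-baseline comparison: mean CV accuracy
        # of the fused set exceeds the spatiotemporal set across cohorts
        from gaitfusion.config import RunConfig
        from gaitfusion.pipeline import run_extract
        from gaitfusion.synthetic import default_spec, generate_cohort

        fused, spatio = [], []
        for seed in range(1, 6):
            cohort, _ = generate_cohort(default_spec(seed=seed))
            matrix, _ = run_extract(cohort, RunConfig(seed=seed))
            views = assemble_feature_sets(matrix)
            y = matrix.groups
            fused.append(lda_baseline(views["fused"], y, seed=seed))
            spatio.append(lda_baseline(views["spatiotemporal"], y, seed=seed))
        assert np.mean(fused) > np.mean(spatio)
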