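"""Classifier evaluation under nested stratified cross-validation.

Four feature categories — fused (cyclogram + entropy), cyclogram-only,
entropy-only, spatiotemporal — are each evaluated with four classifiers
(random forest, RBF support vector machine, decision tree, k-nearest
neighbours).  The outer layer is 5-fold stratified cross-validation; inside
each outer training fold the preprocessing (median imputation, Z-score
standardization), ANOVA-F top-k feature selection and a 3-fold
hyperparameter search are fitted on the training data only, so no
information leaks from the held-out fold.  Hyperparameter ranges:
trees 50–100 and depth 3–5 for the forest (random search), C in 0.1–10
with an RBF kernel for the SVM, depth 3–5 with Gini splitting for the
tree, and 3–7 distance-weighted neighbours for KNN.  Class imbalance is
handled by stratification plus inverse-frequency class weights (per-class
penalty multipliers for the SVM).

Metrics are pooled over the held-out folds: accuracy, weighted precision /
recall / F1 and the macro one-vs-rest AUC, with bootstrap percentile
confidence intervals for the AUC.  Everything is reproducible from one
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import randint
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.inspection import permutation_importance
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, RandomizedSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .matrix import FeatureMatrix

logger = logging.getLogger("gaitfusion.ml")

MODEL_NAMES = ("RF", "SVM", "DT", "KNN")
FEATURE_SETS = ("fused", "cyclogram", "entropy", "spatiotemporal")


def assemble_feature_sets(matrix: FeatureMatrix) -> dict[str, pd.DataFrame]:
    """The four category views of the feature matrix.

    fused = cyclogram ∪ entropy (13 columns with the default feature set).
    """
    views: dict[str, pd.DataFrame] = {}
    cyclo = matrix.features_of("cyclogram")
    entro = matrix.features_of("entropy")
    spatio = matrix.features_of("spatiotemporal")
    for name, cols in (
        ("fused", cyclo + entro),
        ("cyclogram", cyclo),
        ("entropy", entro),
        ("spatiotemporal", spatio),
    ):
        if not cols:
            raise ValueError(f"feature category {name!r} is empty")
        views[name] = matrix.view(cols)
    return views


class FoldPreprocessor:
    """Median imputation + Z-score standardization fitted on train only.

    Columns with zero variance on the training fold are dropped (with a
    warning) since they carry no information and break standardization.
    """

    def fit(self, train: pd.DataFrame) -> "FoldPreprocessor":
        if len(train) == 0:
            raise ValueError("empty training fold")
        self.medians_ = train.median()
        filled = train.fillna(self.medians_)
        self.means_ = filled.mean()
        self.sds_ = filled.std(ddof=0)
        keep = self.sds_ > 0
        if not keep.all():
            logger.warning(
                "zero-variance train column(s) dropped: %s",
                list(self.sds_.index[~keep]),
            )
        self.columns_ = list(self.sds_.index[keep])
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        filled = data.fillna(self.medians_)
        out = (filled[self.columns_] - self.means_[self.columns_]) / self.sds_[
            self.columns_
        ]
        return out


def preprocess_fold(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute and standardize with parameters fitted on the train fold."""
    prep = FoldPreprocessor().fit(train)
    return prep.transform(train), prep.transform(test)


def select_top_features(train: pd.DataFrame, y: np.ndarray, k: int) -> list[str]:
    """Columns with the k largest one-way ANOVA F statistics on train.

    Constant columns get F = 0 and rank last; if fewer than k columns
    exist, all are kept.  Ties break by column order for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs at least two classes")
    X = train.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_scores, _ = f_classif(X, y)
    f_scores = np.nan_to_num(f_scores, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-f_scores, kind="stable")
    return [train.columns[i] for i in order[: min(k, train.shape[1])]]


def _make_search(model_name: str, seed: int, inner_folds: int,
                 rf_search_iters: int, rf_search_mode: str):
    inner_cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    if model_name == "RF":
        est = RandomForestClassifier(class_weight="balanced", random_state=seed)
        if rf_search_mode == "random":
            return RandomizedSearchCV(
                est,
                {"n_estimators": randint(50, 101), "max_depth": [3, 4, 5]},
                n_iter=rf_search_iters,
                cv=inner_cv,
                random_state=seed,
                n_jobs=1,
            )
        return GridSearchCV(
            est,
            {"n_estimators": [50, 60, 70, 80, 90, 100], "max_depth": [3, 4, 5]},
            cv=inner_cv,
            n_jobs=1,
        )
    if model_name == "SVM":
        est = SVC(
            kernel="rbf",
            probability=True,
            class_weight="balanced",
            random_state=seed,
        )
        return GridSearchCV(
            est, {"C": [0.1, 0.5, 1.0, 2.0, 5.0, 10.0]}, cv=inner_cv, n_jobs=1
        )
    if model_name == "DT":
        est = DecisionTreeClassifier(
            criterion="gini", class_weight="balanced", random_state=seed
        )
        return GridSearchCV(est, {"max_depth": [3, 4, 5]}, cv=inner_cv, n_jobs=1)
    if model_name == "KNN":
        est = KNeighborsClassifier(weights="distance")
        return GridSearchCV(
            est, {"n_neighbors": [3, 4, 5, 6, 7]}, cv=inner_cv, n_jobs=1
        )
    raise ValueError(
        f"unknown model {model_name!r}; expected one of {list(MODEL_NAMES)}"
    )


@dataclass
class CVResult:
    """Pooled nested-CV outcome for one (model, feature set) pair."""

    model: str
    feature_set: str
    seed: int
    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    auc_macro: float
    chosen_params: list[dict] = field(default_factory=list)
    selected_features: list[list[str]] = field(default_factory=list)
    top_importances: list[tuple[str, float]] = field(default_factory=list)
    oof_proba: pd.DataFrame | None = None  # subjects × classes, pooled
    oof_true: pd.Series | None = None

    def metrics_percent(self) -> dict[str, float]:
        return {
            "accuracy": round(100 * self.accuracy, 2),
            "precision_weighted": round(100 * self.precision_weighted, 2),
            "recall_weighted": round(100 * self.recall_weighted, 2),
            "f1_weighted": round(100 * self.f1_weighted, 2),
            "auc_macro": round(self.auc_macro, 4),
        }


def compute_importances(
    model, X: pd.DataFrame, y: np.ndarray, seed: int = 0, top_k: int = 5
) -> list[tuple[str, float]]:
    """Top-k feature importances of a fitted model.

    Impurity-based for tree models; seeded permutation importance
    (50 shuffles) otherwise.
    """
    if hasattr(model, "feature_importances_"):
        scores = np.asarray(model.feature_importances_, dtype=float)
    else:
        res = permutation_importance(
            model, X, y, n_repeats=50, random_state=seed, n_jobs=1
        )
        scores = res.importances_mean
    order = np.argsort(-scores, kind="stable")[:top_k]
    return [(str(X.columns[i]), float(scores[i])) for i in order]


def nested_cv_evaluate(
    view: pd.DataFrame,
    y: pd.Series,
    model_name: str,
    seed: int = 0,
    n_top_features: int = 10,
    outer_folds: int = 5,
    inner_folds: int = 3,
    rf_search_iters: int = 20,
    rf_search_mode: str = "random",
    importances: bool = False,
) -> CVResult:
    """Nested stratified cross-validation of one model on one view.

    Per outer fold: preprocessing and ANOVA-F selection fit on the outer
    training data, inner grid/random search for hyperparameters, refit on
    the full outer-train, predict the held-out fold.  Metrics are computed
    on the pooled out-of-fold predictions.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {model_name!r}; expected one of {list(MODEL_NAMES)}"
        )
    y = pd.Series(np.asarray(y), index=view.index)
    classes = np.sort(y.unique())
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    oof_pred = pd.Series(index=view.index, dtype=object)
    oof_proba = pd.DataFrame(index=view.index, columns=classes, dtype=float)
    chosen, selected = [], []
    last_model = last_X = last_y = None
    for train_idx, test_idx in outer.split(view, y):
        tr, te = view.iloc[train_idx], view.iloc[test_idx]
        ytr, yte = y.iloc[train_idx], y.iloc[test_idx]
        tr_p, te_p = preprocess_fold(tr, te)
        cols = select_top_features(tr_p, ytr.to_numpy(), n_top_features)
        tr_s, te_s = tr_p[cols], te_p[cols]
        search = _make_search(
            model_name, seed, inner_folds, rf_search_iters, rf_search_mode
        )
        search.fit(tr_s, ytr)
        best = search.best_estimator_
        chosen.append(dict(search.best_params_))
        selected.append(cols)
        oof_pred.iloc[test_idx] = best.predict(te_s)
        proba = best.predict_proba(te_s)
        oof_proba.iloc[test_idx] = proba[:, np.argsort(np.argsort(classes))] \
            if not np.array_equal(best.classes_, classes) else proba
        last_model, last_X, last_y = best, tr_s, ytr.to_numpy()

    y_true = y
    y_hat = oof_pred.astype(y.dtype)
    auc = float(
        roc_auc_score(y_true, oof_proba[classes], multi_class="ovr", average="macro")
    )
    result = CVResult(
        model=model_name,
        feature_set="",
        seed=seed,
        accuracy=float(accuracy_score(y_true, y_hat)),
        precision_weighted=float(
            precision_score(y_true, y_hat, average="weighted", zero_division=0)
        ),
        recall_weighted=float(
            recall_score(y_true, y_hat, average="weighted", zero_division=0)
        ),
        f1_weighted=float(
            f1_score(y_true, y_hat, average="weighted", zero_division=0)
        ),
        auc_macro=auc,
        chosen_params=chosen,
        selected_features=selected,
        oof_proba=oof_proba,
        oof_true=y_true,
    )
    if importances and last_model is not None:
        result.top_importances = compute_importances(
            last_model, last_X, last_y, seed=seed
        )
    return result


def bootstrap_auc(
    result: CVResult, B: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Macro one-vs-rest AUC with a 95% bootstrap percentile CI.

    Subjects are resampled with replacement from the pooled out-of-fold
    probabilities; a resample missing a class is redrawn.
    """
    if result.oof_proba is None or result.oof_true is None:
        raise ValueError("result carries no out-of-fold probabilities")
    proba = result.oof_proba.to_numpy(dtype=float)
    y = result.oof_true.to_numpy()
    classes = np.sort(np.unique(y))
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == len(classes):
                break
        aucs[b] = roc_auc_score(
            y[idx], proba[idx], multi_class="ovr", average="macro"
        )
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return {
        "auc_macro": result.auc_macro,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "B": B,
    }


def lda_baseline(view: pd.DataFrame, y: pd.Series, seed: int = 0,
                 folds: int = 5) -> float:
    """5-fold stratified CV accuracy (%) of linear discriminant analysis."""
    y = pd.Series(np.asarray(y), index=view.index)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    hits = 0
    for train_idx, test_idx in cv.split(view, y):
        tr_p, te_p = preprocess_fold(view.iloc[train_idx], view.iloc[test_idx])
        model = LinearDiscriminantAnalysis().fit(tr_p, y.iloc[train_idx])
        hits += int(np.sum(model.predict(te_p) == y.iloc[test_idx].to_numpy()))
    return round(100.0 * hits / len(y), 2)


def evaluate_all(
    matrix: FeatureMatrix,
    seed: int = 0,
    models: tuple[str, ...] = MODEL_NAMES,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    bootstrap_B: int = 1000,
    importances: bool = True,
    **cv_kwargs,
) -> dict:
    """Full evaluation: models × feature sets, AUC bootstrap, LDA baseline."""
    views = assemble_feature_sets(matrix)
    y = matrix.groups
    report: dict = {"seed": seed, "results": []}
    for fs in feature_sets:
        for model_name in models:
            res = nested_cv_evaluate(
                views[fs], y, model_name, seed=seed,
                importances=importances, **cv_kwargs,
            )
            res.feature_set = fs
            entry = {
                "model": model_name,
                "feature_set": fs,
                **res.metrics_percent(),
                "chosen_params": res.chosen_params,
                "top_importances": res.top_importances,
                "auc_bootstrap": bootstrap_auc(res, B=bootstrap_B, seed=seed),
            }
            report["results"].append(entry)
    report["lda_baseline"] = {
        fs: lda_baseline(views[fs], y, seed=seed) for fs in feature_sets
    }
    return report
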