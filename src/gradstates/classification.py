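"""Multi-classifier evaluation of gradient + dynamic-connectivity features.

Five classifiers (linear SVM, RBF SVM, k-nearest neighbours, random forest,
gradient-boosted trees) are evaluated under leave-one-out and stratified
5-fold cross-validation.  Feature standardisation is fit inside training folds
only; decision scores are pooled across folds into a single ROC/AUC; confusion
-matrix metrics follow the standard definitions

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Feature importance for the linear-margin model is assessed by recursive
feature elimination (drop the smallest-|weight| feature, refit, repeat).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger("gradstates.classification")

CLASSIFIERS = ("linear_svm", "rbf_svm", "knn", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity; undefined ratios are NaN."""
    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": ratio(c.tp, c.tp + c.fp, "precision"),
        "sensitivity": ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": ratio(c.tn, c.tn + c.fp, "specificity"),
    }


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x features with labels and per-feature provenance."""

    data: pd.DataFrame  # index subject_id
    labels: pd.Series  # index subject_id, values group names
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()][0]
            sid = self.data.index[self.data[bad].isna()][0]
            raise ValueError(f"missing feature value: subject {sid}, feature {bad!r}")
        if not self.data.index.equals(self.labels.index):
            raise ValueError("feature rows and labels must share the subject index")


def assemble_features(gradient_scores: pd.DataFrame | None,
                      gradient_clusters: pd.DataFrame | None,
                      dfc_values: pd.DataFrame | None,
                      dfc_stats: pd.DataFrame | None,
                      labels: pd.Series,
                      n_gradient: int = 12, n_dfc: int = 12) -> FeatureTable:
    """Build the classifier input: mean aligned gradient score per selected
    cluster plus the dFC value at each selected edge.

    Clusters come from the permutation-corrected cluster table (significant
    first, then by |peak t|); edges are ranked by |t| with significant edges
    first.  When fewer candidates exist than requested, all are used (logged).
    The default 12 + 12 = 24 features matches the size of the evaluated
    feature set in the motivating analysis.
    """
    cols: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}

    if n_gradient and gradient_clusters is not None and len(gradient_clusters):
        ranked = gradient_clusters.sort_values(
            ["significant", "size"], ascending=False, kind="stable")
        if len(ranked) < n_gradient:
            logger.info("only %d gradient clusters available (requested %d)",
                        len(ranked), n_gradient)
        for _, row in ranked.head(n_gradient).iterrows():
            idx = np.arange(int(row["start"]), int(row["start"]) + int(row["size"]))
            name = f"FG:{row['region']}:c{int(row['cluster_id'])}"
            cols[name] = gradient_scores.iloc[:, idx].mean(axis=1)
            provenance[name] = f"mean gradient score over cluster of {row['size']} voxels"

    if n_dfc and dfc_stats is not None and len(dfc_stats):
        ranked = dfc_stats.copy()
        ranked["abs_t"] = ranked["t"].abs()
        sort_cols = (["significant", "abs_t"] if "significant" in ranked.columns
                     else ["abs_t"])
        ranked = ranked.sort_values(sort_cols, ascending=False, kind="stable")
        if len(ranked) < n_dfc:
            logger.info("only %d dFC edges available (requested %d)", len(ranked), n_dfc)
        for _, row in ranked.head(n_dfc).iterrows():
            edge = row["feature"]
            if edge not in dfc_values.columns:
                raise ValueError(f"dFC value missing for selected edge {edge!r}")
            name = f"dFC:{edge}"
            cols[name] = dfc_values[edge]
            provenance[name] = "windowed-connectivity value at selected edge"

    if not cols:
        raise ValueError("no features selected (no candidates or top_n = 0)")
    data = pd.DataFrame(cols).loc[labels.index]
    for feat in data.columns:
        if data[feat].isna().any():
            sid = data.index[data[feat].isna()][0]
            raise ValueError(f"subject {sid} missing value for feature {feat!r}")
    return FeatureTable(data, labels, provenance)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _make_classifier(name: str, seed: int):
    if name == "linear_svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if name == "rbf_svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=100, max_depth=3,
                                          random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass
class CVResult:
    classifier: str
    scheme: str
    fold_assignment: np.ndarray
    predictions: pd.DataFrame  # subject_id, true, predicted, score
    confusion: ConfusionCounts
    metrics: dict[str, float]
    roc: pd.DataFrame  # fpr, tpr, threshold
    auc: float
    seed: int
    scaler_means: list[np.ndarray] = field(default_factory=list, repr=False)


def _decision_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    clf = model.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def cross_validate(features: FeatureTable, classifier: str = "linear_svm",
                   scheme: str = "loocv", seed: int = 0,
                   positive_class: str = "patient") -> CVResult:
    """Cross-validated evaluation with fold-internal standardisation.

    LOOCV yields exactly n folds; "5fold" is stratified and shuffled with the
    given seed.  Decision scores are pooled over folds for one ROC/AUC.
    """
    X = features.data.to_numpy(float)
    y = (features.labels == positive_class).to_numpy()
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 subjects for cross-validation")
    if scheme == "loocv":
        splitter = LeaveOneOut()
        splits = list(splitter.split(X, y))
    elif scheme in ("5fold", "5-fold"):
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed % (2**31))
        splits = list(splitter.split(X, y))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    fold_of = np.full(n, -1)
    pred = np.zeros(n, bool)
    score = np.zeros(n)
    scaler_means = []
    for f, (tr, te) in enumerate(splits):
        if len(set(y[tr])) < 2:
            raise ValueError(
                f"fold {f} lacks a class in training; refold with a different seed")
        model = Pipeline([
            ("scale", StandardScaler()),
            ("clf", _make_classifier(classifier, seed % (2**31))),
        ]).fit(X[tr], y[tr])
        fold_of[te] = f
        pred[te] = model.predict(X[te])
        score[te] = _decision_scores(model, X[te])
        scaler_means.append(model.named_steps["scale"].mean_.copy())

    c = ConfusionCounts(
        tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()), fn=int((~pred & y).sum()),
    )
    fpr, tpr, thr = roc_curve(y, score)
    auc = float(roc_auc_score(y, score))
    preds = pd.DataFrame({
        "subject_id": features.data.index, "true": y, "predicted": pred,
        "score": score, "fold": fold_of,
    })
    metrics = confusion_metrics(c)
    metrics["auc"] = auc
    return CVResult(classifier, scheme, fold_of, preds, c, metrics,
                    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
                    auc, seed, scaler_means)


def evaluate_all(features: FeatureTable, schemes=("loocv", "5fold"),
                 classifiers=CLASSIFIERS, seed: int = 0) -> dict[tuple[str, str], CVResult]:
    return {(clf, sch): cross_validate(features, clf, sch, seed)
            for clf in classifiers for sch in schemes}


def rank_features(features: FeatureTable, seed: int = 0,
                  method: str = "recursive-elimination",
                  positive_class: str = "patient") -> pd.DataFrame:
    """Feature ranking from the linear-margin model.

    "recursive-elimination" drops the smallest-|weight| feature each round and
    refits; "weight-magnitude" ranks by a single fit's |weight|.  Duplicated
    columns necessarily carry equal weights and end up adjacent (tie order
    follows column order; logged).
    """
    X = StandardScaler().fit_transform(features.data.to_numpy(float))
    y = (features.labels == positive_class).to_numpy()
    names = list(features.data.columns)
    est = SVC(kernel="linear", C=1.0, random_state=seed % (2**31))
    if method == "recursive-elimination":
        rfe = RFE(est, n_features_to_select=1, step=1).fit(X, y)
        rank = rfe.ranking_
    elif method == "weight-magnitude":
        w = np.abs(est.fit(X, y).coef_.ravel())
        rank = np.empty(len(w), int)
        rank[np.argsort(-w, kind="stable")] = np.arange(1, len(w) + 1)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    dup = pd.Series(names).duplicated().any()
    if dup:
        logger.info("duplicated feature names present; ties follow column order")
    return (pd.DataFrame({"feature": names, "rank": rank})
            .sort_values("rank", kind="stable").reset_index(drop=True))
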