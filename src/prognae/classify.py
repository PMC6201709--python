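"""Supervised label transfer: per-omics classifiers trained on the
discovered subtypes.

Features for the linear models (linear-kernel SVM, Gaussian naive Bayes,
logistic regression) are chosen by ANOVA-F backward elimination evaluated
with repeated stratified 10-fold cross-validation; gradient-boosted trees
(XGBoost) skip elimination and rely on split-gain importance.  Per omics
layer the candidate with the highest mean cross-validated AUC becomes the
transfer model, which then predicts subtype membership in cohorts that
carry only that layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import ValidationError
from .subtype import SubtypeAssignment
from .survival import ConcordanceResult, LogRankResult, concordance_index, logrank_two_group
from .types import OmicsMatrix, SurvivalTable

logger = logging.getLogger(__name__)

ALGORITHMS = ("svm", "naive_bayes", "logistic", "xgboost")
#: tie-break order when AUC and accuracy tie: simpler first
_SIMPLICITY = {"logistic": 0, "naive_bayes": 1, "svm": 2, "xgboost": 3}


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algorithm == "xgboost":
        return XGBClassifier(n_estimators=100, max_depth=3, learning_rate=0.1,
                             random_state=seed, verbosity=0, n_jobs=1,
                             eval_metric="logloss")
    raise ValidationError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _decision_scores(est, X) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


@dataclass
class TrainedClassifier:
    """A fitted transfer model plus its selection provenance."""

    algorithm: str
    omics_kind: str
    selected_features: list[str]
    estimator: object
    seed: int
    cv_mean_accuracy: float = float("nan")
    cv_mean_auc: float = float("nan")
    training_auc: float = float("nan")
    cv_trace: pd.DataFrame | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 = G1 (high risk), 0 = G2."""
        return np.asarray(self.estimator.predict(X), dtype=int)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedClassifier":
        return joblib.load(path)


def _aligned_xy(m: OmicsMatrix, labels: SubtypeAssignment):
    order = [s for s in m.sample_ids]
    lab = labels.as_series().reindex(order)
    if lab.isna().any():
        raise ValidationError("matrix contains samples without subtype labels")
    y = (lab.to_numpy() == "G1").astype(int)
    return m.values.T, y  # samples x features


def anova_f_scores(m: OmicsMatrix, labels: SubtypeAssignment) -> pd.Series:
    """One-way ANOVA F statistic between subtypes for every feature."""
    X, y = _aligned_xy(m, labels)
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValidationError("each class needs >= 2 samples for ANOVA F")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_classif(X, y)
    return pd.Series(np.nan_to_num(f, nan=0.0), index=m.feature_ids, name="anova_f")


def _cv_scores(est, X, y, folds, repeats, seed):
    """Mean accuracy and AUC over repeated stratified k-fold CV."""
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    accs, aucs = [], []
    for train_idx, test_idx in cv.split(X, y):
        model = clone(est)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        if len(np.unique(y[test_idx])) == 2:
            aucs.append(roc_auc(_decision_scores(model, X[test_idx]), y[test_idx]))
    return float(np.mean(accs)), float(np.mean(aucs)) if aucs else float("nan")


def backward_elimination_cv(m: OmicsMatrix, labels: SubtypeAssignment,
                            algorithm: str, folds: int = 10, repeats: int = 10,
                            seed: int = 0, start_size: int = 100
                            ) -> tuple[list[str], pd.DataFrame]:
    """ANOVA-F backward elimination.

    Starting from the ``start_size`` top-F features, the lowest-ranked
    feature is dropped one at a time; mean accuracy over repeated
    stratified CV is recorded at each set size, and the size with the
    highest mean accuracy wins (ties go to the smaller set).
    """
    X_all, y = _aligned_xy(m, labels)
    if len(y) < folds:
        raise ValidationError(f"need >= {folds} samples for {folds}-fold CV")
    f_scores = anova_f_scores(m, labels)
    ranked = list(f_scores.sort_values(ascending=False).index[:start_size])
    col = {f: i for i, f in enumerate(m.feature_ids)}
    est = _make_estimator(algorithm, seed)

    rows = []
    best_acc, best_set = -np.inf, None
    current = list(ranked)
    while current:
        Xs = X_all[:, [col[f] for f in current]]
        acc, auc = _cv_scores(est, Xs, y, folds, repeats, seed)
        rows.append({"n_features": len(current), "cv_accuracy": acc, "cv_auc": auc})
        if acc >= best_acc:  # >= so ties prefer the smaller (later) set
            best_acc, best_set = acc, list(current)
        current = current[:-1]  # drop the lowest-F feature
    trace = pd.DataFrame(rows)
    return best_set, trace


def train_final(m: OmicsMatrix, labels: SubtypeAssignment, algorithm: str,
                selected_features: list[str] | None = None,
                seed: int = 0) -> TrainedClassifier:
    """Fit the final model on all training samples.

    For gradient-boosted trees ``selected_features`` may be omitted: the
    model is fit on every feature and its nonzero-importance features are
    reported as selected.
    """
    if selected_features is None:
        if algorithm != "xgboost":
            raise ValidationError("selected_features required for non-tree models")
        selected_features = list(m.feature_ids)
    sub = m.subset_features(selected_features)
    X, y = _aligned_xy(sub, labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    est = _make_estimator(algorithm, seed)
    est.fit(X, y)
    if algorithm == "xgboost":
        imp = est.feature_importances_
        selected_features = [f for f, w in zip(sub.feature_ids, imp) if w > 0]
        # refit on the internally selected features so the stored
        # estimator and its feature list stay consistent at transfer time
        sub = sub.subset_features(selected_features)
        X, _ = _aligned_xy(sub, labels)
        est = _make_estimator(algorithm, seed)
        est.fit(X, y)
    training_auc = roc_auc(_decision_scores(est, X), y)
    return TrainedClassifier(algorithm, m.omics_kind, list(selected_features),
                             est, seed, training_auc=training_auc)


def fit_candidate(m: OmicsMatrix, labels: SubtypeAssignment, algorithm: str,
                  folds: int = 10, repeats: int = 10, seed: int = 0,
                  start_size: int = 100) -> TrainedClassifier:
    """Feature selection + final fit + CV metrics for one algorithm."""
    if algorithm == "xgboost":
        model = train_final(m, labels, algorithm, None, seed)
        X, y = _aligned_xy(m, labels)
        acc, auc = _cv_scores(_make_estimator(algorithm, seed), X, y, folds, repeats, seed)
        model.cv_mean_accuracy, model.cv_mean_auc = acc, auc
        return model
    features, trace = backward_elimination_cv(m, labels, algorithm, folds=folds,
                                              repeats=repeats, seed=seed,
                                              start_size=start_size)
    model = train_final(m, labels, algorithm, features, seed)
    best = trace.loc[trace["n_features"] == len(features)].iloc[0]
    model.cv_mean_accuracy = float(best["cv_accuracy"])
    model.cv_mean_auc = float(best["cv_auc"])
    model.cv_trace = trace
    return model


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve by the Mann–Whitney rank formulation;
    tied scores receive 0.5 credit."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValidationError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def select_best_model(candidates: list[TrainedClassifier]) -> TrainedClassifier:
    """Highest cross-validated AUC wins; ties fall to higher CV accuracy,
    then to the simpler algorithm."""
    if not candidates:
        raise ValidationError("no candidate models")
    return sorted(candidates,
                  key=lambda c: (-c.cv_mean_auc, -c.cv_mean_accuracy,
                                 _SIMPLICITY[c.algorithm]))[0]


def transfer_labels(model: TrainedClassifier, cohort: OmicsMatrix,
                    surv: SurvivalTable
                    ) -> tuple[SubtypeAssignment, dict[str, LogRankResult],
                               dict[str, ConcordanceResult]]:
    """Predict G1/G2 for a cohort with one omics layer and validate the
    prediction prognostically (log-rank and C-index per endpoint).

    Refuses to predict when fewer than 90% of the model's features are
    present in the cohort.
    """
    have = set(cohort.feature_ids)
    missing = [f for f in model.selected_features if f not in have]
    frac = 1.0 - len(missing) / len(model.selected_features)
    if missing and frac < 0.9:
        raise ValidationError(
            f"cohort covers only {frac:.0%} of model features; "
            f"missing e.g. {missing[:10]}")
    if missing:
        raise ValidationError(f"model features absent from cohort: {missing[:10]}")
    X = cohort.subset_features(model.selected_features).values.T
    pred = model.predict(X)
    labels = np.where(pred == 1, "G1", "G2").astype(object)
    assign = SubtypeAssignment(list(cohort.sample_ids), labels, 2, model.seed)
    logrank: dict[str, LogRankResult] = {}
    cindex: dict[str, ConcordanceResult] = {}
    if len(np.unique(labels)) == 2:
        for endpoint in ("efs", "os"):
            time, event = surv.endpoint(endpoint, assign.sample_ids)
            logrank[endpoint] = logrank_two_group(assign.binary(), time, event)
            cindex[endpoint] = concordance_index(pred.astype(float), time, event)
    else:
        logger.warning("transfer produced a single class; prognostic "
                       "validation skipped")
    return assign, logrank, cindex
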