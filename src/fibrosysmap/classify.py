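"""Signature-based sample classification.

Expression values are brought onto a common scale by per-feature Z-scoring
within each dataset, then samples are either (a) clustered with k-means and
the clusters mapped to the known binary labels by the assignment minimizing
misclassifications, or (b) classified with a cross-validated maximum-margin
linear model (linear-kernel SVM), reporting accuracy, sensitivity,
specificity, AUC and the Matthews correlation coefficient.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import ClassificationResult

log = logging.getLogger(__name__)


def zscore_transform(matrix: pd.DataFrame, per_feature: bool = True) -> pd.DataFrame:
    """Standardize to mean 0, sd 1 (n-1 denominator).

    With ``per_feature`` (default) each feature row is standardized across
    samples; otherwise each sample column is standardized across features.
    Constant rows (or columns) cannot be standardized and are dropped with a
    logged warning.
    """
    axis = 1 if per_feature else 0
    if matrix.shape[1] < 2:
        raise ValueError("need >=2 samples to standardize")
    mean = matrix.mean(axis=axis)
    sd = matrix.std(axis=axis, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("dropping %d constant %s", int(constant.sum()),
                    "features" if per_feature else "samples")
    if per_feature:
        kept = matrix.loc[~constant]
        return kept.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)
    kept = matrix.loc[:, ~constant]
    return kept.sub(mean[~constant], axis=1).div(sd[~constant], axis=1)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table.

    ``(tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``; by convention
    the value is 0 when any denominator factor is zero (e.g. a constant
    prediction).
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + tn + fp + fn == 0:
        raise ValueError("all counts zero")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def success_rate_pct(n_total: int, n_misclassified: int) -> float:
    """Success rate as a percentage, rounded to the nearest integer percent
    (displayed with two decimals downstream): 2/6 misclassified -> 67.0."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_misclassified <= n_total:
        raise ValueError("n_misclassified out of range")
    return float(round(100.0 * (1.0 - n_misclassified / n_total)))


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def _restrict_features(matrix: pd.DataFrame, features) -> pd.DataFrame:
    if features is None:
        return matrix
    features = list(features)
    present = [f for f in features if f in matrix.index]
    missing = len(features) - len(present)
    if missing:
        log.warning("%d requested features absent from matrix; dropped", missing)
    if not present:
        raise ValueError("no requested feature present in the matrix")
    return matrix.loc[present]


def kmeans_evaluate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    features=None,
    case_label: str = "IPF",
    k: int = 2,
    restarts: int = 100,
    seed: int = 0,
    study_id: str = "study",
) -> ClassificationResult:
    """Cluster samples with k-means and score clusters against known labels.

    Clusters are mapped to labels by the assignment minimizing the number of
    misclassified samples (for binary labels this is the better of the two
    mappings, so the success rate is never below 50%).
    """
    matrix = _restrict_features(matrix, features)
    y = (labels.loc[matrix.columns] == case_label).to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    if matrix.shape[1] < k:
        raise ValueError("fewer samples than clusters")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    clusters = km.fit_predict(matrix.to_numpy(float).T)

    # map clusters to the two labels minimizing misclassification
    cont = np.zeros((k, 2), dtype=int)
    for c, lab in zip(clusters, y):
        cont[c, lab] += 1
    cost = cont.max() - cont  # maximize matched samples
    if k == 2:
        row, col = linear_sum_assignment(-cont)
        mapping = dict(zip(row, col))
    else:
        # each cluster takes its majority label, ties toward the lower index
        mapping = {c: int(np.argmax(cont[c])) for c in range(k)}
    del cost
    y_pred = np.array([mapping[c] for c in clusters])

    n_mis = int(np.sum(y_pred != y))
    tp, tn, fp, fn = _binary_metrics(y, y_pred)
    n_total = len(y)
    return ClassificationResult(
        study_id=study_id,
        n_total=n_total,
        n_case=int(y.sum()),
        n_control=int(n_total - y.sum()),
        n_misclassified=n_mis,
        success_rate_pct=success_rate_pct(n_total, n_mis),
        accuracy=(tp + tn) / n_total,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        mcc=mcc(tp, tn, fp, fn),
        auc=float("nan"),  # hard cluster assignments have no score to rank
    )


def crossval_classify(
    matrix: pd.DataFrame,
    labels: pd.Series,
    features=None,
    case_label: str = "IPF",
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    C: float = 1.0,
    study_id: str = "study",
) -> pd.DataFrame:
    """Repeated stratified k-fold cross-validation of a linear-kernel SVM.

    Each repeat uses a distinct stratified partition (derived from ``seed``);
    out-of-fold predictions are pooled per repeat.  Returns one row per
    repeat plus a ``mean`` row, with accuracy, sensitivity, specificity,
    AUC (from the SVM decision function) and MCC.
    """
    matrix = _restrict_features(matrix, features)
    y = (labels.loc[matrix.columns] == case_label).to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y)) < folds:
        raise ValueError("need >= folds samples per class")
    X = matrix.to_numpy(float).T

    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed * repeats + rep)
        y_pred = np.empty_like(y)
        score = np.empty(len(y), dtype=float)
        for train, test in skf.split(X, y):
            model = SVC(kernel="linear", C=C)
            model.fit(X[train], y[train])
            y_pred[test] = model.predict(X[test])
            score[test] = model.decision_function(X[test])
        tp, tn, fp, fn = _binary_metrics(y, y_pred)
        rows.append({
            "repeat": rep,
            "accuracy": (tp + tn) / len(y),
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "auc": float(roc_auc_score(y, score)),
            "mcc": mcc(tp, tn, fp, fn),
        })
    out = pd.DataFrame(rows).set_index("repeat")
    out.loc["mean"] = out.mean()
    out.attrs["study_id"] = study_id
    return out
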