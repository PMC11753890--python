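"""Binary-classification metrics and stratified cross-validation.

Metrics: accuracy, sensitivity (recall on the positive class), specificity,
Matthews correlation coefficient (MCC, with the convention that a zero
factor in its denominator yields MCC = 0), ROC AUC (rank/Mann-Whitney with
tie averaging) and AUPR (step-wise average precision, which avoids the
optimism of trapezoidal PR interpolation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Acc/Sen/Spe/MCC from confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any factor
    of the denominator is zero the MCC is reported as 0 and flagged.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    denom_factors = (tp + fp, tp + fn, tn + fp, tn + fn)
    degenerate = 0 in denom_factors
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(
        math.prod(denom_factors)
    )
    return {"Acc": acc, "Sen": sen, "Spe": spe, "MCC": mcc,
            "mcc_degenerate": degenerate}


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for 0/1 labels and predictions."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return tp, tn, fp, fn


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties averaged)."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise average precision."""
    return float(average_precision_score(np.asarray(labels), np.asarray(scores)))


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded stratified fold assignment: per-class counts across folds
    differ by at most one.  Returns the fold index (0..k-1) of each row."""
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ValueError(
                f"class {cls} has fewer than k={k} members; cannot stratify"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = i
    return folds


@dataclass
class EvalReport:
    """Cross-validated evaluation summary (means and per-fold values)."""

    metrics: dict
    per_fold: list = field(default_factory=list)
    folds: np.ndarray | None = None
    seed: int = 0
    aupr_method: str = "average_precision_step"

    def to_json(self) -> str:
        payload = {
            "metrics": self.metrics,
            "per_fold": self.per_fold,
            "seed": self.seed,
            "aupr_method": self.aupr_method,
        }
        return json.dumps(payload, indent=2)


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> dict:
    """All six metrics from probabilities; label rule is strictly p > Th."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores > threshold).astype(int)
    out = confusion_metrics(*confusion_counts(y_true, y_pred))
    out["AUC"] = roc_auc(scores, y_true)
    out["AUPR"] = pr_auc(scores, y_true)
    return out


def cross_validate(estimator, X, y, k: int = 5, seed: int = 0,
                   threshold: float = 0.5) -> EvalReport:
    """Stratified k-fold CV of any fit/predict_proba estimator."""
    from sklearn.base import clone

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    folds = stratified_kfold(y, k=k, seed=seed)
    per_fold = []
    for fold in range(k):
        test = folds == fold
        est = clone(estimator)
        est.fit(X[~test], y[~test])
        scores = est.predict_proba(X[test])[:, 1]
        per_fold.append(evaluate_predictions(y[test], scores, threshold))
    keys = ("Acc", "Sen", "Spe", "MCC", "AUC", "AUPR")
    means = {key: float(np.mean([f[key] for f in per_fold])) for key in keys}
    return EvalReport(metrics=means, per_fold=per_fold, folds=folds, seed=seed)
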