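"""SVM evaluation of a biomarker panel, within and across platforms.

The panel is evaluated three ways, mirroring a standard biomarker
validation ladder: stratified five-fold cross-validation on the full
discovery cohort; a held-out train/test split of the same cohort; and a
cross-platform blind test where the classifier is trained on gene-
averaged, min-max-normalized microarray data and applied to min-max-
normalized RPKM values from an independent RNA-seq cohort.  The
classifier throughout is a radial-basis-function SVM with C = 1 and
gamma = 1/n_features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .diffexpr import ExpressionStudy, TUMOR

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "SVM_PARAMS",
    "average_by_gene",
    "minmax_normalize",
    "crossvalidate_svm",
    "train_test_split_eval",
    "cross_platform_eval",
    "confusion_metrics",
    "auc_from_scores",
]

#: Fixed SVM hyperparameters ("auto" = 1/n_features).
SVM_PARAMS = dict(kernel="rbf", C=1.0, gamma="auto")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with HCC/tumor as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceReport:
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    accuracy: float
    auc: Optional[float] = None


def confusion_metrics(cm: ConfusionMatrix, auc: Optional[float] = None) -> PerformanceReport:
    """Sensitivity, specificity, precision and accuracy from a 2x2 table.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    precision = tp/(tp+fp); accuracy = (tp+tn)/total.  A metric whose
    denominator is zero is reported as None (flagged with a warning).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den, name):
        if den == 0:
            log.warning("%s undefined: zero denominator", name)
            return None
        return num / den

    return PerformanceReport(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        precision=_ratio(cm.tp, cm.tp + cm.fp, "precision"),
        accuracy=(cm.tp + cm.tn) / cm.total,
        auc=auc,
    )


def auc_from_scores(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Rank-based (Mann-Whitney) AUC; ties counted half.

    AUC = [sum of positive-class ranks - n_pos(n_pos+1)/2] / (n_pos*n_neg)
    using midranks, which equals the probability a random tumor sample
    scores above a random normal sample (+ half the tie probability).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([lab == TUMOR for lab in labels])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Matrix preparation


def average_by_gene(study: ExpressionStudy, probe_to_gene: Mapping[str, str]) -> ExpressionStudy:
    """Collapse probe rows to gene rows by per-sample arithmetic mean."""
    unmapped = [p for p in study.feature_ids if p not in probe_to_gene]
    if unmapped:
        raise KeyError(f"probes with no gene mapping: {unmapped}")
    df = study.to_frame()
    genes = [probe_to_gene[p] for p in study.feature_ids]
    collapsed = df.groupby(pd.Index(genes, name="gene"), sort=False).mean()
    return ExpressionStudy(
        list(collapsed.index), list(study.sample_ids), collapsed.to_numpy(),
        list(study.groups), study.platform,
    )


def minmax_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Per-feature min-max scaling to [0, 1] across this study's samples.

    y = (x - min)/(max - min) row-wise; constant rows map to 0.5 with a
    warning since the transform is undefined there.
    """
    v = study.values
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    if flat.any():
        log.warning("%d constant features set to 0.5 under min-max", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span == 0, 0.5, (v - lo) / span)
    return ExpressionStudy(
        list(study.feature_ids), list(study.sample_ids), out,
        list(study.groups), study.platform,
    )


def _xy(study: ExpressionStudy):
    return study.values.T, np.asarray([g == TUMOR for g in study.groups], dtype=int)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# Evaluation ladders


def crossvalidate_svm(
    study: ExpressionStudy, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, ConfusionMatrix, PerformanceReport]:
    """Stratified k-fold out-of-fold predictions with an RBF SVM.

    Every sample is predicted exactly once by a model not trained on its
    fold; metrics and AUC are computed from the pooled out-of-fold
    predictions/decision scores.  Deterministic for a fixed seed.
    """
    X, y = _xy(study)
    if min((y == 1).sum(), (y == 0).sum()) < k:
        raise ValueError(f"need >= {k} samples per class for {k}-fold stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    score = np.empty(len(y), dtype=float)
    for tr, te in skf.split(X, y):
        clf = SVC(**SVM_PARAMS).fit(X[tr], y[tr])
        pred[te] = clf.predict(X[te])
        score[te] = clf.decision_function(X[te])
    cm = _confusion(y, pred)
    report = confusion_metrics(cm, auc=auc_from_scores(score, study.groups))
    return pred, score, cm, report


def train_test_split_eval(
    study: ExpressionStudy, train_per_group: int = 8, seed: int = 0
) -> dict[str, tuple[ConfusionMatrix, PerformanceReport]]:
    """Seeded stratified split (train_per_group per class) + blind test.

    Reproduces an 8+8 / 8+8 design on a 16-vs-16 cohort: the SVM is
    fitted on the training half only and applied once to the held-out
    half.  Returns reports for both halves (training = resubstitution).
    """
    X, y = _xy(study)
    rng = np.random.default_rng(seed)
    train_idx = []
    for cls in (1, 0):
        members = np.flatnonzero(y == cls)
        if len(members) < train_per_group + 1:
            raise ValueError("not enough samples per class for the requested split")
        train_idx.extend(rng.choice(members, size=train_per_group, replace=False))
    train_mask = np.zeros(len(y), dtype=bool)
    train_mask[train_idx] = True

    clf = SVC(**SVM_PARAMS).fit(X[train_mask], y[train_mask])
    out = {}
    for name, mask in (("training", train_mask), ("testing", ~train_mask)):
        pred = clf.predict(X[mask])
        score = clf.decision_function(X[mask])
        cm = _confusion(y[mask], pred)
        labels = [g for g, m in zip(study.groups, mask) if m]
        out[name] = (cm, confusion_metrics(cm, auc=auc_from_scores(score, labels)))
    return out


def cross_platform_eval(
    train_study: ExpressionStudy,
    test_study: ExpressionStudy,
    genes: Sequence[str],
    seed: int = 0,
    k: int = 5,
) -> dict:
    """Train on one platform, test blind on another, over a shared panel.

    Both studies are restricted to ``genes`` and min-max normalized
    independently (each platform with its own per-feature min/max, so no
    test information reaches training).  The SVM is cross-validated on
    the training study for reporting, then refitted on all training
    samples and applied once to the blind test study.
    """
    if not len(genes):
        raise ValueError("shared gene panel is empty")
    missing = [g for g in genes if g not in test_study.feature_ids]
    if missing:
        raise KeyError(f"genes missing from test study: {missing}")
    tr = minmax_normalize(train_study.subset(genes))
    te = minmax_normalize(test_study.subset(genes))

    _, _, cv_cm, cv_report = crossvalidate_svm(tr, k=k, seed=seed)

    Xtr, ytr = _xy(tr)
    Xte, yte = _xy(te)
    clf = SVC(**SVM_PARAMS).fit(Xtr, ytr)
    pred = clf.predict(Xte)
    score = clf.decision_function(Xte)
    cm = _confusion(yte, pred)
    report = confusion_metrics(cm, auc=auc_from_scores(score, te.groups))
    return {
        "train_cv": (cv_cm, cv_report),
        "blind_test": (cm, report),
        "genes": list(genes),
        "svm_params": dict(SVM_PARAMS),
    }

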