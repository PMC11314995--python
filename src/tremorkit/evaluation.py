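"""Cross-validated evaluation: confusion metrics, ROC/PRC curves, fold reports.

Performance is assessed with stratified 5-fold cross-validation (80/20
train/test splits preserving the class proportions in each fold). The
confusion-count metrics are computed from first principles::

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

with the convention that a 0/0 ratio is reported as 0 (and logged).
ROC curves use trapezoidal area; precision-recall curves use step
interpolation (average precision). Rule-based pipelines emit degenerate
{0, 1} scores and therefore no curves by default; the trainable spectral
pipelines get per-fold and mean +/- SD curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from ._errors import DataError
from .estimators import labels_to_int, make_detector

logger = logging.getLogger(__name__)

METRIC_NAMES = ("f1", "accuracy", "precision", "recall", "specificity")


@dataclass
class ConfusionCounts:
    """Binary confusion counts (positive class = tremor present)."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Confusion metrics for one evaluation (typically one CV fold)."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auroc: float | None = None
    auprc: float | None = None
    fold_id: int | None = None
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        if self.auroc is not None:
            d["auroc"] = self.auroc
        if self.auprc is not None:
            d["auprc"] = self.auprc
        return d


@dataclass
class CurveSet:
    """ROC and PRC points with their areas, for one fold."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    precision: np.ndarray
    recall: np.ndarray
    auprc: float


@dataclass
class CVResult:
    """Per-fold metrics plus mean and sample SD (n-1) across folds."""

    pipeline_id: str
    folds: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    curves: list[CurveSet] = field(default_factory=list)
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "pipeline": self.pipeline_id,
            "k": len(self.folds),
            "seed": self.seed,
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean,
            "sd": self.sd,
        }


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per record).

    Each test fold's class counts are within one record of proportional.
    """
    y = labels_to_int(labels)
    if len(y) < k:
        raise DataError(f"need at least k={k} records, got {len(y)}")
    n_pos = int(y.sum())
    if n_pos < k or (len(y) - n_pos) < k:
        raise DataError(
            f"need at least k={k} records of each class (got {n_pos} positive, "
            f"{len(y) - n_pos} negative)"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Count TP/FP/TN/FN (positive class = present = 1)."""
    yt = labels_to_int(labels_true)
    yp = labels_to_int(labels_pred)
    if yt.shape != yp.shape:
        raise DataError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s; reporting 0 by convention", name)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    fold_id: int | None = None,
    specificity_as_printed: bool = False,
) -> MetricsReport:
    """Confusion metrics from counts.

    ``specificity_as_printed`` switches the specificity denominator from the
    standard TN+FP to TN+FN for auditing against sources that print the
    latter form.
    """
    c = counts
    if c.total == 0:
        raise DataError("cannot compute metrics from empty counts")
    precision = _ratio(c.TP, c.TP + c.FP, "precision")
    recall = _ratio(c.TP, c.TP + c.FN, "recall")
    spec_den = (c.TN + c.FN) if specificity_as_printed else (c.TN + c.FP)
    specificity = _ratio(c.TN, spec_den, "specificity")
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    )
    return MetricsReport(
        accuracy=(c.TP + c.TN) / c.total,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        fold_id=fold_id,
        counts=c,
    )


def roc_pr_curves(scores, labels_true) -> CurveSet:
    """ROC and precision-recall curves with trapezoidal / step areas."""
    y = labels_to_int(labels_true)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise DataError("ROC/PRC require both classes in the truth labels")
    fpr, tpr, _ = roc_curve(y, s)
    auroc = float(np.trapezoid(tpr, fpr))
    prec, rec, _ = precision_recall_curve(y, s)
    auprc = float(average_precision_score(y, s))
    return CurveSet(fpr=fpr, tpr=tpr, auroc=auroc, precision=prec, recall=rec, auprc=auprc)


def mean_roc_curve(
    curves: list[CurveSet], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertically averaged ROC on a common FPR grid: (grid, mean TPR, SD)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    return grid, tprs.mean(axis=0), tprs.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(n_grid)


def cross_validate(
    pipeline_id: str,
    records,
    labels,
    k: int = 5,
    seed: int = 0,
    emit_curves: bool | None = None,
    specificity_as_printed: bool = False,
) -> CVResult:
    """Stratified k-fold evaluation of one pipeline on labeled recordings.

    Features are extracted once for all records (extraction is unsupervised,
    so no information leaks across folds); the classifier is refit per fold
    — a no-op for the rule pipelines, whose per-fold variation comes only
    from fold membership. Curves are emitted for the trainable spectral
    pipelines by default (rule pipelines have no operating range).
    """
    y = labels_to_int(labels)
    if len(records) != len(y):
        raise DataError("records and labels must have equal length")
    if emit_curves is None:
        emit_curves = pipeline_id.lower() in ("b1", "b2")
    pipeline = make_detector(pipeline_id, seed=seed)
    features = pipeline.named_steps["features"].fit(records).transform(records)
    base_clf = pipeline.named_steps["clf"]

    assignment = stratified_kfold(y, k=k, seed=seed)
    folds: list[MetricsReport] = []
    curves: list[CurveSet] = []
    for fold in range(k):
        test = assignment == fold
        train = ~test
        clf = clone(base_clf)
        clf.fit(features[train], y[train])
        pred = clf.predict(features[test])
        report = compute_metrics(
            confusion(y[test], pred),
            fold_id=fold,
            specificity_as_printed=specificity_as_printed,
        )
        if emit_curves:
            scores = clf.predict_proba(features[test])[:, 1]
            cs = roc_pr_curves(scores, y[test])
            report.auroc = cs.auroc
            report.auprc = cs.auprc
            curves.append(cs)
        folds.append(report)

    keys = list(METRIC_NAMES) + (["auroc", "auprc"] if emit_curves else [])
    mean = {m: float(np.mean([getattr(f, m) for f in folds])) for m in keys}
    sd = {m: float(np.std([getattr(f, m) for f in folds], ddof=1)) for m in keys}
    return CVResult(
        pipeline_id=pipeline_id, folds=folds, mean=mean, sd=sd, curves=curves, seed=seed
    )


def evaluate_all(
    records, labels, pipeline_ids=("a1r", "a2r", "a1s", "a2s", "b1", "b2"),
    k: int = 5, seed: int = 0,
) -> dict[str, CVResult]:
    """Cross-validate several pipelines on the same dataset and folds."""
    return {
        pid: cross_validate(pid, records, labels, k=k, seed=seed) for pid in pipeline_ids
    }
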