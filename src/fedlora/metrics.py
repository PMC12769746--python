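"""Confusion-matrix-derived evaluation metrics and micro-averaged curves.

Accuracy, one-vs-rest precision/recall/F1 (macro and micro), Cohen's
kappa, Matthews correlation (binary formula and its multiclass
generalization, which coincide at C=2) and micro-averaged ROC / PR
curves with AUC / average precision. Curve construction delegates to
scikit-learn; the chance-corrected statistics are computed from their
closed forms and cross-checked against scikit-learn in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int):
        """(TP, FP, FN, TN) for class ``c``."""
        m = self.counts
        tp = int(m[c, c])
        fn = int(m[c].sum() - tp)
        fp = int(m[:, c].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fp, fn, tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    precision_micro: float
    recall_micro: float
    f1_micro: float
    kappa: float
    mcc: float
    p_observed: float
    p_chance: float
    roc_auc_micro: float | None = None
    average_precision_micro: float | None = None
    zero_division_classes: tuple[int, ...] = ()

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def confusion_matrix(y_true, y_pred, n_classes: int,
                     class_names=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for arr, nm in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{nm} contains labels outside [0, {n_classes})")
    counts = _skm.confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(counts, tuple(class_names) if class_names else None)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Macro and micro one-vs-rest metrics; per-class rates with a zero
    denominator are reported as 0 and flagged."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    c = cm.n_classes
    precisions, recalls, f1s = [], [], []
    flagged: list[int] = []
    tp_sum = fp_sum = fn_sum = 0
    for k in range(c):
        tp, fp, fn, _ = cm.one_vs_rest(k)
        tp_sum, fp_sum, fn_sum = tp_sum + tp, fp_sum + fp, fn_sum + fn
        p, z1 = _safe_div(tp, tp + fp)
        r, z2 = _safe_div(tp, tp + fn)
        f, z3 = _safe_div(2 * p * r, p + r)
        if z1 or z2 or z3:
            flagged.append(k)
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    if flagged:
        warnings.warn(f"zero denominator for class(es) {flagged}; rate set to 0",
                      stacklevel=2)
    p_micro, _ = _safe_div(tp_sum, tp_sum + fp_sum)
    r_micro, _ = _safe_div(tp_sum, tp_sum + fn_sum)
    f_micro, _ = _safe_div(2 * p_micro * r_micro, p_micro + r_micro)
    acc = float(np.trace(cm.counts) / cm.total)
    try:
        po, pe, kap = _kappa_terms(cm)
    except ZeroDivisionError:
        # single-cell matrix: chance agreement is 1, kappa undefined;
        # report 0 so reports on degenerate client shards stay finite
        po, pe, kap = acc, 1.0, 0.0
        warnings.warn("chance agreement is 1; kappa reported as 0", stacklevel=2)
    return MetricsReport(
        accuracy=acc,
        precision_macro=float(np.mean(precisions)),
        recall_macro=float(np.mean(recalls)),
        f1_macro=float(np.mean(f1s)),
        precision_micro=float(p_micro),
        recall_micro=float(r_micro),
        f1_micro=float(f_micro),
        kappa=kap,
        mcc=mcc(cm),
        p_observed=po,
        p_chance=pe,
        zero_division_classes=tuple(flagged),
    )


def _kappa_terms(cm: ConfusionMatrix):
    n = cm.total
    po = float(np.trace(cm.counts) / n)
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    pe = float((rows * cols).sum() / n**2)
    if pe >= 1.0:
        raise ZeroDivisionError("chance agreement is 1; kappa undefined")
    return po, pe, (po - pe) / (1.0 - pe)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """(p_o - p_e) / (1 - p_e) with p_o = trace/total and
    p_e = sum_c row_c * col_c / total^2."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return _kappa_terms(cm)[2]


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation; generalized multiclass form

        (n * trace - sum_k row_k col_k) /
        sqrt((n^2 - sum row^2)(n^2 - sum col^2))

    which reduces to the familiar binary TP/TN/FP/FN formula at C=2.
    A zero denominator yields 0 by convention.
    """
    m = cm.counts.astype(np.float64)
    n = m.sum()
    if n == 0:
        raise ValueError("confusion matrix is empty")
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    num = n * np.trace(m) - rows @ cols
    den = np.sqrt(n**2 - rows @ rows) * np.sqrt(n**2 - cols @ cols)
    if den == 0:
        return 0.0
    return float(num / den)


def mcc_binary(tp: int, tn: int, fp: int, fn: int) -> float:
    """Binary formula (TP*TN - FP*FN) / sqrt of the four marginal products."""
    num = tp * tn - fp * fn
    den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        return 0.0
    return float(num / den)


# ---------------------------------------------------------------------------
# Micro-averaged curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurvePoints:
    """Ordered curve points plus the area underneath."""

    x: np.ndarray
    y: np.ndarray
    area: float
    thresholds: np.ndarray | None = None
    kind: str = "roc"


def micro_curves(y_true, scores) -> tuple[CurvePoints, CurvePoints]:
    """Micro-averaged ROC and PR curves.

    ``y_true`` is either integer labels or a one-hot matrix; ``scores`` is
    the (n, C) class-score matrix. The C one-vs-rest problems are
    flattened into a single binary problem; AUC uses trapezoid
    integration over unique thresholds and AP the uninterpolated
    step-function area.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_samples, n_classes)")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y_true = np.asarray(y_true)
    if y_true.ndim == 1:
        onehot = np.zeros_like(scores, dtype=int)
        onehot[np.arange(len(y_true)), y_true.astype(int)] = 1
    else:
        onehot = y_true.astype(int)
        if not np.all(onehot.sum(axis=1) == 1):
            raise ValueError("each row must have exactly one positive label")
    flat_y = onehot.ravel()
    flat_s = scores.ravel()
    if flat_y.min() == flat_y.max():
        raise ValueError("ROC undefined for single-class ground truth")
    fpr, tpr, roc_thr = _skm.roc_curve(flat_y, flat_s)
    roc = CurvePoints(fpr, tpr, float(_skm.auc(fpr, tpr)), roc_thr, "roc")
    prec, rec, pr_thr = _skm.precision_recall_curve(flat_y, flat_s)
    ap = float(_skm.average_precision_score(flat_y, flat_s))
    pr = CurvePoints(rec, prec, ap, pr_thr, "pr")
    return roc, pr


def pooled_equals_summed_micro(cms: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Sum per-client confusion matrices into the aggregate matrix (micro
    metrics of the sum equal those of pooled predictions)."""
    if not cms:
        raise ValueError("no matrices to aggregate")
    total = np.sum([c.counts for c in cms], axis=0)
    return ConfusionMatrix(total, cms[0].class_names)
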