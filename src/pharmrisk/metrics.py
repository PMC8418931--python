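"""Multiclass evaluation: confusion matrix, per-class and averaged
precision/recall/F1, accuracy, and one-vs-rest ROC/AUC.

All metrics derive from the confusion matrix C with rows = true labels and
columns = predicted labels.  For each class c (one-vs-rest):

    TP = C[c, c]            FP = column c minus TP
    FN = row c minus TP     TN = everything else

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2 * P * R / (P + R)          accuracy = trace(C) / n

Macro averages are unweighted class means (macro-F1 as the mean of
per-class F1; the alternative harmonic combination of macro-P and macro-R
is also reported, as ``macro_f1_harmonic``).  Weighted averages use true
class sizes as weights — which makes weighted recall identical to accuracy.
ROC curves are built per class by sweeping a threshold over that class's
score, and AUC is the trapezoidal area; the macro AUC is the unweighted
class mean.  Empty denominators yield a 0 metric and are flagged in the
report's ``warnings``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ShapeError

__all__ = [
    "EvaluationReport",
    "confusion_matrix",
    "class_metrics",
    "accuracy",
    "macro_average",
    "weighted_average",
    "roc_auc",
    "evaluate",
]

CLASSES = (0, 1, 2)


def confusion_matrix(y_true, y_pred, classes=CLASSES) -> np.ndarray:
    """Counts[t, p] of samples with true class t predicted as p."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ShapeError("true and predicted label vectors differ in length")
    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[pos[t], pos[p]] += 1
    return cm


def class_metrics(cm: np.ndarray, c: int) -> tuple[float, float, float]:
    """One-vs-rest (precision, recall, F1) for class index c."""
    tp = float(cm[c, c])
    fp = float(cm[:, c].sum() - tp)
    fn = float(cm[c, :].sum() - tp)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def accuracy(cm: np.ndarray) -> float:
    total = cm.sum()
    return float(np.trace(cm) / total) if total else 0.0


def macro_average(per_class: list[tuple[float, float, float]]) -> dict[str, float]:
    """Unweighted class means; both macro-F1 conventions are returned."""
    p = float(np.mean([m[0] for m in per_class]))
    r = float(np.mean([m[1] for m in per_class]))
    f1_mean = float(np.mean([m[2] for m in per_class]))
    f1_harmonic = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return {
        "precision": p,
        "recall": r,
        "f1": f1_mean,
        "f1_harmonic": float(f1_harmonic),
    }


def weighted_average(
    per_class: list[tuple[float, float, float]], class_sizes
) -> dict[str, float]:
    """Class-size-weighted means of precision/recall/F1."""
    w = np.asarray(class_sizes, dtype=float)
    w = w / w.sum()
    return {
        "precision": float(np.dot(w, [m[0] for m in per_class])),
        "recall": float(np.dot(w, [m[1] for m in per_class])),
        "f1": float(np.dot(w, [m[2] for m in per_class])),
    }


def _binary_roc(y_pos: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points by threshold sweep and trapezoidal AUC for one class."""
    order = np.argsort(-score, kind="stable")
    y = y_pos[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    # cumulative TP/FP at each distinct threshold
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.nonzero(np.diff(score[order], append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class EvaluationReport:
    confusion: np.ndarray
    per_class: dict[int, dict[str, float]]
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]
    roc: dict[int, dict[str, list[float]]] = field(default_factory=dict)
    auc_per_class: dict[int, float] = field(default_factory=dict)
    macro_auc: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {str(c): m for c, m in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro": self.macro,
            "weighted": self.weighted,
            "auc_per_class": {str(c): a for c, a in self.auc_per_class.items()},
            "macro_auc": self.macro_auc,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        lines = ["label  precision  recall  f1"]
        for c, m in self.per_class.items():
            lines.append(
                f"{c:>5}  {m['precision']:>9.2f}  {m['recall']:>6.2f}  {m['f1']:.2f}"
            )
        lines.append(
            f"macro  {self.macro['precision']:>9.2f}  {self.macro['recall']:>6.2f}  "
            f"{self.macro['f1']:.2f}"
        )
        lines.append(
            f"wavg   {self.weighted['precision']:>9.2f}  {self.weighted['recall']:>6.2f}  "
            f"{self.weighted['f1']:.2f}"
        )
        lines.append(f"accuracy {100 * self.accuracy:.2f}%")
        if self.macro_auc is not None:
            lines.append(f"macro AUC {self.macro_auc:.2f}")
        return "\n".join(lines)


def roc_auc(y_true, scores, classes=CLASSES) -> tuple[dict, dict, float, list[str]]:
    """One-vs-rest ROC points and AUC per class plus the macro AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    warnings: list[str] = []
    roc: dict[int, dict[str, list[float]]] = {}
    aucs: dict[int, float] = {}
    for i, c in enumerate(classes):
        y_pos = (y_true == c).astype(int)
        s = scores[:, i]
        if np.all(s == s[0]):
            warnings.append(f"class {c}: constant scores, degenerate ROC (AUC 0.5)")
            roc[c] = {"fpr": [0.0, 1.0], "tpr": [0.0, 1.0]}
            aucs[c] = 0.5
            continue
        fpr, tpr, auc = _binary_roc(y_pos, s)
        roc[c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
        aucs[c] = auc
        if auc < 0.5:
            warnings.append(f"class {c}: AUC {auc:.3f} below chance")
    macro_auc = float(np.mean(list(aucs.values())))
    return roc, aucs, macro_auc, warnings


def evaluate(y_true, y_pred, scores=None, classes=CLASSES) -> EvaluationReport:
    """Assemble the full report from labels and (optionally) class scores."""
    cm = confusion_matrix(y_true, y_pred, classes)
    per = [class_metrics(cm, i) for i in range(len(classes))]
    macro = macro_average(per)
    sizes = cm.sum(axis=1)
    weighted = weighted_average(per, sizes)
    report = EvaluationReport(
        confusion=cm,
        per_class={
            c: {"precision": p, "recall": r, "f1": f}
            for c, (p, r, f) in zip(classes, per)
        },
        accuracy=accuracy(cm),
        macro=macro,
        weighted=weighted,
    )
    for i, c in enumerate(classes):
        tp_fp = cm[:, i].sum()
        if tp_fp == 0:
            report.warnings.append(f"class {c}: never predicted (precision set to 0)")
    if scores is not None:
        roc, aucs, macro_auc, warns = roc_auc(y_true, scores, classes)
        report.roc = roc
        report.auc_per_class = aucs
        report.macro_auc = macro_auc
        report.warnings.extend(warns)
    return report


def plot_roc(report: EvaluationReport, path: str | Path) -> None:
    """Optional ROC figure; requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for c, pts in report.roc.items():
        ax.plot(pts["fpr"], pts["tpr"], label=f"class {c} (AUC {report.auc_per_class[c]:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
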