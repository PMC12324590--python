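"""Confusion matrices and the multi-class metric suite.

Per-class rates use the one-vs-rest reduction: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), precision = TP/(TP+FP), F1 the harmonic mean of
precision and sensitivity.  The headline summary is the macro-averaged F1
(unweighted mean of per-class F1), alongside accuracy, the generalized
multi-class Matthews correlation coefficient, and Cohen's kappa.
Zero-denominator rates return 0 and are flagged rather than raising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .audio_io import AudioValidationError


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise AudioValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} classes")
        if (self.counts < 0).any():
            raise AudioValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="true\\predicted")


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              classes: Sequence[str] | None = None) -> ConfusionMatrix:
    """Tally a confusion matrix; class order is fixed and explicit."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise AudioValidationError(
            f"{len(true_labels)} true vs {len(predicted_labels)} predicted labels")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([true_labels, predicted_labels])))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise AudioValidationError(f"label {t!r} or {p!r} outside class set")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def _safe_ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix, klass: str,
                  flags: list[str] | None = None) -> dict[str, float]:
    """One-vs-rest sensitivity, specificity, precision, and F1 for a class."""
    if klass not in cm.classes:
        raise AudioValidationError(f"unknown class {klass!r}")
    if flags is None:
        flags = []
    i = cm.classes.index(klass)
    tp = cm.counts[i, i]
    fn = cm.counts[i].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fn - fp
    sens = _safe_ratio(tp, tp + fn, flags, f"{klass}.sensitivity")
    spec = _safe_ratio(tn, tn + fp, flags, f"{klass}.specificity")
    prec = _safe_ratio(tp, tp + fp, flags, f"{klass}.precision")
    f1 = _safe_ratio(2 * prec * sens, prec + sens, flags, f"{klass}.f1")
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "f1": f1}


def summary_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, macro-F1, generalized MCC, and Cohen's kappa.

    MCC uses the multi-class covariance form; kappa is
    ``(p_o - p_e) / (1 - p_e)`` with the expected agreement ``p_e`` from
    products of row and column marginals.
    """
    if cm.total == 0:
        raise AudioValidationError("empty confusion matrix")
    C = cm.counts.astype(float)
    n = C.sum()
    accuracy = np.trace(C) / n
    macro_f1 = float(np.mean([class_metrics(cm, k)["f1"] for k in cm.classes]))

    t = C.sum(axis=1)  # true-class totals
    p = C.sum(axis=0)  # predicted-class totals
    cov_tp = np.trace(C) * n - t @ p
    cov_pp = n**2 - p @ p
    cov_tt = n**2 - t @ t
    mcc = 0.0 if cov_pp == 0 or cov_tt == 0 else cov_tp / np.sqrt(cov_pp * cov_tt)

    p_o = accuracy
    p_e = (t @ p) / n**2
    kappa = 0.0 if p_e == 1 else (p_o - p_e) / (1 - p_e)
    return {"accuracy": float(accuracy), "macro_f1": macro_f1,
            "mcc": float(mcc), "kappa": float(kappa)}


def normalized_summaries(cm: ConfusionMatrix) -> dict[str, dict[str, tuple[float, float]]]:
    """Column- and row-normalized (correct %, incorrect %) summaries.

    The column summary gives, per predicted class, the percentage of that
    column's observations classified correctly and incorrectly; the row
    summary does the same per true class.  Empty columns/rows yield (0, 0).
    """
    col_summary: dict[str, tuple[float, float]] = {}
    row_summary: dict[str, tuple[float, float]] = {}
    for i, klass in enumerate(cm.classes):
        col_total = cm.counts[:, i].sum()
        row_total = cm.counts[i, :].sum()
        diag = cm.counts[i, i]
        col_summary[klass] = (
            (100.0 * diag / col_total, 100.0 * (col_total - diag) / col_total)
            if col_total else (0.0, 0.0))
        row_summary[klass] = (
            (100.0 * diag / row_total, 100.0 * (row_total - diag) / row_total)
            if row_total else (0.0, 0.0))
    return {"column_summary": col_summary, "row_summary": row_summary}


@dataclass
class EvaluationReport:
    """Full evaluation of one model on one labeled set."""

    confusion_matrix: ConfusionMatrix
    per_class: dict[str, dict[str, float]]
    summary: dict[str, float]
    macro_averages: dict[str, float]
    micro_averages: dict[str, float]
    normalized: dict[str, dict[str, tuple[float, float]]]
    flags: list[str] = field(default_factory=list)
    train_seconds: float | None = None
    predict_seconds: float | None = None

    def to_dict(self) -> dict:
        return {
            "classes": self.confusion_matrix.classes,
            "confusion": self.confusion_matrix.counts.tolist(),
            "per_class": self.per_class,
            "summary": self.summary,
            "macro_averages": self.macro_averages,
            "micro_averages": self.micro_averages,
            "normalized": {k: {c: list(v) for c, v in d.items()}
                           for k, d in self.normalized.items()},
            "flags": self.flags,
            "train_seconds": self.train_seconds,
            "predict_seconds": self.predict_seconds,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_text(self) -> str:
        lines = ["confusion matrix (rows true, cols predicted):",
                 self.confusion_matrix.to_frame().to_string(), ""]
        per = pd.DataFrame(self.per_class).T
        lines.append(per.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append("  ".join(f"{k}={v:.4f}" for k, v in self.summary.items()))
        return "\n".join(lines)


def evaluate(true_labels: Sequence[str], predicted_labels: Sequence[str],
             classes: Sequence[str] | None = None,
             train_seconds: float | None = None,
             predict_seconds: float | None = None) -> EvaluationReport:
    """Build the complete report for one set of predictions."""
    cm = confusion(true_labels, predicted_labels, classes=classes)
    flags: list[str] = []
    per_class = {k: class_metrics(cm, k, flags) for k in cm.classes}
    summary = summary_metrics(cm)
    macro = {m: float(np.mean([per_class[k][m] for k in cm.classes]))
             for m in ("sensitivity", "specificity", "precision", "f1")}
    # micro average: pool TP/FN/FP over classes (sensitivity == accuracy
    # identity for single-label problems)
    tp = np.trace(cm.counts)
    total = cm.total
    tn = sum(cm.total - cm.counts[i].sum() - cm.counts[:, i].sum()
             + cm.counts[i, i] for i in range(len(cm.classes)))
    fp = total - tp
    micro = {
        "sensitivity": tp / total if total else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "precision": tp / total if total else 0.0,
        "f1": tp / total if total else 0.0,
    }
    return EvaluationReport(
        confusion_matrix=cm, per_class=per_class, summary=summary,
        macro_averages=macro, micro_averages={k: float(v) for k, v in micro.items()},
        normalized=normalized_summaries(cm), flags=flags,
        train_seconds=train_seconds, predict_seconds=predict_seconds,
    )
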