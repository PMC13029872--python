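"""One-vs-rest confusion accounting: per-class precision/recall, accuracy.

Each class is treated as its own binary problem: TP_c is the diagonal
entry, TP_c + FN_c the row sum (all true members of c) and TP_c + FP_c the
column sum (all predictions of c).  Overall accuracy is the summed TPs over
the dataset size.  Classes with zero support (or zero predictions) get NaN
recall (precision) rather than a silent zero, since averaging conventions
differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes), [true, predicted]
    classes: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion_matrix(true_labels, pred_labels, classes) -> ConfusionMatrix:
    if len(true_labels) != len(pred_labels):
        raise ValueError("label lists must have equal length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label {t if t not in index else p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def precision_recall(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision TP/(TP+FP) and recall TP/(TP+FN)."""
    counts = cm.counts
    tp = np.diag(counts).astype(np.float64)
    support = counts.sum(axis=1).astype(np.float64)  # TP + FN
    predicted = counts.sum(axis=0).astype(np.float64)  # TP + FP
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(support > 0, tp / support, np.nan)
        precision = np.where(predicted > 0, tp / predicted, np.nan)
    if np.isnan(recall).any():
        logger.warning("recall undefined for class(es) with zero support")
    if np.isnan(precision).any():
        logger.warning("precision undefined for class(es) never predicted")
    return pd.DataFrame(
        {"precision": precision, "recall": recall}, index=cm.classes
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """Summed per-class true positives over the total dataset size."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision/recall table with an overall-accuracy row."""
    tab = precision_recall(cm)
    tab.loc["__accuracy__"] = [accuracy(cm), accuracy(cm)]
    return tab


def write_report(cm: ConfusionMatrix, path) -> None:
    report(cm).to_csv(path)
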