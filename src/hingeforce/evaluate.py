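"""Confusion matrices and per-class precision / recall / F1.

The confusion matrix follows the convention of the original six-behavior
validation study: rows are the *predicted* behavior, columns the *actual*
behavior, in the fixed class order NHM, LC, RC, LW, RW, TK.  The diagonal
holds true positives; off-diagonal row entries are false positives of the
row's class and off-diagonal column entries its false negatives, so

    precision_i = TP_i / row_total_i      (outcome accuracy)
    recall_i    = TP_i / column_total_i   (condition accuracy)
    F1_i        = 2 * P_i * R_i / (P_i + R_i)

and the headline score is the arithmetic mean of the six F1 values.  The
study's published confusion matrix ships with the package (see
:func:`load_reference_confusion`) as a fixture for validating the metric
implementation against its printed percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from hingeforce.behaviors import CLASS_ORDER, Behavior

N_CLASSES = len(CLASS_ORDER)


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 counts with predicted behavior in rows and actual in columns."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"counts must be {N_CLASSES}x{N_CLASSES}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            c = c.astype(np.int64)
            if np.any(c < 0):
                raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        """Per predicted class: TP + false positives."""
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        """Per actual class: TP + false negatives."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        names = [b.name for b in CLASS_ORDER]
        frame = pd.DataFrame(self.counts, index=names, columns=names)
        frame.index.name = "predicted"
        return frame


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregate classification metrics, as fractions in [0, 1].

    ``undefined`` lists class codes whose precision or recall could not be
    computed (empty row or column); their entries are NaN rather than a
    silent zero.
    """

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    average_f1: float
    accuracy: float
    undefined: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"precision": self.precision, "recall": self.recall, "f1": self.f1}
        )


def confusion(
    actual: Sequence[Behavior | str | int], predicted: Sequence[Behavior | str | int]
) -> ConfusionMatrix:
    """Count (predicted, actual) pairs into the 6x6 matrix."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for a, p in zip(actual, predicted):
        ai = Behavior.from_code(a).value - 1
        pi = Behavior.from_code(p).value - 1
        counts[pi, ai] += 1
    return ConfusionMatrix(counts=counts)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall, F1 per class; mean F1 and overall accuracy."""
    tp = np.diag(cm.counts).astype(float)
    row = cm.row_totals.astype(float)
    col = cm.column_totals.astype(float)
    undefined = []
    precision, recall, f1 = {}, {}, {}
    for i, b in enumerate(CLASS_ORDER):
        p = tp[i] / row[i] if row[i] > 0 else np.nan
        r = tp[i] / col[i] if col[i] > 0 else np.nan
        if np.isnan(p) or np.isnan(r):
            undefined.append(b.name)
            f = np.nan
        elif p + r == 0:
            f = 0.0
        else:
            f = 2 * p * r / (p + r)
        precision[b.name] = float(p)
        recall[b.name] = float(r)
        f1[b.name] = float(f)
    f1_values = np.array(list(f1.values()))
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        average_f1=float(np.mean(f1_values)),
        accuracy=float(tp.sum() / cm.total) if cm.total else np.nan,
        undefined=tuple(undefined),
    )


def round_percent(fraction: float, ndigits: int = 1) -> float:
    """Fraction -> percent, rounded half-up to ``ndigits`` decimals.

    Matches the half-up convention used in printed report tables (banker's
    rounding would turn e.g. 89.45 into 89.4 instead of 89.5).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def load_reference_confusion() -> ConfusionMatrix:
    """The published 20,700-window reference confusion matrix.

    Ten subjects, 3,450 windows per class; used to validate the metric
    implementation against the study's printed precision/recall/F1 table.
    """
    ref = resources.files("hingeforce.data") / "reference_confusion.csv"
    with resources.as_file(ref) as path:
        return read_confusion_csv(path)


def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    """Read a confusion matrix CSV (rows predicted, columns actual)."""
    frame = pd.read_csv(path, index_col=0)
    names = [b.name for b in CLASS_ORDER]
    return ConfusionMatrix(counts=frame.loc[names, names].to_numpy())


def read_predictions_csv(path: str | Path) -> ConfusionMatrix:
    """Build a confusion matrix from a predictions CSV (actual, predicted)."""
    frame = pd.read_csv(path)
    return confusion(frame["actual"].tolist(), frame["predicted"].tolist())
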