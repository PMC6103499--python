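"""Binary segmentation evaluation: correlation, Dice, Hausdorff,
sensitivity and specificity between predicted and ground-truth masks.

Correlation on binary masks is the Pearson correlation of the flattened 0/1
vectors, computed through the phi-coefficient contingency identity for
numerical stability.  The Hausdorff distance is the unmodified maximum of
the two directed distances between the full foreground pixel sets, in
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "EvalReport",
    "confusion_counts",
    "dice",
    "hausdorff",
    "correlation",
    "sensitivity_specificity",
    "evaluate_pair",
    "evaluate_cohort",
]

REPORT_COLUMNS = ["correlation", "dice", "hausdorff", "sensitivity", "specificity"]


@dataclass
class EvalReport:
    correlation: float
    dice: float
    hausdorff: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


def _binarize(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    return pred > 0, truth > 0


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) pixel counts."""
    p, t = _binarize(pred, truth)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    tn = int(np.count_nonzero(~p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, fp, tn, fn


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as perfect."""
    tp, fp, _, fn = confusion_counts(pred, truth)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def hausdorff(pred: np.ndarray, truth: np.ndarray) -> float:
    """Symmetric Hausdorff distance between foreground pixel sets, in px."""
    p, t = _binarize(pred, truth)
    if not p.any() or not t.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    a = np.argwhere(p).astype(float)
    b = np.argwhere(t).astype(float)
    return float(max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0]))


def correlation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation of the flattened binary masks (phi coefficient)."""
    tp, fp, tn, fn = confusion_counts(pred, truth)
    n1p, n0p = tp + fp, tn + fn          # predicted positives / negatives
    n1t, n0t = tp + fn, tn + fp          # true positives / negatives
    denom = float(n1p) * n0p * n1t * n0t
    if denom == 0:
        raise ValueError("correlation undefined for a constant mask")
    return float((float(tp) * tn - float(fp) * fn) / np.sqrt(denom))


def sensitivity_specificity(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)); undefined denominators raise."""
    tp, fp, tn, fn = confusion_counts(pred, truth)
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: truth has no positives")
    if tn + fp == 0:
        raise ValueError("specificity undefined: truth has no negatives")
    return tp / (tp + fn), tn / (tn + fp)


def evaluate_pair(pred: np.ndarray, truth: np.ndarray) -> EvalReport:
    tp, fp, tn, fn = confusion_counts(pred, truth)
    sens, spec = sensitivity_specificity(pred, truth)
    return EvalReport(
        correlation=correlation(pred, truth),
        dice=dice(pred, truth),
        hausdorff=hausdorff(pred, truth),
        sensitivity=sens,
        specificity=spec,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def evaluate_cohort(pairs: list[tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Per-sample metric table plus a final ``mean`` row.

    Samples for which a metric is undefined (e.g. empty prediction for the
    Hausdorff distance) carry NaN in that cell; means ignore NaNs.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one mask pair")
    rows = []
    for pred, truth in pairs:
        row = {}
        for name, fn in (
            ("correlation", correlation),
            ("dice", dice),
            ("hausdorff", hausdorff),
        ):
            try:
                row[name] = fn(pred, truth)
            except ValueError:
                row[name] = np.nan
        try:
            row["sensitivity"], row["specificity"] = sensitivity_specificity(pred, truth)
        except ValueError:
            row["sensitivity"] = row["specificity"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.index.name = "sample"
    df.loc["mean"] = df.mean(skipna=True)
    return df
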