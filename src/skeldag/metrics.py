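"""One-vs-rest classification metrics and train/test split construction.

Each class is scored against all others: a clip predicted as class k counts
as a true positive of k when correct, a false positive of k when wrong, and
on the true class's ledger a false negative.  Per-class precision, recall,
specificity, F1 and accuracy are computed from these counts and reported as
percentages; the headline numbers are their unweighted (macro) means over
classes.  Under many classes the one-vs-rest true negatives dominate, which
is why specificity and accuracy sit near 100% even when recall does not.

Splits partition a clip manifest by performer (cross-subject) or camera
viewpoint (cross-view), so train and test share no subjects / no views.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

LOW_RECALL_THRESHOLD = 70.0  # percent


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest TP / FP / TN / FN over a set of clips."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def n_total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro-averaged metrics, all in percent."""

    per_class: pd.DataFrame  # columns: precision, recall, specificity, f1, accuracy
    macro: dict[str, float]
    low_recall_classes: tuple[int, ...]
    undefined_precision_classes: tuple[int, ...]
    multiclass_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        """Per-class rows plus a final 'macro' row, ready for CSV."""
        macro_row = pd.DataFrame([self.macro], index=["macro"])
        return pd.concat([self.per_class, macro_row])

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="class")


def confusion_counts(
    predictions: Iterable[int], truths: Iterable[int], n_classes: int
) -> ConfusionCounts:
    """One-vs-rest confusion counts for every class."""
    pred = np.asarray(list(predictions))
    true = np.asarray(list(truths))
    if pred.shape != true.shape:
        raise ValueError("predictions and truths differ in length")
    for name, arr in (("prediction", pred), ("truth", true)):
        bad = (arr < 0) | (arr >= n_classes)
        if bad.any():
            raise ValueError(f"{name} label out of range: {arr[bad][0]}")
    n = len(pred)
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for k in range(n_classes):
        tp[k] = np.sum((pred == k) & (true == k))
        fp[k] = np.sum((pred == k) & (true != k))
        fn[k] = np.sum((pred != k) & (true == k))
    tn = n - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _safe_pct(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros(len(num), dtype=float)
    ok = den > 0
    out[ok] = 100.0 * num[ok] / den[ok]
    return out


def compute_metrics(
    counts: ConfusionCounts, average: Literal["macro", "micro"] = "macro"
) -> MetricsReport:
    """Precision, recall, specificity, F1 and one-vs-rest accuracy.

    A class that is never predicted has an undefined precision; it is
    reported as 0 and flagged, which keeps the macro averages defined.
    ``average="micro"`` pools the counts over classes before dividing.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _safe_pct(tp, tp + fp)
    recall = _safe_pct(tp, tp + fn)
    specificity = _safe_pct(tn, tn + fp)
    pr = precision + recall
    f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    accuracy = _safe_pct(tp + tn, tp + tn + fp + fn)

    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f1": f1,
            "accuracy": accuracy,
        }
    )
    if average == "macro":
        macro = {c: float(per_class[c].mean()) for c in per_class.columns}
    else:
        stp, sfp, stn, sfn = tp.sum(), fp.sum(), tn.sum(), fn.sum()
        mp = 100.0 * stp / max(stp + sfp, 1)
        mr = 100.0 * stp / max(stp + sfn, 1)
        macro = {
            "precision": mp,
            "recall": mr,
            "specificity": 100.0 * stn / max(stn + sfp, 1),
            "f1": 2 * mp * mr / (mp + mr) if mp + mr > 0 else 0.0,
            "accuracy": 100.0 * (stp + stn) / (stp + stn + sfp + sfn),
        }
    low = tuple(int(k) for k in np.flatnonzero(recall < LOW_RECALL_THRESHOLD))
    undef = tuple(int(k) for k in np.flatnonzero((tp + fp) == 0))
    multiclass_acc = 100.0 * tp.sum() / counts.n_total if counts.n_total else 0.0
    return MetricsReport(per_class, macro, low, undef, multiclass_acc)


def evaluate_predictions(
    predictions: Iterable[int], truths: Iterable[int], n_classes: int
) -> MetricsReport:
    return compute_metrics(confusion_counts(predictions, truths, n_classes))


def make_splits(
    manifest: pd.DataFrame,
    mode: Literal["cross-subject", "cross-view"],
    train_ids: Iterable[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a clip manifest into disjoint train/test tables.

    ``mode`` chooses the grouping field: performer (``subject_id``) or
    camera (``camera_id``).  Clips whose group id is in ``train_ids`` go to
    train, everything else to test.
    """
    column = {"cross-subject": "subject_id", "cross-view": "camera_id"}.get(mode)
    if column is None:
        raise ValueError(f"unknown split mode {mode!r}")
    if column not in manifest.columns:
        raise ValueError(f"manifest lacks column {column!r}")
    ids = manifest[column]
    if ids.isna().any():
        missing = manifest.loc[ids.isna(), "clip_id"].tolist()[:5]
        raise ValueError(f"clips missing {column}: {missing}")
    train_ids = {str(t) for t in train_ids}
    in_train = ids.astype(str).isin(train_ids)
    return manifest[in_train].copy(), manifest[~in_train].copy()
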