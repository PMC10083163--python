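"""Classification metrics: accuracy, precision, recall, F1, rank-based AUC
with tie handling, Matthews correlation, and the per-class/overall report.

AUC is computed in its Mann-Whitney-Wilcoxon form: the probability that a
random positive sample receives a higher score than a random negative one,
with ties contributing 1/2.  Degenerate denominators yield ``None``
("undefined") rather than a silent zero; aggregate rows may opt into the
undefined-as-zero convention explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "binary_metrics",
    "auc_mww",
    "mcc",
    "per_class_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def binary_metrics(counts: ConfusionCounts, undefined_as_zero: bool = False):
    """Accuracy, precision, recall and F1 from one-vs-rest counts.

    Precision is undefined when nothing was predicted positive, recall when
    no positives exist, and F1 when either is undefined or both are zero;
    undefined values are ``None`` unless ``undefined_as_zero``.
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    und = 0.0 if undefined_as_zero else None

    accuracy = (counts.tp + counts.tn) / counts.total
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else und
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else und
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = und
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def auc_mww(pos_scores, neg_scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic.

    Equals sum_ij I(x_i, y_j) / (n m) with I = 1 if x > y, 1/2 if x = y,
    0 otherwise; computed via midranks so ties are exact at any size.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("auc_mww undefined for empty score lists")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def mcc(counts: ConfusionCounts, undefined_as_zero: bool = False):
    """Matthews correlation coefficient in [-1, 1]; ``None`` (or 0 under the
    explicit convention) when any marginal is empty."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0 if undefined_as_zero else None
    return float((tp * tn - fp * fn) / np.sqrt(denom))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus an overall aggregate row.

    ``table`` is indexed by class name (+ "overall") with columns
    auc, f1, accuracy, precision, recall, mcc, support.
    """

    table: pd.DataFrame
    weighted_overall: bool = True

    def __getitem__(self, class_name: str) -> pd.Series:
        return self.table.loc[class_name]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


_METRIC_COLS = ["auc", "f1", "accuracy", "precision", "recall", "mcc"]


def per_class_report(true_labels, score_matrix, class_names,
                     weighted_overall: bool = True) -> MetricsReport:
    """Build the per-class/overall metrics report.

    Hard predictions are the argmax of each score row (ties broken toward
    the lowest class index).  For each class, one-vs-rest counts feed
    accuracy/precision/recall/F1/MCC, and that class's score column against
    the rest gives the AUC.  The overall row is the class-support-weighted
    mean by default (an unweighted mean is available); undefined per-class
    values are mapped to 0 in the aggregate, as flagged by ``binary_metrics``.
    A class absent from ``true_labels`` has support 0 and NaN metrics.
    """
    true = np.asarray(true_labels)
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != true.size:
        raise ValueError("score_matrix must be (n_samples, n_classes)")
    if scores.shape[1] != len(class_names):
        raise ValueError("one score column per class required")
    preds = scores.argmax(axis=1)

    rows = {}
    for idx, name in enumerate(class_names):
        is_pos = true == idx
        support = int(is_pos.sum())
        if support == 0 or support == true.size:
            rows[name] = dict.fromkeys(_METRIC_COLS, np.nan) | {"support": support}
            continue
        pred_pos = preds == idx
        counts = ConfusionCounts(
            tp=int((pred_pos & is_pos).sum()),
            tn=int((~pred_pos & ~is_pos).sum()),
            fp=int((pred_pos & ~is_pos).sum()),
            fn=int((~pred_pos & is_pos).sum()),
        )
        row = binary_metrics(counts, undefined_as_zero=True)
        row["mcc"] = mcc(counts, undefined_as_zero=True)
        row["auc"] = auc_mww(scores[is_pos, idx], scores[~is_pos, idx])
        row["support"] = support
        rows[name] = row

    table = pd.DataFrame.from_dict(rows, orient="index")[_METRIC_COLS + ["support"]]
    valid = table["support"] > 0
    if weighted_overall:
        wts = table.loc[valid, "support"].to_numpy(dtype=float)
        overall = (table.loc[valid, _METRIC_COLS].mul(wts, axis=0).sum() / wts.sum())
    else:
        overall = table.loc[valid, _METRIC_COLS].mean()
    overall["support"] = int(table["support"].sum())
    table.loc["overall"] = overall
    return MetricsReport(table=table, weighted_overall=weighted_overall)
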