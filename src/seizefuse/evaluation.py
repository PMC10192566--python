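"""Segment-level evaluation: confusion counts, ACC/SN/SP, false alarm rate.

Conventions: preictal is the positive class.  Accuracy and sensitivity
follow the usual definitions

    ACC = (TP + TN) / (TP + TN + FP + FN),      SN = TP / (TP + FN).

Specificity is reported under two definitions: the standard
SP = TN / (TN + FP) (default) and an "as-printed" variant
SP = TN / (TP + TN) retained for comparability with reports that use that
form.  The false alarm rate is the fraction of interictal windows on
which the system raises an alarm, FAR = N_alarm / N_wo, with a single
positive window counting as an alarm.  Undefined ratios (zero
denominator) are returned as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionCounts", "FoldReport", "confusion", "metrics",
    "false_alarm_rate", "fold_report", "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FoldReport:
    patient_id: str
    held_out_episode: int
    counts: ConfusionCounts
    acc: float
    sn: float
    sp: float
    sp_as_printed: float
    far: float
    n_interictal_windows: int
    n_alarm_windows: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.size == 0:
        raise ValueError("cannot build a confusion table from empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(counts: ConfusionCounts,
            sp_definition: str = "standard") -> tuple[float, float, float]:
    """(ACC, SN, SP) from a confusion table.

    sp_definition: "standard" -> TN/(TN+FP); "as-printed" -> TN/(TP+TN).
    """
    acc = _ratio(counts.tp + counts.tn, counts.total)
    sn = _ratio(counts.tp, counts.tp + counts.fn)
    if sp_definition == "standard":
        sp = _ratio(counts.tn, counts.tn + counts.fp)
    elif sp_definition == "as-printed":
        sp = _ratio(counts.tn, counts.tp + counts.tn)
    else:
        raise ValueError(f"unknown sp_definition {sp_definition!r}")
    return acc, sn, sp


def false_alarm_rate(y_true, y_pred) -> tuple[float, int, int]:
    """FAR = alarms among interictal windows / interictal windows.

    Returns (far, n_interictal_windows, n_alarm_windows); far is NaN when
    no interictal window was evaluated.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    inter = y_true == 0
    n_wo = int(inter.sum())
    n_alarm = int(np.sum(y_pred[inter] == 1))
    return _ratio(n_alarm, n_wo), n_wo, n_alarm


def fold_report(patient_id: str, held_out_episode: int,
                y_true, y_pred) -> FoldReport:
    counts = confusion(y_true, y_pred)
    acc, sn, sp = metrics(counts, "standard")
    _, _, sp_printed = metrics(counts, "as-printed")
    far, n_wo, n_alarm = false_alarm_rate(y_true, y_pred)
    return FoldReport(patient_id, held_out_episode, counts, acc, sn, sp,
                      sp_printed, far, n_wo, n_alarm)


def aggregate(reports: list[FoldReport]) -> dict:
    """Mean +/- sd per metric across folds, plus the pooled-confusion view."""
    if not reports:
        raise ValueError("no fold reports to aggregate")

    def mean_sd(values):
        values = np.asarray(values, dtype=float)
        mean = float(np.nanmean(values))
        sd = float(np.nanstd(values, ddof=1)) if len(values) > 1 else 0.0
        return {"mean": mean, "sd": sd}

    summary = {
        name: mean_sd([getattr(r, name) for r in reports])
        for name in ("acc", "sn", "sp", "sp_as_printed", "far")
    }
    pooled = ConfusionCounts(
        tp=sum(r.counts.tp for r in reports),
        tn=sum(r.counts.tn for r in reports),
        fp=sum(r.counts.fp for r in reports),
        fn=sum(r.counts.fn for r in reports),
    )
    acc, sn, sp = metrics(pooled, "standard")
    n_wo = sum(r.n_interictal_windows for r in reports)
    n_alarm = sum(r.n_alarm_windows for r in reports)
    summary["pooled"] = {
        "acc": acc, "sn": sn, "sp": sp,
        "far": _ratio(n_alarm, n_wo),
        "counts": asdict(pooled),
    }
    summary["n_folds"] = len(reports)
    return summary
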