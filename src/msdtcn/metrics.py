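"""Pixel-overlap evaluation: confusion counts and the five standard
segmentation metrics (accuracy, IoU, Dice, sensitivity, specificity).

Metrics are computed from hard masks (predictions thresholded at 0.5
upstream).  For degenerate denominators the conventional sentinels are used:
a ratio with an empty reference class is 1 when the prediction agrees that
the class is absent and 0 otherwise.  From a single confusion table the
identity Dice = 2*IoU / (1 + IoU) holds exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics",
           "aggregate_reports", "write_reports"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    acc: float
    iou: float
    dice: float
    se: float
    sp: float

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(pred_mask, target_mask) -> ConfusionCounts:
    """Pixel tallies between two binary masks of equal shape."""
    p = np.asarray(pred_mask)
    t = np.asarray(target_mask)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise ValueError("masks must be binary")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: int, den: int, empty_value: float) -> float:
    return num / den if den else empty_value


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC, IoU, Dice, SE, SP from one confusion table."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    return MetricsReport(
        acc=(tp + tn) / counts.total,
        iou=_ratio(tp, tp + fp + fn, 1.0),
        dice=_ratio(2 * tp, 2 * tp + fp + fn, 1.0),
        se=_ratio(tp, tp + fn, 1.0 if fp == 0 else 0.0),
        sp=_ratio(tn, tn + fp, 1.0 if fn == 0 else 0.0),
    )


def aggregate_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Per-image averaging (the package default for dataset-level scores)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    arr = np.array([[r.acc, r.iou, r.dice, r.se, r.sp] for r in reports])
    return MetricsReport(*[float(v) for v in arr.mean(axis=0)])


def write_reports(path_prefix: str | Path, ids: list[str],
                  reports: list[MetricsReport]) -> MetricsReport:
    """CSV (one row per image + a summary row) and a JSON summary."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    summary = aggregate_reports(reports)
    with open(prefix.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "acc", "iou", "dice", "se", "sp"])
        for sid, r in zip(ids, reports):
            writer.writerow([sid, f"{r.acc:.6f}", f"{r.iou:.6f}",
                             f"{r.dice:.6f}", f"{r.se:.6f}", f"{r.sp:.6f}"])
        writer.writerow(["mean", f"{summary.acc:.6f}", f"{summary.iou:.6f}",
                         f"{summary.dice:.6f}", f"{summary.se:.6f}",
                         f"{summary.sp:.6f}"])
    prefix.with_suffix(".json").write_text(json.dumps(summary.as_dict(),
                                                      indent=1))
    return summary
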