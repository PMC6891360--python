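"""FOV-restricted segmentation metrics.

Only pixels inside the field of view are counted.  With TP/FP/TN/FN the
per-pixel confusion counts against a ground-truth vessel map,

    Sn  = TP / (TP + FN)            (vessel recall / sensitivity)
    Sp  = TN / (TN + FP)            (background recall / specificity)
    Acc = (TP + TN) / (TP+FP+TN+FN) (overall pixel accuracy)

and algebraically Acc = prevalence * Sn + (1 - prevalence) * Sp with
prevalence = (TP + FN) / total.  Batch reports list per-image rows plus an
unweighted mean row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, GeometryError

__all__ = ["ConfusionCounts", "Metrics", "confusion", "metrics", "evaluate_batch"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float


def confusion(pred: np.ndarray, truth: np.ndarray, fov: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts over the FOV only."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    fov = np.asarray(fov, bool)
    if not (pred.shape == truth.shape == fov.shape):
        raise GeometryError("pred, truth and fov must share one geometry")
    p, t = pred[fov], truth[fov]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sn/Sp/Acc from confusion counts; empty classes raise rather than
    silently reporting zero."""
    if counts.tp + counts.fn == 0:
        raise DegenerateInputError("no vessel pixels in ground truth: Sn undefined")
    if counts.tn + counts.fp == 0:
        raise DegenerateInputError("no background pixels in ground truth: Sp undefined")
    sn = counts.tp / (counts.tp + counts.fn)
    sp = counts.tn / (counts.tn + counts.fp)
    acc = (counts.tp + counts.tn) / counts.total
    return Metrics(sn=sn, sp=sp, acc=acc)


def evaluate_batch(records) -> pd.DataFrame:
    """Per-image metrics table with an aggregate mean row.

    ``records`` is an iterable of (image_id, pred, truth, fov) tuples.
    The mean row (image id "mean") is the unweighted average over images.
    """
    rows = []
    for image_id, pred, truth, fov in records:
        c = confusion(pred, truth, fov)
        m = metrics(c)
        rows.append(
            dict(image=str(image_id), tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn,
                 sn=m.sn, sp=m.sp, acc=m.acc)
        )
    if not rows:
        raise DegenerateInputError("evaluate_batch received no records")
    df = pd.DataFrame(rows)
    mean_row = df[["tp", "fp", "tn", "fn", "sn", "sp", "acc"]].mean()
    df.loc[len(df)] = dict(image="mean", **mean_row.to_dict())
    return df
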