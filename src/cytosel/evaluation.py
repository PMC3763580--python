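"""Confusion-matrix metrics (SN, SP, GM, ACC) and cross-validation.

Under extreme class imbalance overall accuracy is dominated by the
majority class (ACC ≈ SP), so the geometric mean GM = sqrt(SN * SP) is
the headline metric: it collapses whenever either class is missed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold


@dataclass
class EvalReport:
    """Confusion counts and derived metrics, optionally per CV fold."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    gm: float
    acc: float
    folds: Optional[list["EvalReport"]] = None

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "EvalReport":
        if tp + fn == 0:
            raise ValueError("SN undefined: no positive samples in y_true")
        if tn + fp == 0:
            raise ValueError("SP undefined: no negative samples in y_true")
        sn = tp / (tp + fn)
        sp = tn / (tn + fp)
        return cls(
            tp=tp, tn=tn, fp=fp, fn=fn,
            sn=sn, sp=sp,
            gm=math.sqrt(sn * sp),
            acc=(tp + tn) / (tp + tn + fp + fn),
        )

    def to_dict(self, include_folds: bool = True) -> dict:
        out = {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "SN": self.sn, "SP": self.sp, "GM": self.gm, "ACC": self.acc,
        }
        if include_folds and self.folds is not None:
            out["folds"] = [f.to_dict(include_folds=False) for f in self.folds]
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def table(self) -> str:
        return (
            f"TP={self.tp}  TN={self.tn}  FP={self.fp}  FN={self.fn}\n"
            f"SN={self.sn:.4f}  SP={self.sp:.4f}  GM={self.gm:.4f}  ACC={self.acc:.4f}"
        )


def confusion_metrics(
    y_true: Sequence, y_pred: Sequence, positive_label=None
) -> EvalReport:
    """SN, SP, GM and ACC from paired label vectors.

    The positive class defaults to the larger of the two labels present
    in ``y_true`` (e.g. 1 for 0/1 labels). Both classes must appear in
    ``y_true``, otherwise the dependent metric is undefined.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.unique(y_true)
    if labels.size > 2:
        raise ValueError("binary labels expected")
    if positive_label is None:
        positive_label = labels.max()
    negative = labels[labels != positive_label]
    if positive_label not in labels:
        raise ValueError("SN undefined: no positive samples in y_true")
    if negative.size == 0:
        raise ValueError("SP undefined: no negative samples in y_true")
    negative_label = negative[0]
    cm = confusion_matrix(y_true, y_pred, labels=[negative_label, positive_label])
    tn, fp, fn, tp = cm.ravel()
    return EvalReport.from_counts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def crossvalidate(
    model_factory: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    presample: bool = False,
    resampling_plan=None,
) -> EvalReport:
    """Stratified k-fold cross-validation with held-out pooling.

    ``model_factory`` returns a fresh unfitted model (anything with
    ``fit``/``predict``); any resampling configured inside that model is
    applied to each training split only, so held-out folds stay untouched
    real data. ``presample=True`` instead resamples the WHOLE dataset
    first (via ``resampling_plan``) and cross-validates the resampled set
    — the literal sample-then-validate order, which leaks synthetic
    copies of held-out minority points into training folds and therefore
    reads optimistically.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )

    if presample:
        if resampling_plan is None:
            raise ValueError("presample requires a resampling_plan")
        from .sampling import hybrid_resample

        rs = hybrid_resample(X, y, resampling_plan)
        X, y = rs.X, rs.y

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    fold_reports: list[EvalReport] = []
    for train_idx, test_idx in skf.split(X, y):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        pooled_true.append(y[test_idx])
        pooled_pred.append(pred)
        fold_reports.append(confusion_metrics(y[test_idx], pred))
    report = confusion_metrics(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    report.folds = fold_reports
    return report
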