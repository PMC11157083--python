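"""Segmentation scoring: confusion matrix and the five derived metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """Voxel counts of a two-class comparison; totals must be conserved."""

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

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class ScorePanel:
    """accuracy, precision, recall, F1, Jaccard — NaN where undefined."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    jaccard: float


def confusion(
    pred: np.ndarray, ref: np.ndarray, eval_region: np.ndarray | None = None
) -> ConfusionMatrix:
    """Count TP/TN/FP/FN of ``pred`` against ``ref`` over ``eval_region``.

    All arrays must share one shape; the evaluation region defaults to the
    whole image (e.g. restrict it to the fully annotated z-sections when
    scoring against sparse manual ground truth).
    """
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    if eval_region is not None:
        eval_region = np.asarray(eval_region, dtype=bool)
        if eval_region.shape != pred.shape:
            raise ValueError("eval_region shape mismatch")
        pred = pred[eval_region]
        ref = ref[eval_region]
    return ConfusionMatrix(
        tp=int(np.count_nonzero(pred & ref)),
        tn=int(np.count_nonzero(~pred & ~ref)),
        fp=int(np.count_nonzero(pred & ~ref)),
        fn=int(np.count_nonzero(~pred & ref)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def scores(cm: ConfusionMatrix) -> ScorePanel:
    """Derive the five metrics; zero denominators yield NaN, not 0.

    Satisfies ``jaccard == f1 / (2 - f1)`` wherever both are defined.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = 0.0 if cm.tp + cm.fp + cm.fn > 0 else float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ScorePanel(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        precision=precision,
        recall=recall,
        f1=f1,
        jaccard=_ratio(cm.tp, cm.tp + cm.fp + cm.fn),
    )


def aggregate_scores(cms: Sequence[ConfusionMatrix]) -> dict[str, ScorePanel]:
    """Macro (mean of per-image scores) and micro (pooled counts) panels.

    The macro panel is the headline number; micro is emitted alongside for
    transparency since per-test-set reporting is ambiguous between the two.
    """
    if len(cms) == 0:
        raise ValueError("no confusion matrices to aggregate")
    panels = [scores(cm) for cm in cms]
    macro = ScorePanel(
        **{
            k: float(np.nanmean([getattr(p, k) for p in panels]))
            for k in ("accuracy", "precision", "recall", "f1", "jaccard")
        }
    )
    pooled = cms[0]
    for cm in cms[1:]:
        pooled = pooled + cm
    return {"macro": macro, "micro": scores(pooled)}
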