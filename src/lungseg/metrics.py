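"""Pixel-classification metrics, the soft dice loss, and report aggregation.

Segmentation is scored as pixel-level binary classification. From the
confusion counts TP/FP/FN/TN the five standard metrics are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    dice        = 2 TP / (2 TP + FP + FN)
    jaccard     = TP / (TP + FP + FN)

Jaccard and dice are algebraically linked by J = D / (2 - D), so J <= D
always, with equality only at 0 and 1.

Degenerate denominators follow the usual segmentation conventions: with an
empty truth and an empty prediction (TP = FP = FN = 0) dice and jaccard are
defined as 1.0 (perfect agreement on "nothing to segment") with a logged
warning; sensitivity is undefined when the truth is empty and specificity
when the truth covers the whole frame — both are reported as NaN and skipped
by the aggregator.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nn import autograd as ag
from .nn.autograd import Tensor

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "specificity", "sensitivity", "dice", "jaccard")

__all__ = [
    "METRIC_NAMES",
    "ConfusionCounts",
    "MetricValues",
    "MetricReport",
    "confusion",
    "metrics_from_counts",
    "soft_dice_loss",
    "batch_soft_dice_loss",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts for one prediction/truth pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricValues:
    accuracy: float
    specificity: float
    sensitivity: float
    dice: float
    jaccard: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1 or bool); found values {vals[:10]}")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/FN/TN pixels between two binary masks of the same shape."""
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_from_counts(c: ConfusionCounts) -> MetricValues:
    """The five ratio metrics from confusion counts (degenerate cases above)."""
    accuracy = (c.tp + c.tn) / c.total
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    if c.tp + c.fp + c.fn == 0:
        logger.warning(
            "empty truth and empty prediction: dice/jaccard defined as 1.0 by convention"
        )
        dice = jaccard = 1.0
    else:
        dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
        jaccard = c.tp / (c.tp + c.fp + c.fn)
    return MetricValues(accuracy, specificity, sensitivity, dice, jaccard)


def soft_dice_loss(probs: np.ndarray, truth: np.ndarray, eps: float = 1e-6) -> float:
    """Differentiable dice loss 1 - (2 Σ p·t + eps) / (Σ p + Σ t + eps).

    ``probs`` is a probability map in [0, 1]; ``truth`` a binary mask of the
    same shape. On hard {0,1} predictions this equals 1 - dice from counts,
    up to the eps smoothing that keeps the empty-vs-empty case at loss 0.
    """
    probs = np.asarray(probs, dtype=np.float64)
    truth_b = _check_binary(truth, "truth").astype(np.float64)
    if probs.shape != truth_b.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs truth {truth_b.shape}")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probs must lie in [0, 1]")
    inter = float((probs * truth_b).sum())
    return 1.0 - (2.0 * inter + eps) / (float(probs.sum()) + float(truth_b.sum()) + eps)


def batch_soft_dice_loss(probs: Tensor, truth: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Autograd dice loss over an (N, 1, H, W) batch, averaged per sample.

    Per-sample averaging keeps large lungs from dominating the batch loss.
    """
    t = np.asarray(truth, dtype=np.float64)
    if t.shape != probs.data.shape:
        raise ValueError(f"shape mismatch: probs {probs.data.shape} vs truth {t.shape}")
    inter = ag.sum_axes(ag.mul(probs, t), axes=(1, 2, 3))
    denom = ag.add(ag.sum_axes(probs, axes=(1, 2, 3)), t.sum(axis=(1, 2, 3)))
    per_sample = ag.sub(1.0, ag.div(ag.add(ag.mul(inter, 2.0), eps), ag.add(denom, eps)))
    return ag.mean_axes(per_sample)


# ---------------------------------------------------------------------------
# aggregation and reporting
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-image metric table plus mean ± sample-std aggregates."""

    per_image: pd.DataFrame  # columns: sample_id + METRIC_NAMES
    aggregate: dict[str, dict[str, float]]  # metric -> {"mean": ..., "std": ...}

    def to_csv(self, path: str | Path) -> None:
        self.per_image.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.aggregate, fh, indent=2)

    def format_table(self, label: str = "") -> str:
        """One-row summary in the mean ± std percent convention of the field."""
        cells = [
            f"{name}: {100 * agg['mean']:.2f} ± {100 * agg['std']:.2f}%"
            for name, agg in self.aggregate.items()
        ]
        prefix = f"{label}  " if label else ""
        return prefix + "  ".join(cells)


def aggregate(rows: Sequence[Mapping[str, float]] | pd.DataFrame) -> MetricReport:
    """Aggregate per-image metric rows into mean ± sample standard deviation.

    Uses the n-1 (sample) standard deviation; a single row reports std 0.
    NaN entries (undefined sensitivity/specificity) are excluded per metric.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows))
    if len(df) == 0:
        raise ValueError("aggregate requires at least one per-image row")
    if "sample_id" not in df.columns:
        df.insert(0, "sample_id", [str(i) for i in range(len(df))])
    agg: dict[str, dict[str, float]] = {}
    for name in METRIC_NAMES:
        vals = df[name].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            agg[name] = {"mean": math.nan, "std": math.nan}
        elif vals.size == 1:
            agg[name] = {"mean": float(vals[0]), "std": 0.0}
        else:
            agg[name] = {"mean": float(vals.mean()), "std": float(vals.std(ddof=1))}
    return MetricReport(per_image=df, aggregate=agg)


def score_pair(pred: np.ndarray, truth: np.ndarray, sample_id: str = "") -> dict[str, float]:
    """Convenience: confusion -> five metrics as a per-image row dict."""
    row: dict[str, float] = {"sample_id": sample_id}
    row.update(metrics_from_counts(confusion(pred, truth)).as_dict())
    return row
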