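"""Detector evaluation: sample-wise binary metrics, multi-class metrics,
classifier confidence, and rank-test effect sizes.

Binary evaluation is duration-weighted by construction: predictions and
annotations are rasterised to boolean masks at the recording's native
sampling rate, so every metric is a proportion of signal time.  Metrics
whose denominator is empty are *undefined* and returned as NaN — never
silently 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_from_masks",
    "accuracy",
    "hit_rate",
    "false_discovery_rate",
    "multiclass_metrics",
    "classifier_confidence",
    "epsilon_squared",
    "eta_squared",
]


@dataclass
class ConfusionCounts:
    """Sample-wise binary confusion counts; artifact is the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_from_masks(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN between two equal-length boolean masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask length mismatch: {pred.shape} vs {truth.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total — fraction of signal classified correctly."""
    if c.total == 0:
        return float("nan")
    return (c.tp + c.tn) / c.total


def hit_rate(c: ConfusionCounts) -> float:
    """TP / (TP + FN) — fraction of annotated artifact that was detected."""
    if c.tp + c.fn == 0:
        return float("nan")
    return c.tp / (c.tp + c.fn)


def false_discovery_rate(c: ConfusionCounts) -> float:
    """FP / (TP + FP) — fraction of detected artifact not annotated as such."""
    if c.tp + c.fp == 0:
        return float("nan")
    return c.fp / (c.tp + c.fp)


def multiclass_metrics(
    matrix: np.ndarray, labels: list[str] | None = None
) -> dict:
    """Metrics of a K×K confusion matrix (rows true, columns predicted).

    Returns overall accuracy, per-class one-vs-all precision and
    sensitivity, and their unweighted means across classes.  Classes with
    an empty column (precision) or row (sensitivity) yield NaN and are
    excluded from the corresponding mean with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(m < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = m.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    K = m.shape[0]
    labels = labels or [f"class_{k}" for k in range(K)]
    diag = np.diag(m)
    colsum = m.sum(axis=0)
    rowsum = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(colsum > 0, diag / colsum, np.nan)
        sensitivity = np.where(rowsum > 0, diag / rowsum, np.nan)
    for name, vec in (("precision", precision), ("sensitivity", sensitivity)):
        if np.any(np.isnan(vec)):
            bad = [labels[k] for k in np.flatnonzero(np.isnan(vec))]
            warnings.warn(
                f"{name} undefined for classes {bad}; excluded from the mean",
                stacklevel=2,
            )
    return {
        "overall_accuracy": float(diag.sum() / total),
        "precision": dict(zip(labels, precision.tolist())),
        "sensitivity": dict(zip(labels, sensitivity.tolist())),
        "mean_precision": float(np.nanmean(precision)),
        "mean_sensitivity": float(np.nanmean(sensitivity)),
    }


def classifier_confidence(probs: np.ndarray) -> float:
    """Mean per-epoch confidence of a probabilistic classifier.

    Confidence of an epoch is the gap between its two highest class
    probabilities; rows must be valid distributions (non-negative,
    summing to 1 within 1e-6) over K ≥ 2 classes.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("need an epochs × K table with K >= 2")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1)))
        raise ValueError(
            f"row {bad} sums to {sums[bad]:.8f}, not 1"
        )
    part = np.partition(p, -2, axis=1)
    return float(np.mean(part[:, -1] - part[:, -2]))


def epsilon_squared(h_statistic: float, n: int) -> float:
    """Epsilon-squared effect size for a Kruskal–Wallis H statistic.

    ``epsilon² = H·(n+1) / (n²−1)`` over ``n`` total observations,
    clipped to [0, 1].
    """
    if n <= 1:
        raise ValueError("need more than one observation")
    return float(np.clip(h_statistic * (n + 1) / (n**2 - 1), 0.0, 1.0))


def eta_squared(z_statistic: float, n: int) -> float:
    """Eta-squared effect size for a rank-sum Z statistic: ``Z²/n``,
    with ``n = n1 + n2`` total observations, clipped to [0, 1]."""
    if n <= 1:
        raise ValueError("need more than one observation")
    return float(np.clip(z_statistic**2 / n, 0.0, 1.0))
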