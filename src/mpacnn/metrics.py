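"""Confusion-matrix evaluation for the binary cancer/healthy classifier.

The positive class is "cancer".  Besides accuracy, error rate and specificity,
two sensitivity conventions are provided: the standard recall TP/(TP+FN) and a
"precision" convention TP/(TP+FP), which some reports print under the
sensitivity name.  Accuracy and error rate are exact complements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies; positive = cancer class."""

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


def confusion(y_true, y_pred, positive_label=1) -> ConfusionCounts:
    """Tally the four agreement cells between true and predicted binary labels."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"label vectors must be equal-length 1-D, got {t.shape} vs {p.shape}")
    labels = set(np.unique(t)) | set(np.unique(p))
    if len(labels - {positive_label}) > 1:
        raise ValueError(f"labels must be binary, got {sorted(labels)}")
    tpos = t == positive_label
    ppos = p == positive_label
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TN + TP) / (TN + FN + TP + FP)."""
    if c.total == 0:
        raise ZeroDivisionError("accuracy undefined for empty counts")
    return (c.tn + c.tp) / c.total


def error_rate(c: ConfusionCounts) -> float:
    """(FN + FP) / (TN + FN + TP + FP); exactly 1 - accuracy."""
    if c.total == 0:
        raise ZeroDivisionError("error rate undefined for empty counts")
    return (c.fn + c.fp) / c.total


def sensitivity(c: ConfusionCounts, convention: str = "standard") -> float:
    """Sensitivity under the chosen convention.

    ``"standard"`` is recall TP/(TP+FN); ``"precision"`` is TP/(TP+FP), the
    precision-style ratio some reports label sensitivity(recall).
    """
    if convention == "standard":
        denom = c.tp + c.fn
    elif convention == "precision":
        denom = c.tp + c.fp
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if denom == 0:
        raise ZeroDivisionError(f"sensitivity ({convention}) undefined: zero denominator")
    return c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP): fraction of healthy slices called healthy."""
    denom = c.tn + c.fp
    if denom == 0:
        raise ZeroDivisionError("specificity undefined: no negative samples")
    return c.tn / denom


def report(c: ConfusionCounts, as_percent: bool = False) -> dict:
    """All metrics in one dict; fractions by default, Table-style percentages on request."""
    scale = 100.0 if as_percent else 1.0
    out = {
        "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
        "accuracy": accuracy(c) * scale,
        "error": error_rate(c) * scale,
    }
    for key, fn in (("sensitivity", lambda: sensitivity(c, "standard")),
                    ("sensitivity_precision", lambda: sensitivity(c, "precision")),
                    ("specificity", lambda: specificity(c))):
        try:
            out[key] = fn() * scale
        except ZeroDivisionError:
            out[key] = float("nan")
    return out
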