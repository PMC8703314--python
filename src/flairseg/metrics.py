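"""Segmentation and classification scoring.

Pixel-level evaluation of a predicted mask S against a reference mask G uses
the confusion counts TP/FP/FN/TN and derives

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    accuracy  = (TP + TN) / total
    DSC       = 2|G n S| / (|G| + |S|)

Zero-denominator ratios are reported as flagged ``None`` rather than being
coerced to 0, because silent zeros bias batch averages.  Two empty masks
score DSC 1 (a correct "no tumor" call) with an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["MetricsReport", "dice", "evaluate_pair", "summarize_runs"]


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError(f"{name} is not binary; found values {vals[:5]}")
    return arr.astype(bool)


@dataclass
class MetricsReport:
    """Confusion counts plus the four derived ratios for one mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    accuracy: float
    dsc: float
    flags: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "dsc": self.dsc,
            "flags": ";".join(self.flags),
        }


def dice(G: np.ndarray, S: np.ndarray) -> float:
    """Dice similarity coefficient 2|G n S| / (|G| + |S|).

    Symmetric in its arguments.  When both masks are empty there is no
    overlap to measure and the correct-rejection convention (1.0) applies;
    use :func:`evaluate_pair` to see the flag.
    """
    g = _as_binary(G, "reference mask")
    s = _as_binary(S, "predicted mask")
    if g.shape != s.shape:
        raise ValidationError(f"mask shapes differ: {g.shape} vs {s.shape}")
    denom = int(g.sum()) + int(s.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((g & s).sum()) / denom


def evaluate_pair(G: np.ndarray, S: np.ndarray) -> MetricsReport:
    """Full pixel-level report for a (reference, prediction) mask pair."""
    g = _as_binary(G, "reference mask")
    s = _as_binary(S, "predicted mask")
    if g.shape != s.shape:
        raise ValidationError(f"mask shapes differ: {g.shape} vs {s.shape}")

    tp = int((g & s).sum())
    fp = int((~g & s).sum())
    fn = int((g & ~s).sum())
    tn = int((~g & ~s).sum())

    flags: list[str] = []
    precision: float | None
    recall: float | None
    if tp + fp == 0:
        precision = None
        flags.append("precision_undefined")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = None
        flags.append("recall_undefined")
    else:
        recall = tp / (tp + fn)
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    if 2 * tp + fp + fn == 0:
        dsc = 1.0
        flags.append("both_masks_empty")
    else:
        dsc = 2 * tp / (2 * tp + fp + fn)
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, accuracy=accuracy, dsc=dsc,
        flags=flags,
    )


def summarize_runs(
    reports: Sequence[MetricsReport | Mapping],
    grouping: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean/median DSC (and mean accuracy) per group.

    ``grouping`` assigns each report a group key (e.g. a contrast stratum or
    before/after post-processing); with no grouping everything lands in one
    row.  Empty inputs are rejected; the result is order-invariant.
    """
    if len(reports) == 0:
        raise ValidationError("no reports to summarize")
    rows = []
    for i, rep in enumerate(reports):
        d = rep.to_dict() if isinstance(rep, MetricsReport) else dict(rep)
        d["group"] = grouping[i] if grouping is not None else "all"
        rows.append(d)
    df = pd.DataFrame(rows)
    out = (
        df.groupby("group", sort=True)
        .agg(
            n=("dsc", "size"),
            mean_dsc=("dsc", "mean"),
            median_dsc=("dsc", "median"),
            mean_accuracy=("accuracy", "mean"),
        )
        .reset_index()
    )
    return out
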