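"""Kinome-panel evaluation of ranked off-target predictions.

Ground truth comes from a competition-binding panel: a kinase counts as a
true off-target when its %control under the high-dose treatment falls below
a threshold (default 30.0, strict).  Predictions ranked in the top k% of
the panel (k = ceil(fraction * panel size), default 2.5%) are called
positive, and the resulting 2x2 confusion table yields precision, recall
and false-positive rate, reported as percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "KinomeAssayRecord",
    "ConfusionCounts",
    "truth_from_kinome",
    "topk_cut",
    "confusion",
    "precision_recall_fpr",
    "round_sig",
    "TRUTH_PCT_CONTROL",
    "TOP_FRACTION",
]

TRUTH_PCT_CONTROL = 30.0
TOP_FRACTION = 0.025


@dataclass(frozen=True)
class KinomeAssayRecord:
    """%control of one kinase at the low and high assay doses."""

    kinase: str
    pct_control_10uM: float
    pct_control_100uM: float

    def __post_init__(self) -> None:
        for v in (self.pct_control_10uM, self.pct_control_100uM):
            if not (v == v and v >= 0 and v != float("inf")):
                raise ValueError(f"%control must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def panel_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def truth_from_kinome(
    records: Iterable[KinomeAssayRecord], threshold: float = TRUTH_PCT_CONTROL
) -> dict[str, bool]:
    """True off-target iff %control at the high dose is strictly below
    ``threshold``."""
    return {r.kinase: r.pct_control_100uM < threshold for r in records}


def topk_cut(
    ranked: Sequence[str], fraction: float = TOP_FRACTION, panel_size: int | None = None
) -> list[str]:
    """The top k = ceil(fraction * panel_size) entries of a ranked list."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    panel = panel_size if panel_size is not None else len(ranked)
    k = math.ceil(fraction * panel)
    if k == 0:
        raise ValueError(f"fraction {fraction} of panel {panel} selects no predictions")
    return list(ranked[:k])


def confusion(predicted: Iterable[str], truth: Mapping[str, bool]) -> ConfusionCounts:
    """2x2 confusion counts of a predicted-positive set against the panel
    truth map; every prediction must belong to the panel."""
    predicted = set(predicted)
    outside = predicted - set(truth)
    if outside:
        raise ValueError(f"predictions outside the panel: {sorted(outside)[:5]}")
    tp = sum(1 for k in predicted if truth[k])
    fp = len(predicted) - tp
    pos = sum(1 for v in truth.values() if v)
    fn = pos - tp
    tn = len(truth) - pos - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def precision_recall_fpr(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and FPR in percent; a zero denominator reports 0."""
    if counts.panel_size == 0:
        raise ValueError("all confusion counts are zero")
    pp = counts.tp + counts.fp
    pos = counts.tp + counts.fn
    neg = counts.fp + counts.tn
    precision = counts.tp / pp * 100.0 if pp else 0.0
    recall = counts.tp / pos * 100.0 if pos else 0.0
    fpr = counts.fp / neg * 100.0 if neg else 0.0
    return precision, recall, fpr


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))
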