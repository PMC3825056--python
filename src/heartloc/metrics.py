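"""Per-sample and per-event scoring of predicted segments against truth.

Per-sample scoring tabulates each sample into TP/FP/FN/TN and reports

    FNR = 100 * FN / (FN + TP)      FPR = 100 * FP / (FP + TN)
    ACC = 100 * (TP + TN) / n       DER = 100 * (FP + FN) / n

so ACC + DER == 100 identically.  Ratios with a zero denominator are
reported as ``None`` (not-applicable), never silently 0.  Per-event scoring
counts a true segment as detected when any predicted segment overlaps it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .localize import SegmentSet

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "segments_to_mask",
    "confusion_counts",
    "event_confusion",
    "compute_metrics",
    "evaluate_segments",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies (per-sample: they sum to the record length)."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ParameterError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """FNR/FPR/ACC/DER percentages; a ``None`` rate means undefined."""

    fnr_pct: float | None
    fpr_pct: float | None
    acc_pct: float
    der_pct: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "FNR": self.fnr_pct,
            "FPR": self.fpr_pct,
            "ACC": self.acc_pct,
            "DER": self.der_pct,
        }


def segments_to_mask(segs: SegmentSet, n: int) -> np.ndarray:
    """Binary per-sample mask: 1 inside any segment, else 0."""
    if segs.n > n:
        raise ParameterError(f"SegmentSet length {segs.n} exceeds mask length {n}")
    mask = np.zeros(n, dtype=np.uint8)
    for seg in segs:
        mask[seg.start : seg.end] = 1
    return mask


def confusion_counts(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Per-sample 2x2 tabulation of prediction against truth."""
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ParameterError(
            f"mask length mismatch: {pred.shape} vs {truth.shape}"
        )
    return ConfusionCounts(
        TP=int(np.sum(pred & truth)),
        TN=int(np.sum(~pred & ~truth)),
        FP=int(np.sum(pred & ~truth)),
        FN=int(np.sum(~pred & truth)),
    )


def event_confusion(pred: SegmentSet, truth: SegmentSet) -> ConfusionCounts:
    """Segment-level tabulation: overlap of any extent counts as detection.

    TP = true segments overlapped by some prediction, FN = true segments
    missed, FP = predicted segments overlapping no true segment.  TN has no
    event-level meaning and is reported as 0.
    """

    def overlaps(a, b) -> bool:
        return a.start < b.end and b.start < a.end

    tp = sum(1 for t in truth if any(overlaps(t, p) for p in pred))
    fn = len(truth) - tp
    fp = sum(1 for p in pred if not any(overlaps(p, t) for t in truth))
    return ConfusionCounts(TP=tp, TN=0, FP=fp, FN=fn)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Derive the four percentage rates from confusion counts."""
    n = counts.n
    if n == 0:
        raise DegenerateInputError("cannot compute metrics on zero samples")
    fnr = 100.0 * counts.FN / (counts.FN + counts.TP) if counts.FN + counts.TP else None
    fpr = 100.0 * counts.FP / (counts.FP + counts.TN) if counts.FP + counts.TN else None
    acc = 100.0 * (counts.TP + counts.TN) / n
    der = 100.0 * (counts.FP + counts.FN) / n
    return MetricsReport(fnr_pct=fnr, fpr_pct=fpr, acc_pct=acc, der_pct=der,
                         counts=counts)


def evaluate_segments(
    pred: SegmentSet, truth: SegmentSet, n: int, per_event: bool = False
) -> MetricsReport:
    """Score predicted against true segments on a record of length ``n``."""
    if per_event:
        counts = event_confusion(pred, truth)
    else:
        counts = confusion_counts(
            segments_to_mask(pred, n), segments_to_mask(truth, n)
        )
    return compute_metrics(counts)
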