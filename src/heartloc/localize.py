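"""Heart-sound peak selection and boundary estimation — the full pipeline.

Candidate peaks are scored by triangle area; a peak is kept when its area
exceeds an adaptive threshold derived from the spread of the whole area
vector.  Each kept peak spans its flanking minima, and adjacent spans that
share a minimum merge into one segment.  ``localize_hs`` chains all stages:
normalize -> low-pass -> Hilbert envelope -> smooth -> extrema -> peaks ->
areas -> threshold -> selection -> boundaries.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .envelope import hilbert_envelope, smooth_envelope
from .errors import DegenerateInputError, ParameterError
from .heron_area import AreaVector, area_vector
from .peaks import PeakTriple, find_extrema, form_peaks
from .preprocess import lowpass_hs_enhance, normalize_amplitude
from .signal_io import RunConfig, Signal

__all__ = [
    "HSSegment",
    "SegmentSet",
    "adaptive_threshold",
    "select_hs_peaks",
    "estimate_boundaries",
    "localize_hs",
    "write_segments_csv",
    "read_segments_csv",
]

SEGMENT_CSV_COLUMNS = [
    "start_sample",
    "end_sample",
    "start_sec",
    "end_sec",
    "peak_sample",
    "area",
]


@dataclasses.dataclass(frozen=True)
class HSSegment:
    """One detected heart-sound region, a half-open sample interval."""

    start: int  # inclusive
    end: int  # exclusive
    peak: int  # sample index of the event maximum
    area: float  # triangle area of the (dominant) peak

    def __post_init__(self) -> None:
        if not self.start <= self.peak < self.end:
            raise ParameterError(
                f"segment requires start <= peak < end, got "
                f"[{self.start}, {self.end}) peak {self.peak}"
            )


@dataclasses.dataclass(frozen=True)
class SegmentSet:
    """Sorted, non-overlapping segments within a record of length ``n``."""

    segments: tuple
    n: int

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        prev_end = 0
        for seg in segs:
            if seg.start < prev_end or seg.end > self.n:
                raise ParameterError("segments must be sorted, disjoint, in range")
            prev_end = seg.end
        object.__setattr__(self, "segments", segs)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def adaptive_threshold(
    areas: AreaVector, scale: float = 1.0, stat: str = "std"
) -> float:
    """Threshold from the spread of the area vector.

    ``stat="std"`` (default) uses the population standard deviation, which
    keeps the decision rule invariant under a global rescaling of the
    record; ``stat="var"`` uses the population variance.  ``scale``
    multiplies the chosen statistic.
    """
    if len(areas) == 0:
        raise DegenerateInputError("cannot threshold an empty area vector")
    var = float(np.var(areas.areas))  # population (1/N) variance
    if stat == "var":
        return scale * var
    if stat == "std":
        return scale * float(np.sqrt(var))
    raise ParameterError(f"unknown threshold stat {stat!r}")


def select_hs_peaks(
    peaks: Sequence[PeakTriple], areas: AreaVector, threshold: float
) -> List[int]:
    """Indices of peaks whose area strictly exceeds the threshold."""
    if len(peaks) != len(areas):
        raise ParameterError("peaks and areas must have equal length")
    return [i for i, a in enumerate(areas.areas) if a > threshold]


def estimate_boundaries(
    peaks: Sequence[PeakTriple], selected: Sequence[int], n: int
) -> SegmentSet:
    """Segment each selected peak from its left minimum to its right minimum.

    Adjacent selected peaks share their boundary minimum; their spans are
    merged into a single segment carrying the larger-area peak.
    """
    raw: List[HSSegment] = []
    for i in selected:
        p = peaks[i]
        tri_area = _peak_area(p)
        raw.append(
            HSSegment(
                start=p.left_min[0],
                end=min(p.right_min[0] + 1, n),
                peak=p.max[0],
                area=tri_area,
            )
        )
    raw.sort(key=lambda s: s.start)

    merged: List[HSSegment] = []
    for seg in raw:
        if merged and seg.start < merged[-1].end:
            prev = merged[-1]
            keep = prev if prev.area >= seg.area else seg
            merged[-1] = HSSegment(
                start=prev.start,
                end=max(prev.end, seg.end),
                peak=keep.peak,
                area=keep.area,
            )
        else:
            merged.append(seg)
    return SegmentSet(segments=tuple(merged), n=n)


def _peak_area(peak: PeakTriple) -> float:
    from .heron_area import heron_area_of, triangle_from_peak

    return heron_area_of(triangle_from_peak(peak))


def localize_hs(signal: Signal, config: RunConfig | None = None) -> SegmentSet:
    """Run the full localization pipeline on one recording.

    Deterministic for a fixed input and config.  A silent (all-zero) record
    returns an empty SegmentSet; a record shorter than three smoothing time
    constants raises, since no stable envelope minima can form.
    """
    if config is None:
        config = RunConfig()
    config.validate_for_rate(signal.rate)

    min_samples = int(3 * signal.rate / config.smooth_cutoff_hz)
    if signal.n < max(min_samples, 3):
        raise ParameterError(
            f"signal of {signal.n} samples is too short for smoothing at "
            f"{config.smooth_cutoff_hz} Hz (need >= {min_samples})"
        )
    if not np.any(signal.samples):
        return SegmentSet(segments=(), n=signal.n)

    norm = normalize_amplitude(signal)
    filtered = lowpass_hs_enhance(
        norm,
        cutoff_hz=config.hs_filter_cutoff_hz,
        order=config.hs_filter_order,
        mode=config.filter_mode,
    )
    env = hilbert_envelope(filtered)
    smooth = smooth_envelope(
        env, cutoff_hz=config.smooth_cutoff_hz, order=config.smooth_order
    )
    extrema = find_extrema(smooth)
    peaks = form_peaks(extrema)
    if not peaks:
        return SegmentSet(segments=(), n=signal.n)
    areas = area_vector(peaks, x_scale=config.x_scale, y_scale=config.y_scale)
    threshold = adaptive_threshold(
        areas, scale=config.threshold_scale, stat=config.threshold_stat
    )
    selected = select_hs_peaks(peaks, areas, threshold)
    return estimate_boundaries(peaks, selected, signal.n)


def write_segments_csv(segs: SegmentSet, rate: float, path: str | Path) -> None:
    """Write segments as CSV with sample and second units plus peak/area."""
    rows = [
        {
            "start_sample": s.start,
            "end_sample": s.end,
            "start_sec": s.start / rate,
            "end_sec": s.end / rate,
            "peak_sample": s.peak,
            "area": s.area,
        }
        for s in segs
    ]
    pd.DataFrame(rows, columns=SEGMENT_CSV_COLUMNS).to_csv(path, index=False)


def read_segments_csv(path: str | Path, n: int) -> SegmentSet:
    """Read a segments CSV back into a SegmentSet for a record of length n."""
    df = pd.read_csv(path)
    segs = tuple(
        HSSegment(
            start=int(r.start_sample),
            end=int(r.end_sample),
            peak=int(r.peak_sample),
            area=float(r.area),
        )
        for r in df.itertuples()
    )
    return SegmentSet(segments=segs, n=n)
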