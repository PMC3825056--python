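"""Local-extrema detection on the smoothed envelope and peak assembly.

Extrema are the samples where the first difference of the envelope changes
sign.  A plateau (run of equal values) contributes a single extremum at its
first sample.  Record endpoints are appended as minima when needed so that
every maximum has flanking minima, and each maximum together with its two
flanking minima forms one candidate peak; consecutive peaks share their
boundary minimum.
"""

from __future__ import annotations

import dataclasses
from typing import List, Tuple

import numpy as np

from .envelope import EnvelopeCurve
from .errors import ParameterError

__all__ = ["MIN", "MAX", "ExtremaSequence", "PeakTriple", "find_extrema", "form_peaks"]

MIN = "min"
MAX = "max"


@dataclasses.dataclass(frozen=True)
class ExtremaSequence:
    """Strictly increasing extremum positions with alternating kinds."""

    indices: np.ndarray  # int sample positions
    kinds: Tuple[str, ...]  # parallel labels in {MIN, MAX}
    values: np.ndarray  # envelope values at indices

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        if not (idx.size == len(self.kinds) == vals.size):
            raise ParameterError("indices, kinds and values must be parallel")
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ParameterError("extremum indices must be strictly increasing")
        for a, b in zip(self.kinds, self.kinds[1:]):
            if a == b:
                raise ParameterError("extremum kinds must alternate")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kinds", tuple(self.kinds))

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclasses.dataclass(frozen=True)
class PeakTriple:
    """One candidate event: (left minimum, maximum, right minimum)."""

    left_min: Tuple[int, float]
    max: Tuple[int, float]
    right_min: Tuple[int, float]

    def __post_init__(self) -> None:
        if not self.left_min[0] < self.max[0] < self.right_min[0]:
            raise ParameterError("peak extrema must be ordered left < max < right")
        if self.max[1] < self.left_min[1] or self.max[1] < self.right_min[1]:
            raise ParameterError("maximum value must dominate flanking minima")


def find_extrema(env: EnvelopeCurve) -> ExtremaSequence:
    """Locate alternating minima/maxima of a smoothed envelope.

    A constant envelope yields an empty sequence (no sign changes).
    """
    if not env.smoothed:
        raise ParameterError("extrema are detected on the smoothed envelope")
    v = env.values
    if v.size < 3:
        raise ParameterError("need at least 3 samples to detect extrema")

    d = np.diff(v)
    nz = np.flatnonzero(d)
    if nz.size == 0:  # constant envelope
        return ExtremaSequence(np.empty(0, dtype=np.int64), (), np.empty(0))
    signs = np.sign(d[nz])
    change = np.flatnonzero(signs[:-1] != signs[1:])
    # extremum sits one past the last sample of the preceding monotone run,
    # i.e. at a plateau's first sample
    indices = (nz[change] + 1).tolist()
    kinds = [MAX if signs[k] > 0 else MIN for k in change]

    if kinds and kinds[0] == MAX and indices[0] > 0:
        indices.insert(0, 0)
        kinds.insert(0, MIN)
    if kinds and kinds[-1] == MAX and indices[-1] < v.size - 1:
        indices.append(v.size - 1)
        kinds.append(MIN)

    idx = np.asarray(indices, dtype=np.int64)
    return ExtremaSequence(indices=idx, kinds=tuple(kinds), values=v[idx])


def form_peaks(extrema: ExtremaSequence) -> List[PeakTriple]:
    """Assemble one PeakTriple per maximum from its flanking minima."""
    peaks: List[PeakTriple] = []
    for k, kind in enumerate(extrema.kinds):
        if kind != MAX:
            continue
        if k == 0 or k == len(extrema) - 1:
            raise ParameterError("maximum without flanking minima")
        peaks.append(
            PeakTriple(
                left_min=(int(extrema.indices[k - 1]), float(extrema.values[k - 1])),
                max=(int(extrema.indices[k]), float(extrema.values[k])),
                right_min=(int(extrema.indices[k + 1]), float(extrema.values[k + 1])),
            )
        )
    return peaks
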