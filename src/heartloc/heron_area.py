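"""Triangle geometry and area scoring of candidate peaks.

Each candidate peak defines a scalene triangle whose vertices are its two
flanking minima and its maximum, in (sample-index * x_scale,
envelope-value * y_scale) coordinates.  Sides are Euclidean distances,
angles follow the law of cosines, and the score is the triangle's area by
the semiperimeter formula: h = (u+v+w)/2, area = sqrt(h(h-u)(h-v)(h-w)).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .peaks import PeakTriple

__all__ = [
    "TriangleGeometry",
    "AreaVector",
    "triangle_from_peak",
    "heron_area_of",
    "area_vector",
]

# cross products below this fraction of the squared scale flag degeneracy
_DEGENERATE_REL_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class TriangleGeometry:
    """Sides, interior angles and vertex coordinates of one peak triangle.

    ``a`` is the left lateral side, ``b`` the right lateral side and ``c``
    the base (left minimum to right minimum).  ``degenerate`` marks
    collinear vertices; such triangles score area 0 rather than raising.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    vertices: tuple
    degenerate: bool = False

    @property
    def sides(self) -> tuple:
        return (self.a, self.b, self.c)


@dataclasses.dataclass(frozen=True)
class AreaVector:
    """Peak areas in temporal order; input to the adaptive threshold."""

    areas: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=np.float64)
        if areas.ndim != 1:
            raise ValueError("areas must be 1-D")
        if np.any(areas < 0):
            raise ValueError("areas must be nonnegative")
        object.__setattr__(self, "areas", areas)

    def __len__(self) -> int:
        return int(self.areas.size)


def _angle(opposite: float, s1: float, s2: float) -> float:
    """Interior angle opposite a side, by the law of cosines (clipped acos)."""
    denom = 2.0 * s1 * s2
    if denom == 0.0:
        return 0.0
    cos_val = (s1 * s1 + s2 * s2 - opposite * opposite) / denom
    return math.acos(min(1.0, max(-1.0, cos_val)))


def triangle_from_peak(
    peak: PeakTriple, x_scale: float = 1.0, y_scale: float = 1.0
) -> TriangleGeometry:
    """Build the scalene triangle spanned by a peak's three extrema."""
    p1 = (peak.left_min[0] * x_scale, peak.left_min[1] * y_scale)
    p2 = (peak.max[0] * x_scale, peak.max[1] * y_scale)
    p3 = (peak.right_min[0] * x_scale, peak.right_min[1] * y_scale)

    a = math.hypot(p2[0] - p1[0], p2[1] - p1[1])  # left lateral
    b = math.hypot(p3[0] - p2[0], p3[1] - p2[1])  # right lateral
    c = math.hypot(p3[0] - p1[0], p3[1] - p1[1])  # base

    cross = abs(
        (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p3[0] - p1[0]) * (p2[1] - p1[1])
    )
    scale_sq = max(a, b, c) ** 2
    degenerate = scale_sq == 0.0 or cross <= _DEGENERATE_REL_TOL * scale_sq

    alpha = _angle(a, b, c)
    beta = _angle(b, a, c)
    gamma = _angle(c, a, b)
    return TriangleGeometry(
        a=a, b=b, c=c, alpha=alpha, beta=beta, gamma=gamma,
        vertices=(p1, p2, p3), degenerate=degenerate,
    )


def heron_area_of(tri: TriangleGeometry) -> float:
    """Area from side lengths via the semiperimeter.

    Floating error on near-degenerate triangles can make the radicand
    slightly negative; it is clamped to 0 (area is nonnegative).
    """
    # Kahan's stable evaluation of the same radicand: the naive
    # h(h-u)(h-v)(h-w) product cancels catastrophically on the needle-like
    # triangles that flat envelope stretches produce.
    u, v, w = sorted((tri.a, tri.b, tri.c), reverse=True)  # u >= v >= w
    radicand = (u + (v + w)) * (w - (u - v)) * (w + (u - v)) * (u + (v - w))
    return 0.25 * math.sqrt(max(radicand, 0.0))


def area_vector(
    peaks: Sequence[PeakTriple], x_scale: float = 1.0, y_scale: float = 1.0
) -> AreaVector:
    """Score every peak by its triangle area, preserving temporal order."""
    areas = np.array(
        [heron_area_of(triangle_from_peak(p, x_scale, y_scale)) for p in peaks],
        dtype=np.float64,
    )
    return AreaVector(areas=areas)
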