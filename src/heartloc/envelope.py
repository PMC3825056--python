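"""Discrete Hilbert envelope extraction and envelope smoothing.

The analytic signal is built by the DFT construction: take the DFT of the
real input, keep DC (and, for even length, the Nyquist bin), double the
positive-frequency bins, zero the negative-frequency bins, and invert.  The
even- and odd-length spectral weightings differ only in the Nyquist bin,
which exists only for even record lengths.  The envelope is the magnitude of
the analytic signal and the instantaneous phase its angle.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .preprocess import lowpass_filter
from .signal_io import Signal

__all__ = [
    "AnalyticSeries",
    "EnvelopeCurve",
    "analytic_signal",
    "hilbert_envelope",
    "instantaneous_phase",
    "smooth_envelope",
]


@dataclasses.dataclass(frozen=True)
class AnalyticSeries:
    """Real input and its discrete Hilbert transform as a complex pair."""

    real_part: np.ndarray
    imag_part: np.ndarray

    def __post_init__(self) -> None:
        re = np.asarray(self.real_part, dtype=np.float64)
        im = np.asarray(self.imag_part, dtype=np.float64)
        if re.shape != im.shape or re.ndim != 1:
            raise ParameterError("real and imaginary parts must be equal-length 1-D")
        object.__setattr__(self, "real_part", re)
        object.__setattr__(self, "imag_part", im)

    @property
    def n(self) -> int:
        return int(self.real_part.size)

    @property
    def complex_values(self) -> np.ndarray:
        return self.real_part + 1j * self.imag_part


@dataclasses.dataclass(frozen=True)
class EnvelopeCurve:
    """Nonnegative envelope samples aligned 1:1 with a source signal."""

    values: np.ndarray
    rate: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ParameterError("envelope values must be 1-D")
        if np.any(values < 0):
            raise ParameterError("envelope values must be nonnegative")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)


def _analytic_weights(n: int) -> np.ndarray:
    """Spectral weights of the analytic-signal construction for length ``n``.

    Even n keeps DC and Nyquist at unit weight; odd n has no Nyquist bin.
    """
    h = np.zeros(n)
    if n % 2 == 0:
        h[0] = 1.0
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[0] = 1.0
        h[1 : (n + 1) // 2] = 2.0
    return h


def analytic_signal(signal: Signal) -> AnalyticSeries:
    """Compute x + j*H{x} via the DFT construction.

    Raises
    ------
    DegenerateInputError
        If the record holds fewer than 2 samples.
    """
    x = signal.samples
    if x.size < 2:
        raise DegenerateInputError("analytic signal needs at least 2 samples")
    spectrum = np.fft.fft(x)
    analytic = np.fft.ifft(spectrum * _analytic_weights(x.size))
    return AnalyticSeries(real_part=analytic.real, imag_part=analytic.imag)


def hilbert_envelope(signal: Signal) -> EnvelopeCurve:
    """Envelope as the magnitude of the analytic signal."""
    analytic = analytic_signal(signal)
    env = np.hypot(analytic.real_part, analytic.imag_part)
    return EnvelopeCurve(values=env, rate=signal.rate, smoothed=False)


def instantaneous_phase(analytic: AnalyticSeries) -> np.ndarray:
    """Instantaneous phase in (-pi, pi] of each analytic sample."""
    return np.arctan2(analytic.imag_part, analytic.real_part)


def smooth_envelope(
    env: EnvelopeCurve,
    cutoff_hz: float = 15.0,
    order: int = 5,
) -> EnvelopeCurve:
    """Low-pass filter the envelope (zero-phase) for stable peak detection.

    Filter ringing can push samples slightly negative near silent stretches;
    such values are clamped to 0 so the nonnegativity invariant holds.
    """
    if env.smoothed:
        raise ParameterError("envelope is already smoothed")
    smoothed = lowpass_filter(env.values, env.rate, cutoff_hz, order, "zerophase")
    return EnvelopeCurve(
        values=np.maximum(smoothed, 0.0), rate=env.rate, smoothed=True
    )
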