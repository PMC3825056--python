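"""Audio I/O, run configuration, and the core :class:`Signal` container.

All processing modules operate on :class:`Signal` objects: mono, uniformly
sampled, finite-valued float arrays with an attached sample rate.  Files are
read and written as 16-bit PCM little-endian mono RIFF WAV; the rate is taken
from the file header, so recordings at any rate are accepted and Nyquist
checks downstream are derived from it.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from scipy.io import wavfile

from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = ["Signal", "RunConfig", "read_wav", "write_wav", "load_config"]

#: integer full-scale used for the int16 <-> float conversion
_INT16_SCALE = 32768.0


@dataclasses.dataclass(frozen=True)
class Signal:
    """A mono, uniformly sampled audio signal.

    Parameters
    ----------
    samples
        Real-valued amplitude sequence; coerced to a float64 array.
    rate
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ParameterError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 1:
            raise DegenerateInputError("signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("signal contains non-finite samples")
        if not self.rate > 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def n(self) -> int:
        """Number of samples."""
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n / self.rate

    def replace_samples(self, samples: np.ndarray) -> "Signal":
        """Return a new Signal with the same rate and new samples."""
        return Signal(samples=samples, rate=self.rate)


@dataclasses.dataclass
class RunConfig:
    """Tunable parameters of the localization pipeline.

    Defaults follow the reference operating point: a 10th-order 150 Hz
    low-pass to emphasize heart sounds, a 5th-order envelope smoother with
    cutoff in the 7-25 Hz band (15 Hz default), and an adaptive area
    threshold derived from the spread of the peak-area vector.
    """

    hs_filter_cutoff_hz: float = 150.0
    hs_filter_order: int = 10
    smooth_cutoff_hz: float = 15.0
    smooth_order: int = 5
    threshold_scale: float = 1.0
    threshold_stat: str = "std"  # "std" or "var" of the area vector
    filter_mode: str = "zerophase"  # "zerophase" or "single"
    x_scale: float = 1.0  # triangle x-axis units per sample index
    y_scale: float = 1.0  # triangle y-axis units per envelope unit
    seed: int | None = None

    _SMOOTH_RANGE = (7.0, 25.0)

    def __post_init__(self) -> None:
        if self.threshold_scale <= 0:
            raise ParameterError("threshold_scale must be > 0")
        if self.threshold_stat not in ("std", "var"):
            raise ParameterError(f"unknown threshold_stat {self.threshold_stat!r}")
        if self.filter_mode not in ("zerophase", "single"):
            raise ParameterError(f"unknown filter_mode {self.filter_mode!r}")
        if self.hs_filter_order < 1 or self.smooth_order < 1:
            raise ParameterError("filter orders must be >= 1")
        lo, hi = self._SMOOTH_RANGE
        if not lo <= self.smooth_cutoff_hz <= hi:
            warnings.warn(
                f"smooth_cutoff_hz={self.smooth_cutoff_hz} outside the "
                f"recommended [{lo}, {hi}] Hz band",
                stacklevel=2,
            )

    def validate_for_rate(self, rate: float) -> None:
        """Check every cutoff against the Nyquist frequency of ``rate``."""
        nyq = rate / 2.0
        for name in ("hs_filter_cutoff_hz", "smooth_cutoff_hz"):
            cutoff = getattr(self, name)
            if not 0 < cutoff < nyq:
                raise ParameterError(
                    f"{name}={cutoff} must lie in (0, {nyq}) Hz for rate {rate}"
                )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        """Build a config from a flat mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file of flat key-value pairs."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"config file {path} must contain a mapping")
    return RunConfig.from_mapping(data)


def read_wav(path: str | Path) -> Signal:
    """Read a PCM WAV file into a :class:`Signal` scaled to [-1, 1].

    Multi-channel files are reduced to channel 0 with a warning.  Integer
    sample formats are divided by their full-scale value; float formats are
    passed through.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise FormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.ndim > 1:
        warnings.warn(
            f"{path} has {data.shape[1]} channels; using channel 0", stacklevel=2
        )
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _INT16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Signal(samples=samples, rate=float(rate))


def write_wav(signal: Signal, path: str | Path) -> None:
    """Write a :class:`Signal` as 16-bit PCM mono WAV at ``signal.rate``.

    Samples outside [-1, 1] are clipped with a warning.
    """
    path = Path(path)
    samples = signal.samples
    if np.any(np.abs(samples) > 1.0):
        warnings.warn(
            f"samples outside [-1, 1] clipped when writing {path}", stacklevel=2
        )
        samples = np.clip(samples, -1.0, 1.0)
    quantized = np.clip(
        np.round(samples * _INT16_SCALE), -32768, 32767
    ).astype(np.int16)
    try:
        wavfile.write(str(path), int(round(signal.rate)), quantized)
    except OSError as exc:
        raise OSError(f"cannot write WAV file {path}: {exc}") from exc
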