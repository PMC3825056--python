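"""Synthetic heart sounds, lung sounds, and convolutive mixtures.

Heart sounds are trains of amplitude-windowed damped sinusoids: S1 and S2
every cardiac cycle, with optional S3 (after S2), S4 (just before the next
S1) and a systolic murmur burst for the "abnormal" variant.  Lung sounds are
band-shaped Gaussian noise (20-1600 Hz, energy concentrated below 200 Hz)
amplitude-modulated by breathing, with added wheeze tones for the
"abnormal" variant.  Mixtures convolve each source with a random 4-tap FIR
filter: the heart-sound taps are normalized to unit Euclidean norm and the
lung-sound tap norm is drawn from a per-(mixture type, flow) range, so the
tap-norm ratio controls the breathing-flow stratum.

Ground truth marks, for every injected S1/S2/S3/S4 instance, the interval
where the component's amplitude window exceeds a small fraction of its peak
(the audible extent; the sub-percent window tails are below any annotation
floor).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ParameterError
from .localize import HSSegment, SegmentSet
from .signal_io import Signal

__all__ = [
    "ComponentSpec",
    "HeartSoundSpec",
    "MixtureSpec",
    "GroundTruth",
    "MixResult",
    "TABLE1_NORM_RANGES",
    "FLOWS",
    "MIXTURE_TYPES",
    "synth_heart_sound",
    "synth_lung_sound",
    "convolutive_mix",
    "make_mixture",
    "write_truth_csv",
    "read_truth_csv",
]

FLOWS = ("low", "medium", "high")
MIXTURE_TYPES = (
    "normal-normal",
    "normal-abnormal",
    "abnormal-normal",
    "abnormal-abnormal",
)

# Lung-filter tap-norm ranges per (LS type - HS type) mixture and flow
# stratum.  Open-ended "high" cells span (lower bound, 2 * lower bound].
TABLE1_NORM_RANGES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "normal-normal": {"low": (0.10, 0.80), "medium": (0.81, 3.10), "high": (3.10, 6.20)},
    "normal-abnormal": {"low": (0.10, 0.90), "medium": (0.91, 3.30), "high": (3.30, 6.60)},
    "abnormal-normal": {"low": (0.10, 1.58), "medium": (1.59, 3.28), "high": (3.28, 6.56)},
    "abnormal-abnormal": {"low": (0.10, 1.96), "medium": (1.97, 3.35), "high": (3.35, 6.70)},
}

#: fraction of a component's peak window amplitude that bounds its
#: ground-truth (audible) extent
TRUTH_AMPLITUDE_FRACTION = 0.12


@dataclasses.dataclass(frozen=True)
class ComponentSpec:
    """One heart-sound component per cardiac cycle."""

    name: str
    center_hz: float
    duration_s: float
    amplitude: float
    onset_s: float  # offset from cycle start


# Canonical timing: S1 opens the cycle, S2 after ~0.3 s of systole,
# S3 shortly after S2's end, S4 just before the next S1.  Frequencies sit
# in the 20-150 Hz heart-sound band.
DEFAULT_COMPONENTS: Dict[str, ComponentSpec] = {
    "S1": ComponentSpec("S1", center_hz=50.0, duration_s=0.120, amplitude=1.00, onset_s=0.02),
    "S2": ComponentSpec("S2", center_hz=70.0, duration_s=0.100, amplitude=0.90, onset_s=0.32),
    "S3": ComponentSpec("S3", center_hz=35.0, duration_s=0.080, amplitude=0.90, onset_s=0.46),
    "S4": ComponentSpec("S4", center_hz=30.0, duration_s=0.080, amplitude=0.90, onset_s=0.62),
}


@dataclasses.dataclass(frozen=True)
class HeartSoundSpec:
    """Parameters of a synthetic heart-sound train."""

    rate: float = 8000.0
    duration_s: float = 10.0
    cycle_s: float = 0.8
    components: Tuple[str, ...] = ("S1", "S2")
    murmur: bool = False
    component_specs: Tuple[ComponentSpec, ...] = ()

    def resolved_components(self) -> List[ComponentSpec]:
        overrides = {c.name: c for c in self.component_specs}
        out = []
        for name in self.components:
            if name in overrides:
                out.append(overrides[name])
            elif name in DEFAULT_COMPONENTS:
                out.append(DEFAULT_COMPONENTS[name])
            else:
                raise ParameterError(f"unknown heart-sound component {name!r}")
        return out

    def validate(self) -> None:
        comps = sorted(self.resolved_components(), key=lambda c: c.onset_s)
        for c in comps:
            if c.duration_s >= self.cycle_s:
                raise ParameterError(f"{c.name} duration exceeds the cardiac cycle")
            if c.onset_s + c.duration_s > self.cycle_s:
                raise ParameterError(f"{c.name} extends past the cycle end")
        for a, b in zip(comps, comps[1:]):
            if a.onset_s + a.duration_s > b.onset_s:
                raise ParameterError(
                    f"components {a.name} and {b.name} overlap within a cycle"
                )
        names = [c.name for c in comps]
        if "S3" in names and "S2" in names:
            s2, s3 = (next(c for c in comps if c.name == k) for k in ("S2", "S3"))
            if s3.onset_s < s2.onset_s + s2.duration_s:
                raise ParameterError("S3 must start after S2 ends")
        if "S4" in names and "S1" in names:
            s1, s4 = (next(c for c in comps if c.name == k) for k in ("S1", "S4"))
            if not s4.onset_s + s4.duration_s <= self.cycle_s:
                raise ParameterError("S4 must end before the next S1 onset")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """True heart-sound component extents with parallel S1-S4 labels."""

    segments: SegmentSet
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.labels):
            raise ParameterError("one label per ground-truth segment required")
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclasses.dataclass(frozen=True)
class MixtureSpec:
    """Convolutive-mixing parameters for one (mixture type, flow) cell."""

    flow: str
    mixture_type: str
    seed: int
    a_norm: float | None = None  # drawn from the table range when None

    def __post_init__(self) -> None:
        if self.flow not in FLOWS:
            raise ParameterError(f"flow must be one of {FLOWS}, got {self.flow!r}")
        if self.mixture_type not in MIXTURE_TYPES:
            raise ParameterError(
                f"mixture_type must be one of {MIXTURE_TYPES}, got {self.mixture_type!r}"
            )
        if self.a_norm is not None:
            lo, hi = TABLE1_NORM_RANGES[self.mixture_type][self.flow]
            if not lo <= self.a_norm <= hi:
                raise ParameterError(
                    f"a_norm={self.a_norm} outside [{lo}, {hi}] for "
                    f"{self.mixture_type}/{self.flow}"
                )

    def norm_range(self) -> Tuple[float, float]:
        return TABLE1_NORM_RANGES[self.mixture_type][self.flow]


@dataclasses.dataclass(frozen=True)
class MixResult:
    """A convolutive mixture plus the filters that produced it."""

    signal: Signal
    truth: GroundTruth | None
    a_taps: np.ndarray
    b_taps: np.ndarray
    a_norm: float


def _component_wave(comp: ComponentSpec, rate: float, rng: np.random.Generator):
    """Windowed damped sinusoid for one component instance.

    Returns (samples, truth_lo, truth_hi): the waveform and the half-open
    index range, relative to onset, where the window exceeds the audible
    fraction of its peak.
    """
    m = int(round(comp.duration_s * rate))
    t = np.arange(m) / rate
    window = np.hanning(m) * np.exp(-1.0 * t / comp.duration_s)
    phase = rng.uniform(0, 2 * np.pi)
    freq = comp.center_hz * rng.uniform(0.95, 1.05)
    wave = comp.amplitude * window * np.sin(2 * np.pi * freq * t + phase)
    audible = np.flatnonzero(window >= TRUTH_AMPLITUDE_FRACTION * window.max())
    return wave, int(audible[0]), int(audible[-1]) + 1


def synth_heart_sound(
    spec: HeartSoundSpec, seed: int | None = None
) -> Tuple[Signal, GroundTruth]:
    """Generate a heart-sound train with per-component ground truth.

    Each full cardiac cycle receives one instance of every component in the
    spec, with small per-cycle amplitude/frequency/phase jitter drawn from
    ``seed``.  The abnormal variant adds a 500-700 Hz murmur burst between
    S1 and S2 (not part of the S1-S4 ground truth).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.rate))
    samples = np.zeros(n)
    cycle_n = int(round(spec.cycle_s * spec.rate))
    n_cycles = n // cycle_n

    segments: List[HSSegment] = []
    labels: List[str] = []
    comps = sorted(spec.resolved_components(), key=lambda c: c.onset_s)
    for k in range(n_cycles):
        cycle_start = k * cycle_n
        for comp in comps:
            onset = cycle_start + int(round(comp.onset_s * spec.rate))
            wave, lo, hi = _component_wave(comp, spec.rate, rng)
            amp_jitter = rng.uniform(0.95, 1.05)
            end = min(onset + wave.size, n)
            if end <= onset:
                continue
            samples[onset:end] += amp_jitter * wave[: end - onset]
            seg_end = min(onset + hi, n)
            peak = min(onset + (lo + hi) // 2, seg_end - 1)
            segments.append(
                HSSegment(start=onset + lo, end=seg_end, peak=peak, area=0.0)
            )
            labels.append(comp.name)
        if spec.murmur:
            s1, s2 = comps[0], comps[1]
            m_start = cycle_start + int(
                round((s1.onset_s + s1.duration_s + 0.02) * spec.rate)
            )
            m_dur = int(round(max(s2.onset_s - s1.onset_s - s1.duration_s - 0.04, 0.05)
                              * spec.rate))
            m_end = min(m_start + m_dur, n)
            if m_end > m_start:
                burst = rng.standard_normal(m_end - m_start)
                sos = sps.butter(4, [500, 700], btype="band", fs=spec.rate,
                                 output="sos")
                burst = sps.sosfilt(sos, burst)
                rms = np.sqrt(np.mean(burst**2))
                if rms > 0:
                    burst *= 0.25 / rms
                samples[m_start:m_end] += np.hanning(m_end - m_start) * burst

    truth = GroundTruth(
        segments=SegmentSet(segments=tuple(segments), n=n), labels=tuple(labels)
    )
    return Signal(samples=samples, rate=spec.rate), truth


def synth_lung_sound(
    rate: float = 8000.0,
    duration_s: float = 10.0,
    breath_period_s: float = 3.0,
    abnormal: bool = False,
    seed: int | None = None,
) -> Signal:
    """Broadband breathing noise, unit RMS, band-limited to 20-1600 Hz.

    The spectrum is shaped directly in the frequency domain: full weight on
    20-200 Hz (where most lung-sound energy lives) and reduced weight on
    200-1600 Hz, zero elsewhere.  The result is amplitude-modulated by an
    inspiration/expiration envelope; the abnormal variant superposes
    breath-gated wheeze tones.
    """
    if duration_s < breath_period_s:
        raise ParameterError("duration must cover at least one breath period")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    gain = np.zeros(freqs.size)
    gain[(freqs >= 20) & (freqs < 200)] = 1.0
    gain[(freqs >= 200) & (freqs <= 1600)] = 0.25
    spectrum = gain * (rng.standard_normal(freqs.size)
                       + 1j * rng.standard_normal(freqs.size))
    noise = np.fft.irfft(spectrum, n=n)

    t = np.arange(n) / rate
    breath = 0.35 + 0.65 * np.sin(np.pi * t / breath_period_s) ** 2
    samples = noise * breath
    if abnormal:
        for f0 in (400.0, 560.0):
            tone = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
            samples += 0.3 * np.std(noise) * breath * tone
    rms = np.sqrt(np.mean(samples**2))
    return Signal(samples=samples / rms, rate=rate)


def _draw_taps(rng: np.random.Generator, norm: float) -> np.ndarray:
    """Random nonnegative 4-tap filter rescaled to the requested norm.

    Taps are drawn half-normal: a sign-mixed draw can form a near-perfect
    differencer whose response vanishes over the 20-150 Hz band and erases
    a source from the mixture, which no physical recording path does.
    """
    taps = np.abs(rng.standard_normal(4))
    taps_norm = np.linalg.norm(taps)
    if taps_norm == 0:
        taps = np.array([1.0, 0.0, 0.0, 0.0])
        taps_norm = 1.0
    return taps * (norm / taps_norm)


def convolutive_mix(
    hs: Signal,
    ls: Signal,
    spec: MixtureSpec,
    truth: GroundTruth | None = None,
    a_taps: np.ndarray | None = None,
    b_taps: np.ndarray | None = None,
) -> MixResult:
    """Mix filtered sources: mixture = a_taps * ls + b_taps * hs (FIR).

    When not supplied explicitly, ``b_taps`` is drawn with unit Euclidean
    norm and ``a_taps`` with a norm drawn uniformly from the mixture's
    (type, flow) range.  Explicit taps are used exactly as given.  Ground
    truth passes through untouched: the <= 3-sample filter delay is left to
    evaluation tolerances.
    """
    if hs.rate != ls.rate:
        raise ParameterError(f"rate mismatch: hs {hs.rate} vs ls {ls.rate}")
    if hs.n != ls.n:
        raise ParameterError(f"length mismatch: hs {hs.n} vs ls {ls.n}")
    rng = np.random.default_rng(spec.seed)
    if a_taps is None:
        if spec.a_norm is not None:
            a_norm = float(spec.a_norm)
        else:
            lo, hi = spec.norm_range()
            a_norm = float(rng.uniform(lo, hi))
        a_taps = _draw_taps(rng, a_norm)
    else:
        a_taps = np.asarray(a_taps, dtype=np.float64)
        a_norm = float(np.linalg.norm(a_taps))
    if b_taps is None:
        b_taps = _draw_taps(rng, 1.0)
    else:
        b_taps = np.asarray(b_taps, dtype=np.float64)

    mixture = sps.lfilter(a_taps, [1.0], ls.samples) + sps.lfilter(
        b_taps, [1.0], hs.samples
    )
    return MixResult(
        signal=Signal(samples=mixture, rate=hs.rate),
        truth=truth,
        a_taps=a_taps,
        b_taps=b_taps,
        a_norm=a_norm,
    )


#: pre-mix lung-sound RMS relative to the unit heart-sound peak amplitude;
#: with the tap norms of the high-flow cells this puts lung and heart
#: sounds at comparable level, and leaves the heart dominant at low flow
LS_BASE_RMS = 0.012


def make_mixture(
    mixture_type: str,
    flow: str,
    duration_s: float = 10.0,
    seed: int = 0,
    rate: float = 8000.0,
) -> MixResult:
    """End-to-end generator for one labelled synthetic mixture.

    ``mixture_type`` is "<lung type>-<heart type>"; an abnormal heart sound
    carries a murmur plus an S3 or S4 gallop component (chosen by seed), an
    abnormal lung sound carries wheezes.
    """
    if mixture_type not in MIXTURE_TYPES:
        raise ParameterError(f"unknown mixture type {mixture_type!r}")
    ls_kind, hs_kind = mixture_type.split("-")
    rng = np.random.default_rng(seed)
    hs_seed, ls_seed, mix_seed = (int(s) for s in rng.integers(0, 2**31, 3))

    if hs_kind == "abnormal":
        extra = "S3" if rng.integers(2) == 0 else "S4"
        components: Tuple[str, ...] = ("S1", "S2", extra)
        murmur = True
    else:
        components = ("S1", "S2")
        murmur = False
    hs_spec = HeartSoundSpec(
        rate=rate, duration_s=duration_s, components=components, murmur=murmur
    )
    hs, truth = synth_heart_sound(hs_spec, seed=hs_seed)
    ls = synth_lung_sound(
        rate=rate,
        duration_s=duration_s,
        abnormal=(ls_kind == "abnormal"),
        seed=ls_seed,
    )
    ls = ls.replace_samples(ls.samples * LS_BASE_RMS)
    mix_spec = MixtureSpec(flow=flow, mixture_type=mixture_type, seed=mix_seed)
    return convolutive_mix(hs, ls, mix_spec, truth=truth)


def write_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    """Write ground truth as CSV: start_sample, end_sample, label."""
    rows = [
        {"start_sample": s.start, "end_sample": s.end, "label": lab}
        for s, lab in zip(truth.segments, truth.labels)
    ]
    pd.DataFrame(rows, columns=["start_sample", "end_sample", "label"]).to_csv(
        path, index=False
    )


def read_truth_csv(path: str | Path, n: int) -> GroundTruth:
    """Read a ground-truth CSV for a record of length ``n``."""
    df = pd.read_csv(path)
    segs = []
    labels = []
    for r in df.itertuples():
        start, end = int(r.start_sample), int(r.end_sample)
        segs.append(HSSegment(start=start, end=end, peak=start, area=0.0))
        labels.append(str(r.label))
    return GroundTruth(
        segments=SegmentSet(segments=tuple(segs), n=n), labels=tuple(labels)
    )
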