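"""Synthetic multichannel EMG-like surrogates and oracle fixtures.

Real lower-limb surface EMG from a multi-electrode montage shows (i) energy
concentrated roughly in 20–500 Hz, (ii) oscillatory modes that are shared
across muscle channels because the underlying motor drive is common, with
channel-specific coupling strengths, (iii) channel-specific measurement
noise, and (iv) an activity envelope following the exercise cycle — about
4 s per motion repetition, 2 s of motion and 2 s of rest.

``gen_surrogate`` emulates exactly that structure: each shared mode is
band-limited Gaussian noise (white noise band-passed around a centre
frequency with a zero-phase fourth-order Butterworth filter, unit STD),
mixed into the channels with a coupling-weight matrix, gated by a smooth
motion/rest envelope (100 ms cosine ramps avoid broadband gating edges),
plus independent per-channel white noise.  The default modes sit two
octaves apart (30, 120, 480 Hz) inside the EMG band so a well-behaved
decomposition can recover each one in a distinct IMF.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from ._exceptions import InvalidInputError
from .memd import MultichannelRecording
from .sift import Signal

__all__ = [
    "Mode",
    "SurrogateSpec",
    "SegmentationSpec",
    "gen_surrogate",
    "gen_heterogeneous_surrogate",
    "gen_tone_fixture",
    "gen_wgn_recording",
    "segment_motion",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ("BF", "VM", "RF", "ST")


@dataclass(frozen=True)
class Mode:
    """One shared oscillatory mode: centre frequency, bandwidth, channel weights."""

    center_hz: float
    bandwidth_hz: float
    weights: tuple[float, ...]


def _default_modes() -> tuple[Mode, ...]:
    # Two octaves between neighbouring centres; per-channel weights differ so
    # channels are correlated but not identical, as across muscle groups.
    return (
        Mode(30.0, 15.0, (0.9, 0.7, 1.0, 0.8)),
        Mode(120.0, 60.0, (0.8, 1.0, 0.9, 0.7)),
        Mode(480.0, 120.0, (1.0, 0.9, 0.8, 1.0)),
    )


@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters of an EMG-like multichannel surrogate.

    Defaults emulate a 4-channel lower-limb montage sampled at 1 kHz with a
    4 s exercise cycle (2 s motion, 2 s rest) and additive channel noise at
    0.2 of each mode's unit STD.
    """

    n_channels: int = 4
    duration: float = 4.0
    sampling_rate: float = 1000.0
    modes: tuple[Mode, ...] = field(default_factory=_default_modes)
    channel_noise_std: float = 0.2
    duty_cycle: tuple[float, float] = (2.0, 2.0)
    ramp: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2
        for mode in self.modes:
            if not 0 < mode.center_hz < nyq:
                raise InvalidInputError("mode centre must lie below Nyquist")
            if len(mode.weights) != self.n_channels:
                raise InvalidInputError("one coupling weight per channel required")
        if self.duration < sum(self.duty_cycle):
            raise InvalidInputError("duration must cover at least one motion cycle")
        if self.channel_noise_std < 0:
            raise InvalidInputError("channel_noise_std must be >= 0")


@dataclass(frozen=True)
class SegmentationSpec:
    """Fixed-window segmentation of the exercise cycle."""

    cycle_period: float = 4.0
    active_fraction: float = 0.5
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.active_fraction < 1:
            raise InvalidInputError("active_fraction must lie in (0, 1)")
        if self.cycle_period <= 0:
            raise InvalidInputError("cycle_period must be positive")


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float, mode: Mode) -> np.ndarray:
    """Unit-STD band-limited Gaussian noise centred on the mode frequency."""
    white = rng.normal(size=n)
    lo = max(mode.center_hz - mode.bandwidth_hz / 2, 1e-3)
    hi = min(mode.center_hz + mode.bandwidth_hz / 2, fs / 2 * 0.999)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sosfiltfilt(sos, white)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _motion_gate(n: int, fs: float, duty: tuple[float, float], ramp: float) -> np.ndarray:
    """Periodic motion/rest envelope with cosine on/off ramps."""
    t = np.arange(n) / fs
    period = sum(duty)
    phase = np.mod(t, period)
    active = duty[0]
    gate = np.zeros(n)
    core = (phase >= ramp) & (phase <= active - ramp)
    gate[core] = 1.0
    rise = phase < ramp
    gate[rise] = 0.5 * (1 - np.cos(np.pi * phase[rise] / ramp))
    fall = (phase > active - ramp) & (phase < active)
    gate[fall] = 0.5 * (1 - np.cos(np.pi * (active - phase[fall]) / ramp))
    return gate


def gen_surrogate(spec: SurrogateSpec | None = None) -> MultichannelRecording:
    """Generate an EMG-like multichannel surrogate recording."""
    spec = spec or SurrogateSpec()
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    gate = _motion_gate(n, fs, spec.duty_cycle, spec.ramp)
    X = np.zeros((n, spec.n_channels))
    for k, mode in enumerate(spec.modes):
        rng = np.random.default_rng([spec.seed, k])
        source = _bandpass_noise(rng, n, fs, mode) * gate
        X += np.outer(source, np.asarray(mode.weights, dtype=np.float64))
    if spec.channel_noise_std > 0:
        rng = np.random.default_rng([spec.seed, len(spec.modes) + 1])
        X += rng.normal(0.0, spec.channel_noise_std, size=X.shape)
    names = DEFAULT_CHANNELS if spec.n_channels == 4 else tuple(
        f"ch{i + 1}" for i in range(spec.n_channels)
    )
    return MultichannelRecording(samples=X, sampling_rate=fs, channel_names=names)


def gen_heterogeneous_surrogate(
    seed: int,
    duration: float = 1.0,
    sampling_rate: float = 1000.0,
    n_channels: int = 4,
    wander_probability: float = 0.5,
) -> MultichannelRecording:
    """A randomized surrogate with realistic cross-channel heterogeneity.

    On top of the shared-mode structure of :func:`gen_surrogate`, each draw
    randomizes the mode centres (70–120% of 30/120/400 Hz), bandwidths, and
    coupling weights, and gives each channel, with probability
    ``wander_probability``, its own baseline-wander component (Gaussian
    noise low-passed at 2 Hz, amplitude 0.5–2x the mode STD).  Baseline
    wander is an electrode-specific artifact of surface EMG, so different
    channels genuinely differ in their low-frequency mode content — which is
    what makes channel-by-channel decompositions disagree on IMF counts.
    """
    rng = np.random.default_rng([seed, 901])
    centers = np.array([30.0, 120.0, 400.0]) * rng.uniform(0.7, 1.2, 3)
    modes = tuple(
        Mode(float(c), float(c / 2), tuple(rng.uniform(0.2, 1.0, n_channels)))
        for c in centers
    )
    spec = SurrogateSpec(
        n_channels=n_channels,
        duration=duration,
        sampling_rate=sampling_rate,
        modes=modes,
        channel_noise_std=0.3,
        duty_cycle=(duration / 2, duration / 2),
        seed=seed,
    )
    rec = gen_surrogate(spec)
    X = rec.samples.copy()
    sos = butter(2, 2.0, btype="low", fs=sampling_rate, output="sos")
    for j in range(n_channels):
        if rng.random() < wander_probability:
            drift = sosfiltfilt(sos, rng.normal(size=X.shape[0]))
            sd = drift.std()
            if sd > 0:
                X[:, j] += drift / sd * rng.uniform(0.5, 2.0)
    return MultichannelRecording(
        samples=X, sampling_rate=sampling_rate, channel_names=rec.channel_names
    )


def gen_tone_fixture(
    freqs: Sequence[float],
    amps: Sequence[float] | None = None,
    duration: float = 2.0,
    fs: float = 1000.0,
) -> Signal:
    """Sum-of-sinusoids fixture with a known closed form (oracle for sifting)."""
    freqs = list(freqs)
    amps = list(amps) if amps is not None else [1.0] * len(freqs)
    if len(amps) != len(freqs):
        raise InvalidInputError("freqs and amps must have the same length")
    if any(f >= fs / 2 for f in freqs):
        raise InvalidInputError("tone frequencies must be below Nyquist")
    t = np.arange(int(round(duration * fs))) / fs
    x = np.zeros_like(t)
    for f, a in zip(freqs, amps):
        x += a * np.sin(2 * np.pi * f * t)
    return Signal(samples=x, sampling_rate=fs)


def gen_wgn_recording(
    n_channels: int, n_samples: int, std: float = 1.0, seed: int = 0, fs: float = 1000.0
) -> MultichannelRecording:
    """Independent white-Gaussian-noise channels (filter-bank test fixture)."""
    if std < 0:
        raise InvalidInputError("std must be >= 0")
    rng = np.random.default_rng([seed, 0])
    X = rng.normal(0.0, std, size=(n_samples, n_channels)) if std > 0 else np.zeros(
        (n_samples, n_channels)
    )
    return MultichannelRecording(samples=X, sampling_rate=fs)


def segment_motion(
    recording: MultichannelRecording, seg: SegmentationSpec | None = None
) -> list[MultichannelRecording]:
    """Extract the active (motion) window of each exercise cycle.

    A fixed-window scheme: cycle k contributes the samples in
    [offset + k*period, offset + k*period + active_fraction*period).
    """
    seg = seg or SegmentationSpec()
    fs = recording.sampling_rate
    period = int(round(seg.cycle_period * fs))
    active = int(round(seg.cycle_period * seg.active_fraction * fs))
    start0 = int(round(seg.offset * fs))
    T = recording.n_samples
    out: list[MultichannelRecording] = []
    start = start0
    while start + active <= T:
        out.append(
            MultichannelRecording(
                samples=recording.samples[start : start + active],
                sampling_rate=fs,
                channel_names=recording.channel_names,
            )
        )
        start += period
    if not out:
        import warnings

        warnings.warn("recording shorter than one motion cycle; no segments", stacklevel=2)
    return out
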