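"""Synthetic single-channel EEG with the structure the pipeline assumes.

Each window is a sum of band-limited sinusoidal oscillations (one carrier per
named brain-wave band, drawn uniformly from the integer-Hz bin centers inside
the band so that its energy falls exactly on the ideal-filter bin set), a
slow drift trend emulating eye/muscle artifacts, broadband white noise, and
high-frequency noise (white noise ideal-highpassed at 55 Hz, disjoint from
the retained 0-50 Hz band).  The two classes differ only through a
multiplicative shift of selected band amplitudes.

This is the statistical structure the pipeline consumes, not physiological
EEG: there is no 1/f background, no eye-blink transients, and no
non-stationarity within a window.

Default amplitudes are in microvolt-like units chosen to mimic the usual
dominance ordering of resting EEG rhythms (slow waves largest, gamma
smallest) with noise at a level that leaves band structure clearly visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import STATES, LabeledDataset, RawRecording, Sample
from .spectral import CANONICAL_BANDS

__all__ = ["SignalSpec", "generate_recording", "generate_labeled_dataset"]


class InvalidSpecError(ValueError):
    pass


#: Default per-band oscillation amplitudes (signal units). Only the seven
#: disjoint bands are driven; the overlapping low/whole-beta bands then pick
#: up the beta-range carriers through extraction.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 20.0,
    "theta": 15.0,
    "alpha": 10.0,
    "SMR": 6.0,
    "mid_beta": 6.0,
    "high_beta": 4.0,
    "gamma": 2.0,
}


@dataclass(frozen=True)
class TrendSpec:
    """Slow drift added to every window: none, linear ramp, or slow sinusoid."""

    type: str = "sinusoid"  # none | linear | sinusoid
    amplitude: float = 30.0
    period: float = 10.0  # seconds; only for the sinusoid type

    def __post_init__(self) -> None:
        if self.type not in ("none", "linear", "sinusoid"):
            raise InvalidSpecError(f"unknown trend type {self.type!r}")
        if self.amplitude < 0 or self.period <= 0:
            raise InvalidSpecError("trend amplitude must be >= 0, period > 0")


@dataclass(frozen=True)
class SignalSpec:
    """Generator parameters for one synthetic recording."""

    duration: float = 1.0
    fs: float = 512.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    trend: TrendSpec = TrendSpec()
    noise_sd_highfreq: float = 5.0
    noise_sd_broadband: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise InvalidSpecError("duration and fs must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise InvalidSpecError("duration * fs must be an integer")
        for name, amp in self.band_amplitudes.items():
            if name not in CANONICAL_BANDS:
                raise InvalidSpecError(f"unknown band {name!r}")
            if amp < 0:
                raise InvalidSpecError(f"negative amplitude for band {name!r}")
        if self.noise_sd_highfreq < 0 or self.noise_sd_broadband < 0:
            raise InvalidSpecError("noise amplitudes must be >= 0")

    @property
    def n_points(self) -> int:
        return int(round(self.duration * self.fs))


def _band_carrier_choices(name: str) -> np.ndarray:
    """Integer-Hz carrier frequencies inside the band (bin centers at 1 Hz)."""
    band = CANONICAL_BANDS[name]
    lo = max(1, int(np.ceil(band.f_low)))
    hi = int(np.ceil(band.f_high))  # half-open [f_low, f_high)
    return np.arange(lo, hi)


def _highpass_55(noise: np.ndarray, fs: float) -> np.ndarray:
    spec = np.fft.rfft(noise)
    freqs = np.arange(spec.size) * (fs / noise.size)
    spec[freqs < 55.0] = 0.0
    return np.fft.irfft(spec, n=noise.size)


def _synth_signal(spec: SignalSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_points
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    for name, amp in sorted(spec.band_amplitudes.items()):
        if amp == 0:
            continue
        choices = _band_carrier_choices(name)
        f = float(rng.choice(choices))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x += amp * np.sin(2.0 * np.pi * f * t + phi)
    tr = spec.trend
    if tr.type == "linear" and tr.amplitude > 0:
        x += tr.amplitude * (2.0 * t / t[-1] - 1.0) if n > 1 else 0.0
    elif tr.type == "sinusoid" and tr.amplitude > 0:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x += tr.amplitude * np.sin(2.0 * np.pi * t / tr.period + phi)
    if spec.noise_sd_highfreq > 0:
        x += _highpass_55(rng.normal(0.0, spec.noise_sd_highfreq, n), spec.fs)
    if spec.noise_sd_broadband > 0:
        x += rng.normal(0.0, spec.noise_sd_broadband, n)
    return x


def generate_recording(spec: SignalSpec, meta: dict | None = None) -> RawRecording:
    """One continuous synthetic recording, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    signal = _synth_signal(spec, rng)
    return RawRecording(signal=signal, fs=spec.fs, meta=dict(meta or {}))


def generate_labeled_dataset(
    n_per_class: dict[str, int] | None = None,
    base_spec: SignalSpec | None = None,
    class_shift: dict[str, float] | None = None,
    window_seconds: float = 1.0,
    seed: int = 0,
) -> LabeledDataset:
    """Labeled windows for two-state classification tests.

    Every window is generated independently (fresh carriers, phases and
    noise).  Windows of the "immersion" class have their band amplitudes
    multiplied by ``class_shift`` (default: alpha x 4); "concentration"
    windows use the base amplitudes.
    """
    if n_per_class is None:
        n_per_class = {s: 50 for s in STATES}
    if base_spec is None:
        base_spec = SignalSpec()
    if class_shift is None:
        class_shift = {"alpha": 4.0}
    for state, count in n_per_class.items():
        if state not in STATES:
            raise InvalidSpecError(f"unknown state {state!r}")
        if count < 1:
            raise InvalidSpecError(f"need >= 1 window for state {state!r}")

    window_spec = replace(base_spec, duration=window_seconds)
    shifted = dict(window_spec.band_amplitudes)
    for name, mult in class_shift.items():
        shifted[name] = shifted.get(name, 0.0) * mult
    spec_by_state = {
        "concentration": window_spec,
        "immersion": replace(window_spec, band_amplitudes=shifted),
    }

    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    for state in STATES:
        if state not in n_per_class:
            continue
        spec = spec_by_state[state]
        for i in range(n_per_class[state]):
            samples.append(
                Sample(
                    values=_synth_signal(spec, rng),
                    label=state,
                    meta={"index": i},
                )
            )
    return LabeledDataset(samples=samples, fs=base_spec.fs)
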