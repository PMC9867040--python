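"""FFT-based ideal filtering and brain-wave band extraction.

Denoising and band extraction are both implemented as projections in the
discrete Fourier domain: the FFT of the window is computed, the coefficients
outside the retained frequency set are zeroed (conjugate pairs symmetrically,
so the inverse transform is exactly real), and the inverse FFT is taken.
Because the retained coefficients keep their phase, the operation is
zero-phase — unlike IIR filtering (e.g. Butterworth), no phase distortion is
introduced into the extracted waves.

For a 1 s window sampled at 512 Hz the frequency resolution is 1 Hz, so bin
``k`` sits exactly at ``k`` Hz; in general bin ``k`` of an ``n``-point window
at ``fs`` Hz sits at ``k*fs/n`` Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "BAND_ORDER",
    "load_band_table",
    "band_bins",
    "fft_lowpass_denoise",
    "extract_band",
    "extract_all_bands",
]


class InvalidSignalError(ValueError):
    """Raised for non-finite or too-short input signals."""


class InvalidBandError(ValueError):
    """Raised for band definitions incompatible with the sampling rate."""


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_low, f_high)`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise InvalidBandError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )


#: Canonical nine-band table. SMR is the sensorimotor rhythm; the beta range
#: is additionally split into low/mid/high sub-bands, and the full beta band
#: overlaps its sub-bands on purpose (each is extracted independently).
CANONICAL_BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("delta", 0.5, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 12.0),
        BandDefinition("SMR", 12.0, 14.99),
        BandDefinition("mid_beta", 15.0, 19.99),
        BandDefinition("high_beta", 20.0, 30.0),
        BandDefinition("low_beta", 12.0, 19.0),
        BandDefinition("beta", 12.0, 30.0),
        BandDefinition("gamma", 30.0, 49.0),
    )
}

#: Fixed extraction order of the nine bands.
BAND_ORDER: tuple[str, ...] = tuple(CANONICAL_BANDS)


def load_band_table(path: str | Path) -> dict[str, BandDefinition]:
    """Load a band table from a JSON file ``{name: {"f_low":..,"f_high":..}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        name: BandDefinition(name, float(d["f_low"]), float(d["f_high"]))
        for name, d in raw.items()
    }


def _check_signal(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidSignalError("signal must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise InvalidSignalError("signal contains NaN or Inf")
    return x


def band_bins(band: BandDefinition, n: int, fs: float) -> set[int]:
    """Non-negative FFT bin indices retained for *band*.

    Bin ``k`` (frequency ``k*fs/n``) is kept iff ``f_low <= k*fs/n < f_high``.
    The DC bin is never kept.  Conjugate (negative-frequency) bins are implied.
    """
    if n < 2 or fs <= 0:
        raise InvalidSignalError("need n >= 2 and fs > 0")
    if band.f_high > fs / 2:
        raise InvalidBandError(
            f"band {band.name!r} upper edge {band.f_high} Hz exceeds "
            f"Nyquist {fs / 2} Hz"
        )
    freqs = np.arange(n // 2 + 1) * (fs / n)
    keep = (freqs >= band.f_low) & (freqs < band.f_high)
    keep[0] = False
    return set(np.nonzero(keep)[0].tolist())


def _apply_bin_mask(x: np.ndarray, kept: np.ndarray) -> np.ndarray:
    """Zero all rfft coefficients outside *kept* and invert; exactly real."""
    spec = np.fft.rfft(x)
    mask = np.zeros(spec.shape, dtype=bool)
    mask[kept] = True
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=x.size)


def fft_lowpass_denoise(x: np.ndarray, fs: float, cutoff: float = 50.0) -> np.ndarray:
    """Ideal lowpass: zero every FFT coefficient above *cutoff* Hz.

    Coefficients at frequencies <= cutoff (DC included) are retained, so the
    useful 0-50 Hz content passes unchanged while high-frequency noise is
    removed exactly.  The operation is idempotent and zero-phase.
    """
    x = _check_signal(x)
    n = x.size
    freqs = np.arange(n // 2 + 1) * (fs / n)
    kept = np.nonzero(freqs <= cutoff)[0]
    return _apply_bin_mask(x, kept)


def extract_band(x: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Extract one brain wave by zeroing all FFT coefficients outside *band*."""
    x = _check_signal(x)
    kept = np.sort(np.fromiter(band_bins(band, x.size, fs), dtype=int))
    return _apply_bin_mask(x, kept)


def extract_all_bands(
    x: np.ndarray,
    fs: float,
    bands: dict[str, BandDefinition] | None = None,
) -> dict[str, np.ndarray]:
    """Extract the nine canonical brain waves, in canonical order."""
    if bands is None:
        bands = CANONICAL_BANDS
    return {name: extract_band(x, fs, band) for name, band in bands.items()}
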