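"""Empirical mode decomposition and EMD-based detrending.

EMD represents a signal as a sum of intrinsic mode functions (IMFs) plus a
monotone residue.  Each IMF is obtained by *sifting*: the cubic-spline
envelopes through the maxima and minima are averaged, the mean is subtracted,
and the step repeats until the pointwise sifting statistic

    SD = sum_t m(t)^2 / d_{j-1}(t)^2

drops below 0.3.  The last components of the decomposition carry the slow,
large-time-scale content, so discarding the final two components of the list
[IMF_1, ..., IMF_{N-1}, residue] removes the underlying trend (drift from eye
and muscular activity in EEG recordings).

An IMF satisfies two conditions: (1) the number of extrema and the number of
zero crossings differ by at most one, and (2) the mean of the upper and lower
envelopes is everywhere close to zero.  Condition (2) is checked numerically
(envelope-mean RMS below 10% of signal RMS) because an exactly-zero envelope
mean is unattainable in floating point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "IMFSet",
    "find_extrema",
    "envelope_mean",
    "sift",
    "emd_decompose",
    "detrend",
]

logger = logging.getLogger(__name__)

#: Sifting stops when SD drops below this value.
SD_THRESHOLD = 0.3
#: Cap on sifting iterations per IMF (termination guarantee).
MAX_SIFT_ITER = 100
#: Cap on the number of extracted IMFs.
MAX_IMFS = 12
#: Samples with squared amplitude below this are skipped in the SD sum.
_SD_DENOM_GUARD = 1e-30


class InvalidSignalError(ValueError):
    pass


class NotSiftableError(ValueError):
    """Signal has too few extrema to support spline envelopes."""


@dataclass
class IMFSet:
    """Ordered IMFs plus the residue of one decomposition."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.source_length == 0:
            self.source_length = int(self.residue.size)

    @property
    def components(self) -> list[np.ndarray]:
        """IMFs followed by the residue (the residue is the last component)."""
        return [*self.imfs, self.residue]

    def reconstruct(self) -> np.ndarray:
        out = np.array(self.residue, dtype=float, copy=True)
        for c in self.imfs:
            out += c
        return out


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima of *x*.

    Plateaus count as a single extremum located at the floor-midpoint of the
    plateau.  A constant signal has no extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InvalidSignalError("need at least 3 samples")
    # Collapse runs of equal values so a plateau becomes one "sample", then
    # map detected extrema back to the floor-midpoint of the original run.
    change = np.nonzero(np.diff(x) != 0)[0]
    starts = np.concatenate(([0], change + 1))          # run start indices
    ends = np.concatenate((change, [x.size - 1]))       # run end indices
    vals = x[starts]
    if vals.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.sign(np.diff(vals))
    interior = np.arange(1, vals.size - 1)
    is_max = (d[:-1] > 0) & (d[1:] < 0)
    is_min = (d[:-1] < 0) & (d[1:] > 0)
    mid = (starts + ends) // 2
    maxima = mid[interior[is_max]]
    minima = mid[interior[is_min]]
    return maxima.astype(int), minima.astype(int)


def _mirrored_spline(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic spline through (idx, x[idx]) with the two nearest extrema
    mirrored across each end of the support, evaluated on the full grid."""
    n = x.size
    t = idx.astype(float)
    v = x[idx]
    # mirror the two nearest extrema across t=0 and t=n-1
    left_t = (-t[:2])[::-1]
    left_v = v[:2][::-1]
    right_t = (2 * (n - 1) - t[-2:])[::-1]
    right_v = v[-2:][::-1]
    tt = np.concatenate((left_t, t, right_t))
    vv = np.concatenate((left_v, v, right_v))
    # mirroring can duplicate knots when an extremum sits on the boundary
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    if tt.size < 2:
        return np.full(n, vv[0] if vv.size else 0.0)
    spline = CubicSpline(tt, vv)
    return spline(np.arange(n))


def envelope_mean(
    x: np.ndarray, maxima: np.ndarray, minima: np.ndarray
) -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes, m = (e_max+e_min)/2."""
    x = np.asarray(x, dtype=float)
    if maxima.size < 2 or minima.size < 2:
        raise NotSiftableError(
            f"need >= 2 maxima and >= 2 minima, got {maxima.size}/{minima.size}"
        )
    e_max = _mirrored_spline(x, np.sort(maxima))
    e_min = _mirrored_spline(x, np.sort(minima))
    return (e_max + e_min) / 2.0


def _sd_statistic(m: np.ndarray, d_prev: np.ndarray) -> float:
    denom = d_prev * d_prev
    ok = denom > _SD_DENOM_GUARD
    if not np.any(ok):
        return 0.0
    return float(np.sum(m[ok] * m[ok] / denom[ok]))


def sift(x: np.ndarray) -> np.ndarray:
    """Extract one IMF from *x* by iterated envelope-mean subtraction."""
    d = np.asarray(x, dtype=float).copy()
    for _ in range(MAX_SIFT_ITER):
        maxima, minima = find_extrema(d)
        if maxima.size < 2 or minima.size < 2:
            raise NotSiftableError("too few extrema during sifting")
        m = envelope_mean(d, maxima, minima)
        sd = _sd_statistic(m, d)
        d = d - m
        if sd < SD_THRESHOLD:
            return d
    warnings.warn("sifting iteration cap reached; returning current candidate")
    return d


def _n_extrema(x: np.ndarray) -> int:
    try:
        mx, mn = find_extrema(x)
    except InvalidSignalError:
        return 0
    return mx.size + mn.size


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def emd_decompose(x: np.ndarray) -> IMFSet:
    """Full EMD: peel off IMFs until the residue is monotone or degenerate."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise InvalidSignalError("signal must be 1-D with length >= 4")
    if not np.all(np.isfinite(x)):
        raise InvalidSignalError("signal contains NaN or Inf")

    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < MAX_IMFS:
        if _is_monotone(residue) or _n_extrema(residue) < 4:
            break
        try:
            imf = sift(residue)
        except NotSiftableError:
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, source_length=x.size)


def detrend(x: np.ndarray) -> np.ndarray:
    """Remove the underlying trend by dropping the last two EMD components.

    The component list is [IMF_1, ..., IMF_{N-1}, residue]; the sum of all but
    the final two is returned.  Degenerate decompositions keep their
    oscillatory content: with exactly two components only the residue is
    dropped (the lone IMF is returned), and a residue-only decomposition
    (monotone or non-siftable input, pure trend) returns the zero signal.
    """
    decomp = emd_decompose(x)
    comps = decomp.components
    n_drop = 2 if len(comps) >= 3 else 1
    if len(comps) <= n_drop:
        return np.zeros_like(np.asarray(x, dtype=float))
    out = np.zeros(decomp.source_length)
    for c in comps[:-n_drop]:
        out += c
    return out
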