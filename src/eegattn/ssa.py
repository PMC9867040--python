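"""Singular spectrum analysis (SSA).

SSA decomposes a length-N series into interpretable additive components in
three steps:

1. *Embedding*: stack the K = N - L + 1 lagged length-L segments of the
   series as columns of the L x K Hankel trajectory matrix X.
2. *Decomposition*: eigendecompose the L x L covariance matrix X X^T (cheaper
   than an SVD of X itself when L << K).  With eigenpairs (lambda_i, U_i)
   sorted by descending eigenvalue, the rank-one elementary matrices are
   S_i = U_i U_i^T X = sqrt(lambda_i) U_i V_i^T, where V_i = X^T U_i /
   sqrt(lambda_i); they sum exactly to X.
3. *Diagonal averaging* (the inverse of Hankelization): average each
   anti-diagonal of a grouped sum of elementary matrices to map it back to a
   length-N series.

The attention pipeline uses two fixed schemes: L = 6 with the grouping
{1}, {2,3}, {4,5}, {6} for the detrended EEG (four grouped components), and
L = 2 with singleton groups for each extracted brain wave (two components
each), giving 4 + 9 x 2 = 22 components per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel

from .spectral import BAND_ORDER

__all__ = [
    "TrajectoryMatrix",
    "SSADecomposition",
    "build_trajectory_matrix",
    "diagonal_average",
    "ssa_decompose",
    "group_components",
    "decompose_detrended_eeg",
    "decompose_band",
    "assemble_components",
    "COMPONENT_NAMES",
    "EEG_GROUPING",
]

#: Relative eigenvalue tolerance below which a component is treated as null.
RANK_TOL = 1e-12

#: Grouping of the six detrended-EEG elementary series (0-based indices).
EEG_GROUPING: tuple[tuple[int, ...], ...] = ((0,), (1, 2), (3, 4), (5,))

#: Names of the 22 assembled components, in pipeline order.
COMPONENT_NAMES: tuple[str, ...] = tuple(
    [f"EEG-SSA{i}" for i in range(1, 5)]
    + [f"{band}-SSA{j}" for band in BAND_ORDER for j in (1, 2)]
)


class InvalidWindowError(ValueError):
    pass


class InvalidGroupingError(ValueError):
    pass


@dataclass(frozen=True)
class TrajectoryMatrix:
    entries: np.ndarray  # L x K
    L: int
    K: int
    N: int


@dataclass
class SSADecomposition:
    """Elementary-stage SSA result.

    ``elementary_series[i]`` is the diagonal average of the i-th rank-one
    elementary matrix; the series sum to the input signal.
    ``right_vectors[i]`` is None for eigenvalues below the rank tolerance.
    """

    eigenvalues: np.ndarray            # length L, descending, clipped >= 0
    left_vectors: np.ndarray           # L x L, columns U_i
    right_vectors: list[np.ndarray | None]
    elementary_series: np.ndarray      # L x N
    L: int
    N: int


def build_trajectory_matrix(x: np.ndarray, L: int) -> TrajectoryMatrix:
    """Hankel embedding of *x* with window length *L* (1 < L <= N/2)."""
    x = np.asarray(x, dtype=float)
    N = x.size
    if not (1 < L <= N / 2):
        raise InvalidWindowError(f"window length L={L} outside (1, N/2] for N={N}")
    X = hankel(x[:L], x[L - 1 :])
    return TrajectoryMatrix(entries=X, L=L, K=N - L + 1, N=N)


def diagonal_average(A: np.ndarray) -> np.ndarray:
    """Average the anti-diagonals of *A*, giving a series of length L+K-1.

    Element t (0-based) is the mean of all A[a, b] with a + b = t.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    L, K = A.shape
    idx = np.add.outer(np.arange(L), np.arange(K)).ravel()
    sums = np.bincount(idx, weights=A.ravel(), minlength=L + K - 1)
    counts = np.bincount(idx, minlength=L + K - 1)
    return sums / counts


def ssa_decompose(x: np.ndarray, L: int) -> SSADecomposition:
    """Elementary SSA via eigendecomposition of the lag-covariance matrix."""
    traj = build_trajectory_matrix(x, L)
    X = traj.entries
    C = X @ X.T
    lam, U = np.linalg.eigh(C)
    order = np.argsort(-lam, kind="stable")
    lam = np.clip(lam[order], 0.0, None)
    U = U[:, order]

    tol = RANK_TOL * lam[0] if lam[0] > 0 else np.inf
    right: list[np.ndarray | None] = []
    series = np.empty((L, traj.N))
    for i in range(L):
        u = U[:, i]
        # S_i = U_i U_i^T X; summing the projections over the full eigenbasis
        # reproduces X exactly, so the elementary series sum to x.
        S_i = np.outer(u, u @ X)
        series[i] = diagonal_average(S_i)
        if lam[i] > tol:
            right.append((X.T @ u) / np.sqrt(lam[i]))
        else:
            right.append(None)
    return SSADecomposition(
        eigenvalues=lam,
        left_vectors=U,
        right_vectors=right,
        elementary_series=series,
        L=L,
        N=traj.N,
    )


def group_components(
    decomp: SSADecomposition, grouping: list[tuple[int, ...]] | tuple
) -> list[np.ndarray]:
    """Sum elementary series over each (0-based) index group."""
    seen: set[int] = set()
    for g in grouping:
        gs = set(g)
        if gs & seen:
            raise InvalidGroupingError("grouping subsets overlap")
        if not gs <= set(range(decomp.L)):
            raise InvalidGroupingError(f"group {g} outside 0..{decomp.L - 1}")
        seen |= gs
    return [decomp.elementary_series[list(g)].sum(axis=0) for g in grouping]


def decompose_detrended_eeg(x: np.ndarray) -> list[np.ndarray]:
    """Four grouped SSA components of a detrended EEG window (L = 6)."""
    decomp = ssa_decompose(x, L=6)
    return group_components(decomp, EEG_GROUPING)


def decompose_band(x: np.ndarray) -> list[np.ndarray]:
    """Two SSA components of one extracted brain wave (L = 2)."""
    decomp = ssa_decompose(x, L=2)
    return group_components(decomp, ((0,), (1,)))


def assemble_components(
    detrended: np.ndarray, bands: dict[str, np.ndarray]
) -> list[np.ndarray]:
    """The 22 SSA components of one window, in ``COMPONENT_NAMES`` order."""
    n = np.asarray(detrended).size
    if set(bands) != set(BAND_ORDER):
        raise ValueError("expected exactly the nine canonical bands")
    for name in BAND_ORDER:
        if np.asarray(bands[name]).size != n:
            raise ValueError(f"band {name!r} length differs from the EEG window")
    out = decompose_detrended_eeg(detrended)
    for name in BAND_ORDER:
        out.extend(decompose_band(bands[name]))
    return out
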