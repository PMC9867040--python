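"""Per-component statistics, the 242-value feature vector and the ANOVA screen.

Eleven statistics are computed for each of the 22 SSA components of a window:
approximate entropy, mean, interquartile range, mean absolute deviation,
range, variance, skewness, kurtosis, and the L1 / L2 / L-infinity norms.
Amplitudes and energies differ strongly between brain waves, which is why
these shape/regularity statistics are used rather than raw power.

Approximate entropy (ApEn) follows the classical Pincus construction:
with embedding length m and tolerance P = r * SD(x), the fraction C_i^m(P) of
length-m subsequences within Chebyshev distance P of subsequence i
(self-match included) is averaged in log over i to give phi^m(P), and
ApEn = phi^m(P) - phi^{m+1}(P).  Counting *similar* subsequences (d <= P) is
the standard convention; the opposite count can be selected via
``similarity="greater"`` but is not meaningful as a regularity measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .ssa import COMPONENT_NAMES

__all__ = [
    "FEATURE_NAMES",
    "approximate_entropy",
    "summary_features",
    "FeatureVector",
    "feature_vector",
    "AnovaScreenResult",
    "anova_screen",
    "screen_pvalue_table",
    "load_reference_screen_pvalues",
]

#: The eleven statistics, in fixed column order.
FEATURE_NAMES: tuple[str, ...] = (
    "apen",
    "mean",
    "iqr",
    "mad",
    "range",
    "variance",
    "skewness",
    "kurtosis",
    "l1",
    "l2",
    "linf",
)


class InvalidLengthError(ValueError):
    pass


def _phi_of(E: np.ndarray, P: float, similarity: str) -> float:
    """phi(P) from a pairwise subsequence Chebyshev-distance matrix."""
    if similarity == "greater":
        counts = np.maximum((E > P).sum(axis=1), 1)  # avoid log(0)
    else:
        counts = (E <= P).sum(axis=1)  # self-match included, so >= 1
    return float(np.mean(np.log(counts / E.shape[0])))


def _phi_pair(x: np.ndarray, m: int, P: float, similarity: str) -> tuple[float, float]:
    """(phi^m, phi^{m+1}) sharing one pairwise sample-distance matrix.

    The Chebyshev distance between length-m subsequences i and j is the
    running max of |x[i+k] - x[j+k]| over k, built incrementally from the
    sample-level matrix.
    """
    D = np.abs(x[:, None] - x[None, :])
    E = D
    for k in range(1, m):
        E = np.maximum(E[:-1, :-1], D[k:, k:])
    phi_m = _phi_of(E, P, similarity)
    E = np.maximum(E[:-1, :-1], D[m:, m:])
    return phi_m, _phi_of(E, P, similarity)


def approximate_entropy(
    x: np.ndarray, m: int = 2, r: float = 0.5, similarity: str = "leq"
) -> float:
    """Approximate entropy with tolerance P = r * SD(x).

    ``m`` is the embedding (subsequence) length and ``r`` the tolerance
    coefficient, typically in [0.25, 0.75]; the threshold P is computed once
    from the sample standard deviation of the whole series, which makes ApEn
    invariant under positive rescaling of the series.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size <= m + 1:
        raise InvalidLengthError(f"need N > m+1 = {m + 1}, got N={x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains NaN or Inf")
    P = r * float(np.std(x, ddof=1))
    phi_m, phi_m1 = _phi_pair(x, m, P, similarity)
    return phi_m - phi_m1


def summary_features(x: np.ndarray, apen_m: int = 2, apen_r: float = 0.5) -> np.ndarray:
    """The 11 statistics of one series, in ``FEATURE_NAMES`` order.

    Variance uses the N-1 denominator; skewness and kurtosis standardize by
    the sample SD but divide the summed cubes/fourth powers by N, and
    kurtosis is non-excess (a normal series gives ~3).  A constant series
    gets skewness and kurtosis 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidLengthError("need a 1-D series with N >= 2")
    N = x.size
    mean = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    centered = x - mean
    if s > 0:
        skew = float(np.sum((centered / s) ** 3) / N)
        kurt = float(np.sum((centered / s) ** 4) / N)
    else:
        skew = 0.0
        kurt = 0.0
    q1, q3 = np.percentile(x, [25, 75])
    return np.array(
        [
            approximate_entropy(x, m=apen_m, r=apen_r) if s > 0 else 0.0,
            mean,
            float(q3 - q1),
            float(np.mean(np.abs(centered))),
            float(np.max(x) - np.min(x)),
            s * s,
            skew,
            kurt,
            float(np.sum(np.abs(x))),
            float(np.sqrt(np.sum(x * x))),
            float(np.max(np.abs(x))),
        ]
    )


@dataclass
class FeatureVector:
    """Ordered 242-value feature vector with stable names."""

    values: np.ndarray
    names: tuple[str, ...]
    component_order: tuple[str, ...] = COMPONENT_NAMES
    feature_order: tuple[str, ...] = FEATURE_NAMES


def feature_names(
    components: tuple[str, ...] = COMPONENT_NAMES,
    feats: tuple[str, ...] = FEATURE_NAMES,
) -> tuple[str, ...]:
    return tuple(f"{c}-{f}" for c in components for f in feats)


def feature_vector(components: list[np.ndarray]) -> FeatureVector:
    """Stack the 11 statistics of each of the 22 components (component-major)."""
    if len(components) != len(COMPONENT_NAMES):
        raise ValueError(
            f"expected {len(COMPONENT_NAMES)} components, got {len(components)}"
        )
    values = np.concatenate([summary_features(c) for c in components])
    return FeatureVector(values=values, names=feature_names())


@dataclass
class AnovaScreenResult:
    """One-way ANOVA screen over a feature table."""

    p_values: pd.DataFrame        # components x features (or any table shape)
    n_significant: int
    power: float                  # percent of cells with p < alpha
    alpha: float


def screen_pvalue_table(p_values: pd.DataFrame, alpha: float = 0.05) -> AnovaScreenResult:
    """Count significant cells in an (externally supplied) p-value table."""
    vals = p_values.to_numpy(dtype=float)
    n_sig = int(np.sum(vals < alpha))
    power = 100.0 * n_sig / vals.size
    return AnovaScreenResult(
        p_values=p_values, n_significant=n_sig, power=power, alpha=alpha
    )


def anova_screen(
    features_by_class: dict[str, np.ndarray | list],
    alpha: float = 0.05,
    names: tuple[str, ...] | None = None,
) -> AnovaScreenResult:
    """Per-feature one-way ANOVA across classes.

    ``features_by_class`` maps each class label to an (n_samples, n_features)
    array (or a list of FeatureVector).  Features constant across all samples
    carry no discrimination and get p = 1.
    """
    mats = {}
    for label, rows in features_by_class.items():
        if isinstance(rows, (list, tuple)):
            rows = np.vstack([
                r.values if isinstance(r, FeatureVector) else np.asarray(r)
                for r in rows
            ])
        mats[label] = np.asarray(rows, dtype=float)
    if len(mats) < 2 or any(m.shape[0] < 2 for m in mats.values()):
        raise ValueError("need >= 2 classes with >= 2 samples each")

    n_feat = next(iter(mats.values())).shape[1]
    pvals = np.ones(n_feat)
    for j in range(n_feat):
        groups = [m[:, j] for m in mats.values()]
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            continue  # constant feature -> p = 1
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*groups)
        pvals[j] = 1.0 if np.isnan(p) else float(p)

    if n_feat == len(COMPONENT_NAMES) * len(FEATURE_NAMES):
        table = pd.DataFrame(
            pvals.reshape(len(COMPONENT_NAMES), len(FEATURE_NAMES)),
            index=list(COMPONENT_NAMES),
            columns=list(FEATURE_NAMES),
        )
    else:
        cols = list(names) if names and len(names) == n_feat else list(range(n_feat))
        table = pd.DataFrame(pvals.reshape(1, -1), columns=cols)
    n_sig = int(np.sum(pvals < alpha))
    return AnovaScreenResult(
        p_values=table,
        n_significant=n_sig,
        power=100.0 * n_sig / pvals.size,
        alpha=alpha,
    )


def load_reference_screen_pvalues() -> pd.DataFrame:
    """The published reference table of 242 ANOVA p-values.

    Reproduced from the original attention-assessment study: one-way ANOVA
    p-values of every (component, feature) cell computed on its EEG corpus.
    Rows are components, columns the eleven statistics.
    """
    ref = resources.files("eegattn.data").joinpath("reference_screen_pvalues.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)
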