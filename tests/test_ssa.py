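"""Singular spectrum analysis: embedding, diagonal averaging, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegattn import ssa
from eegattn.spectral import BAND_ORDER, extract_all_bands
from eegattn.ssa import (
    COMPONENT_NAMES,
    EEG_GROUPING,
    assemble_components,
    build_trajectory_matrix,
    decompose_band,
    decompose_detrended_eeg,
    diagonal_average,
    group_components,
    ssa_decompose,
)

from conftest import tone


def brute_force_diag_average(A):
    """Independent oracle: explicit loop over all (a, b) pairs per anti-diagonal."""
    L, K = A.shape
    out = np.zeros(L + K - 1)
    for t in range(L + K - 1):
        vals = [A[a, b] for a in range(L) for b in range(K) if a + b == t]
        out[t] = sum(vals) / len(vals)
    return out


class TestTrajectoryMatrix:
    def test_hand_example(self):
        tm = build_trajectory_matrix(np.array([1.0, 2, 3, 4, 5]), L=2)
        assert np.array_equal(tm.entries, [[1, 2, 3, 4], [2, 3, 4, 5]])
        assert (tm.L, tm.K, tm.N) == (2, 4, 5)

    def test_constant_signal_rank_one(self):
        d = ssa_decompose(np.full(40, 3.0), L=5)
        assert d.eigenvalues[1] < 1e-10 * d.eigenvalues[0]

    def test_hankel_invariant(self, rng):
        tm = build_trajectory_matrix(rng.normal(size=30), L=7)
        for t in range(tm.L + tm.K - 2):
            vals = [tm.entries[a, t - a]
                    for a in range(max(0, t - tm.K + 1), min(tm.L, t + 1))]
            assert np.ptp(vals) == 0

    @pytest.mark.parametrize("L", [0, 1, 17, 100])
    def test_window_out_of_range(self, L):
        with pytest.raises(ssa.InvalidWindowError):
            build_trajectory_matrix(np.arange(32, dtype=float), L)


class TestDiagonalAverage:
    def test_two_by_two(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(diagonal_average(A), [1.0, 2.5, 4.0])

    def test_round_trips_hankelization(self, rng):
        x = rng.normal(size=25)
        tm = build_trajectory_matrix(x, L=8)
        assert np.allclose(diagonal_average(tm.entries), x, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            L, K = rng.integers(1, 7), rng.integers(1, 9)
            A = rng.normal(size=(L, K))
            assert np.allclose(diagonal_average(A), brute_force_diag_average(A))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diagonal_average(np.empty((0, 3)))


class TestDecompose:
    def test_constant_signal(self):
        x = np.full(20, 2.0)
        d = ssa_decompose(x, L=2)
        assert np.allclose(d.elementary_series[0], x, atol=1e-12)
        assert np.max(np.abs(d.elementary_series[1])) < 1e-10

    def test_sinusoid_is_numerically_rank_two(self):
        d = ssa_decompose(tone(10, n=512), L=6)
        lam = d.eigenvalues
        assert lam[:2].sum() > 0.95 * lam.sum()

    def test_eigenvalue_trace_identity(self, rng):
        x = rng.normal(size=60)
        tm = build_trajectory_matrix(x, L=10)
        d = ssa_decompose(x, L=10)
        frob2 = np.sum(tm.entries**2)
        assert abs(d.eigenvalues.sum() - frob2) < 1e-8 * frob2

    def test_zero_signal_gives_zero_series(self):
        d = ssa_decompose(np.zeros(16), L=4)
        assert np.all(d.elementary_series == 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.integers(min_value=8, max_value=40),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_full_reconstruction_property(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        for L in range(2, n // 2 + 1):
            d = ssa_decompose(x, L)
            recon = d.elementary_series.sum(axis=0)
            assert np.linalg.norm(recon - x) < 1e-8 * max(np.linalg.norm(x), 1)

    def test_matches_direct_svd_oracle(self, rng):
        """Covariance-eigendecomposition route vs an SVD of the trajectory
        matrix itself (independent route)."""
        x = rng.normal(size=40)
        L = 6
        tm = build_trajectory_matrix(x, L)
        U, s, Vt = np.linalg.svd(tm.entries, full_matrices=False)
        d = ssa_decompose(x, L)
        for i in range(L):
            oracle = diagonal_average(s[i] * np.outer(U[:, i], Vt[i]))
            assert np.allclose(d.elementary_series[i], oracle, atol=1e-6)

    def test_sign_flip_invariance(self, rng):
        """Elementary series are quadratic in U_i, hence sign-invariant."""
        x = rng.normal(size=30)
        d1 = ssa_decompose(x, L=5)
        d2 = ssa_decompose(-(-x), L=5)
        assert np.allclose(d1.elementary_series, d2.elementary_series)
        # quadratic form check: S_i built from -U_i equals S_i from U_i
        tm = build_trajectory_matrix(x, L=5).entries
        for i in range(5):
            u = d1.left_vectors[:, i]
            assert np.allclose(np.outer(u, u @ tm), np.outer(-u, (-u) @ tm))


class TestGrouping:
    def test_full_group_reconstructs(self, rng):
        x = rng.normal(size=48)
        d = ssa_decompose(x, L=6)
        (g,) = group_components(d, [tuple(range(6))])
        assert np.linalg.norm(g - x) < 1e-8 * np.linalg.norm(x)

    def test_singletons_equal_elementary_bitwise(self, rng):
        x = rng.normal(size=48)
        d = ssa_decompose(x, L=6)
        groups = group_components(d, [(i,) for i in range(6)])
        for i, g in enumerate(groups):
            assert np.array_equal(g, d.elementary_series[i])

    def test_four_group_scheme_sums_to_signal(self, rng):
        x = rng.normal(size=48)
        d = ssa_decompose(x, L=6)
        groups = group_components(d, EEG_GROUPING)
        assert len(groups) == 4
        assert np.allclose(np.sum(groups, axis=0), x, atol=1e-8 * np.linalg.norm(x))

    def test_overlap_rejected(self, rng):
        d = ssa_decompose(rng.normal(size=30), L=4)
        with pytest.raises(ssa.InvalidGroupingError):
            group_components(d, [(0, 1), (1, 2)])


class TestFixedSchemes:
    def test_detrended_eeg_scheme(self, rng):
        x = rng.normal(size=512)
        groups = decompose_detrended_eeg(x)
        assert len(groups) == 4
        assert all(g.size == 512 for g in groups)
        assert np.allclose(np.sum(groups, axis=0), x, atol=1e-8 * np.linalg.norm(x))
        # composition oracle, bitwise
        manual = group_components(ssa_decompose(x, 6), EEG_GROUPING)
        for a, b in zip(groups, manual):
            assert np.array_equal(a, b)

    def test_band_scheme(self, rng):
        x = rng.normal(size=512)
        s1, s2 = decompose_band(x)
        assert np.allclose(s1 + s2, x, atol=1e-8 * np.linalg.norm(x))
        assert np.sum(s1**2) >= np.sum(s2**2)

    def test_zero_signal(self):
        assert all(np.all(g == 0) for g in decompose_detrended_eeg(np.zeros(512)))

    def test_assemble_22_components(self, rng):
        x = rng.normal(size=512)
        bands = extract_all_bands(x, 512)
        comps = assemble_components(x, bands)
        assert len(comps) == 22 == len(COMPONENT_NAMES)
        for a, b in zip(comps[:4], decompose_detrended_eeg(x)):
            assert np.array_equal(a, b)
        # band blocks follow in canonical order
        for k, name in enumerate(BAND_ORDER):
            s1, s2 = decompose_band(bands[name])
            assert np.array_equal(comps[4 + 2 * k], s1)
            assert np.array_equal(comps[4 + 2 * k + 1], s2)

    def test_length_mismatch_rejected(self, rng):
        x = rng.normal(size=512)
        bands = extract_all_bands(x, 512)
        bands["alpha"] = bands["alpha"][:-1]
        with pytest.raises(ValueError):
            assemble_components(x, bands)
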