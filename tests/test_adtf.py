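"""Spectral transfer, ADTF normalization, band integration, and outflow.

The independent oracle assembles A(f,t) and everything downstream directly
from the defining equations with explicit loops, sharing no code with the
implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmsnet import synthetic as syn
from tmsnet.adtf import (
    adtf_from_fit,
    classical_dtf,
    default_freq_grid,
    integrate_band,
    normalized_adtf,
    spectral_transfer,
    total_outflow,
)
from tmsnet.tvmvar import TVMVARFit, fit_kalman

from conftest import simulate_step_trials


def make_fit(coeffs_t, fs=32.0, uc=1e-3):
    """Wrap a (T, p, n, n) coefficient trajectory as a TVMVARFit."""
    t, p, n, _ = coeffs_t.shape
    return TVMVARFit(coeffs=coeffs_t, sigma=np.zeros((t, n, n)), order=p,
                     uc=uc, fs=fs, ensemble=True)


def oracle_chain(coeffs_t, freqs, fs, band):
    """Straight-from-the-equations ADTF with explicit loops."""
    t_len, p, n, _ = coeffs_t.shape
    f_len = len(freqs)
    gamma2 = np.zeros((f_len, t_len, n, n))
    h_all = np.zeros((f_len, t_len, n, n), dtype=complex)
    for fi, f in enumerate(freqs):
        for t in range(t_len):
            a_f = np.eye(n, dtype=complex)
            for k in range(1, p + 1):
                a_f += -coeffs_t[t, k - 1] * np.exp(-2j * np.pi * f * k / fs)
            h = np.linalg.inv(a_f)
            h_all[fi, t] = h
            for i in range(n):
                denom = sum(abs(h[i, m]) ** 2 for m in range(n))
                for j in range(n):
                    gamma2[fi, t, i, j] = abs(h[i, j]) ** 2 / denom
    in_band = [fi for fi, f in enumerate(freqs) if band[0] <= f <= band[1]]
    q2 = np.zeros((t_len, n, n))
    for t in range(t_len):
        for i in range(n):
            for j in range(n):
                q2[t, i, j] = np.mean([gamma2[fi, t, i, j] for fi in in_band])
    outflow = np.zeros((t_len, n))
    for t in range(t_len):
        for j in range(n):
            outflow[t, j] = sum(q2[t, k, j] for k in range(n) if k != j) / (n - 1)
    return h_all, gamma2, q2, outflow


class TestSpectralTransfer:
    def test_zero_coupling_gives_identity_transfer(self):
        fit = make_fit(np.zeros((5, 2, 3, 3)))
        st_ = spectral_transfer(fit, default_freq_grid())
        eye = np.eye(3)
        np.testing.assert_allclose(st_.a, np.broadcast_to(eye, st_.a.shape), atol=1e-12)
        np.testing.assert_allclose(st_.h, np.broadcast_to(eye, st_.h.shape), atol=1e-12)

    def test_scalar_ar1_transfer_at_dc_limit(self):
        # |H|^2 -> 1/|1-a|^2 = 4 as f -> 0 for a = 0.5
        coeffs = np.full((3, 1, 1, 1), 0.5)
        fit = make_fit(coeffs, fs=32.0)
        st_ = spectral_transfer(fit, np.array([1e-6]))
        assert abs(st_.h[0, 0, 0, 0]) ** 2 == pytest.approx(4.0, rel=1e-4)

    def test_h_inverts_a_everywhere(self):
        rng = np.random.default_rng(0)
        coeffs = 0.2 * rng.standard_normal((10, 2, 3, 3))
        fit = make_fit(coeffs)
        st_ = spectral_transfer(fit, default_freq_grid())
        prod = np.einsum("ftij,ftjk->ftik", st_.h, st_.a)
        np.testing.assert_allclose(prod, np.broadcast_to(np.eye(3), prod.shape),
                                   atol=1e-8)

    def test_out_of_band_frequencies_rejected(self):
        fit = make_fit(np.zeros((3, 1, 2, 2)), fs=32.0)
        with pytest.raises(ValueError, match="0, fs/2"):
            spectral_transfer(fit, np.array([20.0]))


class TestNormalizedAdtf:
    def test_identity_transfer_gives_identity_pattern(self):
        fit = make_fit(np.zeros((4, 1, 3, 3)))
        g = normalized_adtf(spectral_transfer(fit, default_freq_grid()))
        np.testing.assert_allclose(g, np.broadcast_to(np.eye(3), g.shape), atol=1e-12)

    def test_equal_magnitudes_split_evenly(self):
        # 2-node H with |H11| = |H12| -> both normalized entries 0.5
        h = np.array([[[[1.0, 1.0], [0.0, 1.0]]]], dtype=complex)
        from tmsnet.adtf import SpectralTransfer

        st_ = SpectralTransfer(freqs=np.array([1.0]), a=h, h=h,
                               missing=np.zeros((1, 1), bool), fs=32.0)
        g = normalized_adtf(st_)
        assert g[0, 0, 0, 0] == pytest.approx(0.5)
        assert g[0, 0, 0, 1] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        coeffs = 0.25 * rng.standard_normal((6, 2, 3, 3))
        g = normalized_adtf(spectral_transfer(make_fit(coeffs), default_freq_grid()))
        np.testing.assert_allclose(g.sum(axis=3), 1.0, atol=1e-8)


class TestBandIntegrationAndOutflow:
    def test_constant_gamma_integrates_to_itself(self):
        g = np.full((29, 4, 3, 3), 0.37)
        q2 = integrate_band(g, default_freq_grid(), (0.5, 14.5))
        np.testing.assert_allclose(q2, 0.37)

    def test_single_grid_point_band(self):
        rng = np.random.default_rng(1)
        g = rng.random((5, 4, 2, 2))
        freqs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        q2 = integrate_band(g, freqs, (3.0, 3.0))
        np.testing.assert_allclose(q2, g[2])

    def test_band_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        g = rng.random((8, 6, 3, 3))
        freqs = np.linspace(1.0, 8.0, 8)
        q2 = integrate_band(g, freqs, (2.0, 6.0))
        expect = np.zeros((6, 3, 3))
        sel = [k for k, f in enumerate(freqs) if 2.0 <= f <= 6.0]
        for t in range(6):
            for i in range(3):
                for j in range(3):
                    expect[t, i, j] = np.mean([g[k, t, i, j] for k in sel])
        np.testing.assert_allclose(q2, expect, atol=1e-12)

    def test_printed_convention_divides_by_bandwidth(self):
        g = np.full((3, 2, 2, 2), 0.5)
        freqs = np.array([1.0, 2.0, 3.0])
        q2 = integrate_band(g, freqs, (1.0, 3.0), convention="printed")
        np.testing.assert_allclose(q2, 3 * 0.5 / 2.0)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no grid points"):
            integrate_band(np.zeros((3, 2, 2, 2)), np.array([1.0, 2.0, 3.0]),
                           (5.0, 6.0))

    def test_outflow_zero_without_cross_flow(self):
        q2 = np.broadcast_to(np.eye(3), (4, 3, 3)).copy()
        np.testing.assert_allclose(total_outflow(q2), 0.0)

    def test_outflow_attains_upper_bound(self):
        q2 = np.ones((2, 3, 3))
        np.testing.assert_allclose(total_outflow(q2), 1.0)

    def test_outflow_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        q2 = rng.random((5, 4, 4))
        out = total_outflow(q2)
        for t in range(5):
            for j in range(4):
                expect = sum(q2[t, k, j] for k in range(4) if k != j) / 3
                assert out[t, j] == pytest.approx(expect, abs=1e-12)

    def test_outflow_needs_two_nodes(self):
        with pytest.raises(ValueError, match="2 nodes"):
            total_outflow(np.ones((3, 1, 1)))


class TestFullChain:
    def test_chain_matches_equation_oracle(self):
        # 3 channels, order 3, 200 time points, random stable-ish trajectory
        rng = np.random.default_rng(4)
        coeffs = 0.2 * rng.standard_normal((200, 3, 3, 3))
        fit = make_fit(coeffs, fs=32.0)
        freqs = default_freq_grid()
        res = adtf_from_fit(fit, freqs, (0.5, 14.5))
        h, gamma2, q2, outflow = oracle_chain(coeffs, freqs, 32.0, (0.5, 14.5))
        st_ = spectral_transfer(fit, freqs)
        np.testing.assert_allclose(st_.h, h, atol=1e-10)
        np.testing.assert_allclose(res.gamma2, gamma2, atol=1e-8)
        np.testing.assert_allclose(res.q2, q2, atol=1e-8)
        np.testing.assert_allclose(res.outflow, outflow, atol=1e-8)

    def test_true_edge_dominates_null_edges(self):
        # single planted edge 0->1: its time-averaged Q2 tops every null edge
        a = np.zeros((2, 3, 3))
        a[0] = np.diag([0.3, 0.3, 0.3])
        a[0, 1, 0] = 0.6
        sch = syn.CoeffSchedule([(0.0, a)])
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            x = simulate_step_trials(sch, 30, 32.0, 1.5, seed=seed)
            fit = fit_kalman(x, 2, uc=1e-3, fs=32.0)
            res = adtf_from_fit(fit)
            qbar = res.q2[fit.warmup:].mean(axis=0)
            off = [(i, j) for i in range(3) for j in range(3) if i != j]
            true_val = qbar[1, 0]
            null_vals = [qbar[i, j] for i, j in off if (i, j) != (1, 0)]
            wins += true_val > max(null_vals)
        assert wins >= 11

    def test_stationary_adtf_matches_classical_dtf(self):
        a = np.zeros((2, 3, 3))
        a[0] = np.diag([0.4, 0.3, 0.5])
        a[0, 1, 0] = 0.4
        sch = syn.CoeffSchedule([(0.0, a)])
        rec = syn.simulate_tvmvar(sch, np.eye(3), 2000 / 32.0, 32.0, seed=5)
        x = rec.signal[None]
        fit = fit_kalman(x, 2, uc=1e-3, fs=32.0)
        res = adtf_from_fit(fit)
        adtf_bar = res.q2[fit.warmup:].mean(axis=0)
        dtf = classical_dtf(x, 2, 32.0)
        # per-edge agreement; the diagonal self-terms are not edges and are
        # excluded from every network statistic
        off = ~np.eye(3, dtype=bool)
        assert np.abs(adtf_bar - dtf)[off].max() < 0.05
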