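"""Noise estimation, the AR(1) deconvolution solver and spike-probability mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from calnet import (
    DeconvolutionModel,
    deconvolve,
    deconvolve_matrix,
    estimate_noise_sd,
    to_spike_probability,
)
from calnet.deconvolution import NOISE_SD_FLOOR, objective


class TestNoiseEstimate:
    def test_constant_trace_floors(self):
        assert estimate_noise_sd(np.full(10, 3.0)) == NOISE_SD_FLOOR

    def test_gaussian_noise_recovered(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.1, 10_000)
        assert 0.095 <= estimate_noise_sd(y) <= 0.105

    def test_robust_to_slow_ramp(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 0.1, 10_000)
        ramped = y + np.linspace(0, 5, 10_000)
        assert estimate_noise_sd(ramped) == pytest.approx(
            estimate_noise_sd(y), rel=0.05
        )

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sd(np.array([1.0, 2.0, 3.0]))


def qp_oracle_objective(y, gamma, sigma, lam):
    """Generic bound-constrained solver on the spike-space formulation."""
    T = y.size
    powers = np.subtract.outer(np.arange(T), np.arange(T))
    A = np.where(powers >= 0, gamma ** np.clip(powers, 0, None), 0.0)

    def f(s):
        r = A @ s - y
        return r @ r / (2 * sigma**2) + lam * s.sum()

    def g(s):
        return A.T @ (A @ s - y) / sigma**2 + lam

    res = minimize(
        f, np.full(T, 0.1), jac=g, bounds=[(0, None)] * T, method="L-BFGS-B",
        options={"maxiter": 3000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.fun


class TestDeconvolve:
    def test_all_zero_trace(self):
        s, C, info = deconvolve(np.zeros(20), DeconvolutionModel(gamma=0.5, noise_sd=0.1))
        assert np.all(s == 0) and np.all(C == 0)
        assert info["converged"]

    def test_single_spike_noiseless_recovery(self):
        gamma = 0.5
        y = np.zeros(40)
        y[5:] = gamma ** np.arange(35)
        model = DeconvolutionModel(gamma=gamma, sparsity_weight=1e-6, noise_sd=0.01)
        s, C, _ = deconvolve(y, model)
        expected = np.zeros(40)
        expected[5] = 1.0
        np.testing.assert_allclose(s, expected, atol=1e-3)

    def test_matches_qp_oracle_on_random_traces(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            T = int(rng.integers(15, 40))
            gamma = float(rng.uniform(0.2, 0.9))
            y = rng.normal(0, 0.3, T)
            y[rng.integers(0, T, 3)] += rng.uniform(0.5, 2.0, 3)
            sigma, lam = 0.3, float(rng.uniform(0.2, 2.0))
            _, _, info = deconvolve(
                y, DeconvolutionModel(gamma=gamma, sparsity_weight=lam, noise_sd=sigma)
            )
            want = qp_oracle_objective(y, gamma, sigma, lam)
            assert info["objective"] <= want * (1 + 1e-6) + 1e-9

    def test_nonnegative_output_always(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 60)
        s, _, _ = deconvolve(y, DeconvolutionModel(gamma=0.7, noise_sd=0.5))
        assert np.all(s >= 0)

    def test_large_sparsity_weight_shrinks_to_zero(self):
        rng = np.random.default_rng(4)
        y = np.abs(rng.normal(0, 0.5, 50))
        s, _, _ = deconvolve(
            y, DeconvolutionModel(gamma=0.5, sparsity_weight=1e6, noise_sd=0.5)
        )
        assert np.all(s < 1e-4)

    def test_small_lambda_small_sigma_interpolates_feasible_trace(self):
        """With lambda ~ 0 and tight noise, C reproduces a feasible trace."""
        gamma = 0.6
        s_true = np.zeros(30)
        s_true[[4, 12, 20]] = [1.0, 0.5, 2.0]
        C_true = np.empty(30)
        C_true[0] = s_true[0]
        for t in range(1, 30):
            C_true[t] = gamma * C_true[t - 1] + s_true[t]
        s, C, _ = deconvolve(
            C_true, DeconvolutionModel(gamma=gamma, sparsity_weight=1e-8, noise_sd=1e-3)
        )
        np.testing.assert_allclose(C, C_true, atol=1e-4)
        np.testing.assert_allclose(s, s_true, atol=1e-4)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            deconvolve(np.array([1.0, np.nan, 0.0, 0.0]),
                       DeconvolutionModel(gamma=0.5, noise_sd=0.1))


def test_matrix_median_centering_suppresses_offset_noise(rng):
    """A positively offset pure-noise cell yields no spurious amplitudes."""
    y = 0.04 + rng.normal(0, 0.05, size=(120, 1))
    amp = deconvolve_matrix(y, DeconvolutionModel(gamma=0.1))
    assert np.sum(amp > 0) <= 2


class TestSpikeProbability:
    def test_max_normalization(self):
        out = to_spike_probability(np.array([0.0, 2.0, 1.0])[:, None])
        np.testing.assert_allclose(out.values[:, 0], [0.0, 1.0, 0.5])

    def test_all_zero_cell_stays_zero(self):
        out = to_spike_probability(np.zeros((5, 2)))
        assert np.all(out.values == 0)

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            to_spike_probability(np.array([[-0.1]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_active_cells_peak_at_exactly_one(self, seed):
        rng = np.random.default_rng(seed)
        amp = np.abs(rng.normal(0, 1, size=(20, 4))) * (rng.random((20, 4)) < 0.3)
        out = to_spike_probability(amp)
        for j in range(4):
            col_max = out.values[:, j].max()
            assert col_max in (0.0, 1.0)
            assert out.values[:, j].min() >= 0.0


def test_objective_helper_consistency():
    y = np.array([0.0, 1.0, 0.5, 0.25])
    val = objective(y, y, gamma=0.5, sigma=0.1, lam=1.0)
    # perfect fit: only the L1 term remains (s = [0, 1, 0, 0])
    assert val == pytest.approx(1.0)
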