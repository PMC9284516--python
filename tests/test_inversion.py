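"""Background fitting, Tikhonov inversion, alpha selection, modes."""

import numpy as np
import pytest

from deeroligo.forward import DistanceDistribution, form_factor, DeerTrace, powder_kernel
from deeroligo.inversion import (
    NoModulationError,
    count_modes,
    distribution_mode,
    fit_background,
    nonneg_tikhonov,
    second_derivative_operator,
    select_alpha,
    tikhonov_invert,
)
from deeroligo.inversion import _design
from deeroligo.synthetic import DeerAcquisitionSpec, generate_deer_trace


def _gaussian(r, mean, sd):
    return DistanceDistribution(r, np.exp(-((r - mean) ** 2) / (2 * sd**2))).normalized()


def _trace(p, lam=0.3, k=5e-4, noise=0.0, seed=0):
    acq = DeerAcquisitionSpec(
        modulation_depth=lam, background_rate=k, noise_sd=noise, seed=seed
    )
    trace, _ = generate_deer_trace(p, acq)
    return trace


class TestFitBackground:
    def test_round_trip_recovers_lambda_and_k(self, r_grid):
        p = _gaussian(r_grid, 2.25, 0.2)
        k_fit, lam_fit, _, _ = fit_background(_trace(p, lam=0.35, k=6e-4))
        assert lam_fit == pytest.approx(0.35, abs=0.02)
        assert k_fit == pytest.approx(6e-4, rel=0.05)

    def test_no_modulation_raises(self, r_grid):
        p = _gaussian(r_grid, 2.25, 0.2)
        with pytest.raises(NoModulationError):
            fit_background(_trace(p, lam=0.0, noise=0.005, seed=3))

    def test_identity_case_reproduces_kernel(self, r_grid):
        # k = 0, lambda ~ 1, near-delta distribution: corrected F is the
        # powder kernel of the peak distance
        i0 = np.argmin(np.abs(r_grid - 2.5))
        p = np.zeros_like(r_grid)
        p[i0] = 1.0
        p = DistanceDistribution(r_grid, p).normalized()
        trace = _trace(p, lam=0.9, k=0.0)
        _, _, tau, F = fit_background(trace)
        assert np.abs(F - powder_kernel(tau, r_grid[i0])).max() < 0.05

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_background(DeerTrace(np.arange(10.0), np.ones(10)))


class TestTikhonov:
    def test_round_trip_mode_recovery(self, r_grid):
        p = _gaussian(r_grid, 2.25, 0.2)
        trace = _trace(p, noise=0.01, seed=5)
        _, _, tau, F = fit_background(trace)
        inv, _, _ = tikhonov_invert(tau, F, r_grid, alpha=1.0)
        assert distribution_mode(inv) == pytest.approx(2.25, abs=0.1)

    def test_output_nonnegative_unit_integral(self, r_grid):
        p = _gaussian(r_grid, 3.0, 0.4)
        trace = _trace(p, noise=0.02, seed=6)
        _, _, tau, F = fit_background(trace)
        inv, _, _ = tikhonov_invert(tau, F, r_grid, alpha=0.5)
        assert np.all(inv.p >= 0)
        assert np.trapezoid(inv.p, inv.r) == pytest.approx(1.0, abs=1e-9)

    def test_penalty_monotone_in_alpha(self, r_grid):
        p = _gaussian(r_grid, 2.25, 0.2)
        tau = 10.0 * np.arange(200)
        F = form_factor(p, tau)
        Kw = _design(tau, r_grid)
        L = second_derivative_operator(r_grid.size)
        penalties = [
            np.linalg.norm(L @ nonneg_tikhonov(Kw, F, L, a))
            for a in np.logspace(-2, 3, 10)
        ]
        assert np.all(np.diff(penalties) <= 1e-9)

    def test_flat_signal_concentrates_at_upper_edge(self, r_grid):
        # F == 1 carries no decay: mass accumulates at the largest
        # distances, outside the sensitivity window
        tau = 10.0 * np.arange(200)
        inv, _, _ = tikhonov_invert(tau, np.ones(200), r_grid, alpha=1.0)
        upper = inv.r > 7.0
        assert np.trapezoid(inv.p[upper], inv.r[upper]) > 0.9

    def test_mismatched_shapes_rejected(self, r_grid):
        with pytest.raises(ValueError):
            tikhonov_invert(np.arange(10.0), np.ones(11), r_grid, alpha=1.0)
        with pytest.raises(ValueError):
            nonneg_tikhonov(
                np.ones((5, 4)), np.ones(5), second_derivative_operator(6), 1.0
            )


class TestActiveSetOracle:
    def test_matches_brute_force_on_coarse_grid(self, active_set_oracle):
        r = np.linspace(1.5, 4.0, 10)
        tau = np.linspace(0.0, 1500.0, 40)
        p_true = np.exp(-((r - 2.4) ** 2) / (2 * 0.3**2))
        p_true /= np.trapezoid(p_true, r)
        Kw = _design(tau, r)
        F = Kw @ p_true
        L = second_derivative_operator(r.size)
        alpha = 0.1
        A = np.vstack([Kw, alpha * L])
        b = np.concatenate([F, np.zeros(L.shape[0])])
        assert np.abs(
            nonneg_tikhonov(Kw, F, L, alpha) - active_set_oracle(A, b)
        ).max() < 1e-6


class TestSelectAlpha:
    def test_deterministic(self, r_grid):
        p = _gaussian(r_grid, 2.25, 0.2)
        trace = _trace(p, noise=0.01, seed=9)
        _, _, tau, F = fit_background(trace)
        assert select_alpha(tau, F, r_grid) == select_alpha(tau, F, r_grid)

    def test_noiseless_selects_weaker_regularization(self, r_grid):
        p = _gaussian(r_grid, 2.25, 0.2)
        _, _, tau0, F0 = fit_background(_trace(p, noise=0.0))
        _, _, tau1, F1 = fit_background(_trace(p, noise=0.01, seed=4))
        grid = np.logspace(-4, 2, 25)
        a_clean = select_alpha(tau0, F0, r_grid, grid)
        a_noisy = select_alpha(tau1, F1, r_grid, grid)
        assert a_clean < a_noisy
        # noiseless corner sits in the weak-regularization third of the grid
        assert a_clean <= grid[len(grid) // 3]

    def test_small_grid_rejected(self, r_grid):
        with pytest.raises(ValueError):
            select_alpha(np.arange(50.0), np.ones(50), r_grid, np.logspace(-2, 1, 5))


class TestModes:
    def test_delta_mode(self, r_grid):
        p = np.zeros_like(r_grid)
        i = np.argmin(np.abs(r_grid - 2.2))
        p[i] = 1.0
        assert distribution_mode(
            DistanceDistribution(r_grid, p).normalized()
        ) == pytest.approx(r_grid[i])

    def test_gaussian_mode_within_grid_step(self, r_grid):
        p = _gaussian(r_grid, 3.0, 0.4)
        step = r_grid[1] - r_grid[0]
        assert abs(distribution_mode(p) - 3.0) <= step

    def test_bimodal_higher_peak_wins(self, r_grid):
        p = np.exp(-((r_grid - 1.6) ** 2) / 0.005) + 0.6 * np.exp(
            -((r_grid - 1.05) ** 2) / 0.005
        )
        assert distribution_mode(
            DistanceDistribution(r_grid, p).normalized()
        ) == pytest.approx(1.6, abs=0.05)

    def test_flat_distribution_raises(self, r_grid):
        with pytest.raises(ValueError):
            distribution_mode(DistanceDistribution(r_grid, np.ones_like(r_grid)))

    def test_count_modes_on_bimodal(self, r_grid):
        p = np.exp(-((r_grid - 1.6) ** 2) / 0.01) + 0.7 * np.exp(
            -((r_grid - 2.8) ** 2) / 0.01
        )
        assert count_modes(DistanceDistribution(r_grid, p).normalized()) == 2
        g = _gaussian(r_grid, 2.25, 0.2)
        assert count_modes(g) == 1
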