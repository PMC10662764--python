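"""Energy landscapes, stationary densities, and the sequential learning rule."""

import numpy as np
import pytest
from scipy.special import i0

from ringdrift.environment import EnvironmentalPrior, sample_stimuli
from ringdrift.landscapes import (LearningState, cosine, dual_cosine, eval_landscape, flat,
                                  gridded, landscape_gradient, learning_update,
                                  longrun_landscape, posterior_to_landscape,
                                  stationary_density, von_mises_kernel)
from ringdrift.ring import make_grid


class TestEvalAndGradient:
    def test_flat_is_zero(self, grid):
        assert np.allclose(eval_landscape(flat(), grid.centers), 0.0)
        assert np.allclose(landscape_gradient(flat(), grid.centers), 0.0)

    def test_cosine_per_well_amplitude(self):
        # U(0) = -(A_p / n) at the well for the per-well normalization
        assert eval_landscape(cosine(1.0, 4), 0.0) == pytest.approx(-0.25)
        assert eval_landscape(cosine(1.0, 4, convention="plain"), 0.0) == pytest.approx(-1.0)

    def test_cosine_minima_at_offsets(self, grid):
        spec = cosine(0.8, 4, theta_off=0.3)
        U = eval_landscape(spec, grid.centers)
        wells = grid.centers[U == U.min()]
        assert np.min(np.abs(wells - 0.3)) <= grid.bin_width

    def test_gradient_examples(self):
        assert landscape_gradient(cosine(1.0, 4), 0.0) == pytest.approx(0.0)
        assert landscape_gradient(cosine(1.0, 4), np.pi / 8) == pytest.approx(1.0)
        # plain convention carries the extra factor n
        assert landscape_gradient(cosine(1.0, 4, convention="plain"),
                                  np.pi / 8) == pytest.approx(4.0)

    def test_dual_cosine_drift_is_sum_of_sines(self):
        spec = dual_cosine(0.5, 2, 0.3, 6, theta_off=0.1)
        th = np.linspace(-np.pi, np.pi, 50)
        expected = 0.5 * np.sin(2 * (th - 0.1)) + 0.3 * np.sin(6 * (th - 0.1))
        assert np.allclose(landscape_gradient(spec, th), expected)

    def test_gridded_gradient_matches_parametric(self, grid):
        spec = cosine(1.0, 4)
        g = gridded(eval_landscape(spec, grid.centers))
        got = landscape_gradient(g, grid.centers, grid)
        assert np.max(np.abs(got - landscape_gradient(spec, grid.centers))) < 1e-3

    def test_gauge_invariance(self, grid):
        base = eval_landscape(cosine(1.0, 4), grid.centers)
        g1, g2 = gridded(base), gridded(base + 5.0)
        assert np.allclose(landscape_gradient(g1, grid.centers, grid),
                           landscape_gradient(g2, grid.centers, grid))

    def test_gridded_wrong_length_rejected(self, grid):
        with pytest.raises(ValueError):
            eval_landscape(gridded(np.zeros(100)), grid.centers, grid)

    def test_parametric_gradient_matches_finite_differences(self, grid):
        for spec in (cosine(1.0, 4), dual_cosine(1.0, 3, 0.5, 7)):
            U = eval_landscape(spec, grid.centers)
            fd = (np.roll(U, -1) - np.roll(U, 1)) / (2 * grid.bin_width)
            assert np.max(np.abs(fd - landscape_gradient(spec, grid.centers))) < \
                grid.bin_width ** 2 * 50


class TestStationaryDensity:
    def test_flat_is_uniform(self, grid):
        p = stationary_density(flat(), 0.1, grid)
        assert np.allclose(p, 1 / grid.n_bins)

    def test_cosine_matches_boltzmann_closed_form(self, grid):
        A_p, n, sigma = 0.05, 4, 0.3
        p = stationary_density(cosine(A_p, n), sigma, grid)
        kappa = 2 * A_p / (n * sigma**2)
        expected = np.exp(kappa * np.cos(n * grid.centers))
        expected /= expected.sum()
        assert np.max(np.abs(p - expected)) < 1e-12

    def test_requires_positive_sigma(self):
        with pytest.raises(ValueError):
            stationary_density(flat(), 0.0)

    def test_detailed_balance_zero_flux(self, grid):
        sigma = 0.3
        spec = cosine(0.05, 4)
        p = stationary_density(spec, sigma, grid) / grid.bin_width  # density
        # spectral derivative: the density is smooth and periodic
        k = np.fft.rfftfreq(grid.n_bins, d=grid.bin_width) * 2 * np.pi
        dp = np.fft.irfft(1j * k * np.fft.rfft(p), n=grid.n_bins)
        J = -landscape_gradient(spec, grid.centers) * p - 0.5 * sigma**2 * dp
        assert np.max(np.abs(J)) < 1e-6


class TestPosteriorInversion:
    def test_zero_variation_gives_flat(self, grid):
        spec = posterior_to_landscape(np.zeros(grid.n_bins), 0.05, grid)
        assert np.allclose(spec.grid_values, 0.0)

    def test_proportional_to_negative_variation(self, grid):
        l = 0.01 * np.cos(4 * grid.centers)
        spec = posterior_to_landscape(l, 0.05, grid)
        assert np.corrcoef(spec.grid_values, -l)[0, 1] > 0.999999

    def test_round_trip_recovers_posterior(self, grid):
        eps = 0.01
        l = eps * np.cos(4 * grid.centers)
        spec = posterior_to_landscape(l, 0.05, grid)
        p = stationary_density(spec, 0.05, grid) / grid.bin_width
        assert np.max(np.abs(p - (1 / (2 * np.pi) + l))) < 1e-3

    def test_nonzero_mean_rejected(self, grid):
        with pytest.raises(ValueError):
            posterior_to_landscape(np.ones(grid.n_bins), 0.05, grid)


class TestLearning:
    def test_first_update_from_flat(self, grid):
        st = LearningState(beta=8.0, s=5.0, h=0.25)
        st = learning_update(st, 0.7)
        expected = 0.25 - 5.0 * von_mises_kernel(grid.centers, 0.7, 8.0)
        assert np.allclose(st.U_est, expected)
        assert st.N == 1

    def test_matches_unrolled_average(self, grid):
        rng = np.random.default_rng(0)
        thetas = rng.uniform(-np.pi, np.pi, 17)
        st = LearningState(beta=4.0, s=2.0, h=0.25)
        for th in thetas:
            st = learning_update(st, th)
        unrolled = np.mean([0.25 - 2.0 * von_mises_kernel(grid.centers, th, 4.0)
                            for th in thetas], axis=0)
        assert np.allclose(st.U_est, unrolled, atol=1e-12)

    def test_permutation_invariance(self, grid):
        rng = np.random.default_rng(1)
        thetas = rng.uniform(-np.pi, np.pi, 20)
        st1 = LearningState(beta=8.0, s=5.0)
        st2 = LearningState(beta=8.0, s=5.0)
        for th in thetas:
            st1 = learning_update(st1, th)
        for th in rng.permutation(thetas):
            st2 = learning_update(st2, th)
        assert np.allclose(st1.U_est, st2.U_est, atol=1e-12)

    def test_initial_landscape_persists_as_pseudocount(self, grid):
        U0 = -np.cos(4 * grid.centers)
        st = LearningState(beta=8.0, s=5.0, U_est=U0)
        st = learning_update(st, 0.0)
        incr = 0.25 - 5.0 * von_mises_kernel(grid.centers, 0.0, 8.0)
        assert np.allclose(st.U_est, (U0 + incr) / 2)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            LearningState(beta=0.0, s=5.0)
        with pytest.raises(ValueError):
            LearningState(beta=8.0, s=-1.0)

    def test_unnormalized_kernel_variant(self, grid):
        st = LearningState(beta=2.0, s=1.0, h=0.0, normalize_kernel=False)
        st = learning_update(st, 0.0)
        assert st.U_est.min() == pytest.approx(-np.exp(2.0))


class TestLongRun:
    def test_uniform_prior_gives_flat(self):
        spec = longrun_landscape(EnvironmentalPrior(form="uniform"), beta=8.0)
        assert np.allclose(spec.grid_values, 0.0, atol=1e-12)

    def test_wells_at_prior_peaks(self, prior4, grid):
        spec = longrun_landscape(prior4, beta=8.0)
        well = grid.centers[np.argmin(spec.grid_values)]
        peaks = np.array([-np.pi, -np.pi / 2, 0, np.pi / 2])
        assert np.min(np.abs(well - peaks)) <= grid.bin_width

    def test_dominant_mode_matches_prior(self, prior4):
        spec = longrun_landscape(prior4, beta=8.0)
        mag = np.abs(np.fft.rfft(spec.grid_values))
        assert np.argmax(mag[1:]) + 1 == 4

    def test_empirical_learning_converges_to_longrun(self, prior4, grid):
        samples = sample_stimuli(prior4, 5000, seed=5)
        st = LearningState(beta=8.0, s=5.0, h=0.25)
        for th in samples:
            st = learning_update(st, th)
        U_inf = longrun_landscape(prior4, beta=8.0, s=5.0).grid_values
        emp = st.U_est - st.U_est.mean()
        assert np.corrcoef(emp, U_inf)[0, 1] > 0.95
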