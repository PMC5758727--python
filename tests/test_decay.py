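"""Decay model, simulation and fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flimredox import (
    BiExpParams,
    DecayHistogram,
    FitOptions,
    IRFModel,
    InsufficientPhotonsError,
    TimeAxis,
    amplitude_weighted_lifetime,
    fit_biexp,
    fit_image,
    model_decay,
    normalized_fractions,
    reduced_chi2,
    simulate_decay,
)
from flimredox.decay import bin_spatial

from conftest import brute_force_model


class TestModelDecay:
    def test_mono_exponential_closed_form(self, axis, delta_irf):
        """With a delta IRF a single component is the bare periodic exponential."""
        tau, amp = 2.0, 500.0
        params = BiExpParams(a1=0.0, a2=amp, tau1=1.0, tau2=tau)
        out = model_decay(params, delta_irf, axis)
        periodic_factor = 1.0 / (1.0 - np.exp(-axis.period / tau))
        assert out[0] == pytest.approx(amp * periodic_factor, rel=1e-12)
        np.testing.assert_allclose(
            out, amp * periodic_factor * np.exp(-axis.times / tau), rtol=1e-9
        )

    def test_zero_amplitudes_give_flat_background(self, axis, irf):
        params = BiExpParams(a1=0.0, a2=0.0, tau1=0.5, tau2=2.5, background=7.0)
        np.testing.assert_allclose(model_decay(params, irf, axis), 7.0, rtol=1e-12)

    def test_matches_brute_force_periodic_oracle(self, axis, irf):
        """Closed-form periodic sum + FFT convolution vs explicit 200-period O(n^2) sum."""
        params = BiExpParams(a1=100.0, a2=100.0, tau1=0.5, tau2=2.5)
        fast = model_decay(params, irf, axis)
        slow = brute_force_model(params, irf.discretize(axis), axis, n_periods=200)
        assert np.max(np.abs(fast - slow) / np.max(slow)) < 1e-9

    def test_values_never_below_background(self, axis, irf):
        params = BiExpParams(a1=50.0, a2=20.0, tau1=0.3, tau2=3.0, background=2.0)
        assert np.all(model_decay(params, irf, axis) >= 2.0)

    def test_degenerate_long_lifetime_rejected(self, axis, irf):
        params = BiExpParams(a1=1.0, a2=1.0, tau1=0.5, tau2=50.0 * axis.period)
        with pytest.raises(ValueError, match="degenerate"):
            model_decay(params, irf, axis)


class TestSimulateDecay:
    def test_total_photons_within_poisson_concentration(self, axis, irf, truth_params):
        total = 1_000_000
        hist = simulate_decay(truth_params, irf, axis, total, seed=0)
        assert abs(hist.total_photons - total) < 5 * np.sqrt(total)

    def test_same_seed_is_deterministic(self, axis, irf, truth_params):
        h1 = simulate_decay(truth_params, irf, axis, 5000, seed=42)
        h2 = simulate_decay(truth_params, irf, axis, 5000, seed=42)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_bin_means_converge_to_model(self, axis, irf, truth_params):
        """Law of large numbers: replicate-mean counts approach the scaled model."""
        total = 10_000
        mean = model_decay(truth_params, irf, axis)
        mean = mean * (total / mean.sum())
        rng = np.random.default_rng(7)
        acc = np.zeros(axis.n_bins)
        n_rep = 500
        for _ in range(n_rep):
            acc += simulate_decay(truth_params, irf, axis, total, seed=rng).counts
        acc /= n_rep
        # 5 sigma Monte-Carlo band per bin
        tol = 5 * np.sqrt(np.maximum(mean, 1.0) / n_rep)
        assert np.all(np.abs(acc - mean) < tol)


class TestFractionsAndLifetime:
    @pytest.mark.parametrize(
        "a1,a2,expected",
        [(1.0, 1.0, (0.5, 0.5)), (3.0, 1.0, (0.75, 0.25)), (0.0, 2.0, (0.0, 1.0))],
    )
    def test_normalized_fractions(self, a1, a2, expected):
        assert normalized_fractions(a1, a2) == pytest.approx(expected)

    @given(st.floats(1e-6, 1e6))
    def test_scale_invariance(self, c):
        assert normalized_fractions(3.0 * c, 1.0 * c) == pytest.approx((0.75, 0.25))

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            normalized_fractions(0.0, 0.0)

    @pytest.mark.parametrize(
        "a1,a2,expected",
        [(6.0, 4.0, 1.3), (1.0, 0.0, 0.5), (0.0, 1.0, 2.5)],
    )
    def test_amplitude_weighted_lifetime(self, a1, a2, expected):
        params = BiExpParams(a1=a1, a2=a2, tau1=0.5, tau2=2.5)
        assert amplitude_weighted_lifetime(params) == pytest.approx(expected)

    @given(st.floats(0.01, 0.99))
    def test_tau_m_bounded_by_components(self, a1_pct):
        params = BiExpParams(a1=a1_pct, a2=1 - a1_pct, tau1=0.5, tau2=2.5)
        assert 0.5 <= amplitude_weighted_lifetime(params) <= 2.5


class TestReducedChi2:
    def test_exact_model_gives_zero(self, axis):
        model = np.full(axis.n_bins, 10.0)
        hist = DecayHistogram(counts=model.copy(), axis=axis)
        assert reduced_chi2(hist, model, n_free_params=4) == 0.0

    def test_quadratic_in_residuals(self, axis):
        model = np.full(axis.n_bins, 100.0)
        base = model + 5.0
        doubled = model + 10.0
        c1 = reduced_chi2(DecayHistogram(counts=base, axis=axis), model, 4)
        c2 = reduced_chi2(DecayHistogram(counts=doubled, axis=axis), model, 4)
        assert c2 == pytest.approx(4 * c1)

    def test_poisson_calibration_mean_near_one(self, axis):
        """On true-model Poisson realisations the statistic averages ~1."""
        model = np.full(axis.n_bins, 50.0)
        rng = np.random.default_rng(3)
        vals = [
            reduced_chi2(
                DecayHistogram(counts=rng.poisson(model), axis=axis), model, 4
            )
            for _ in range(200)
        ]
        assert 0.9 < np.mean(vals) < 1.1

    def test_too_few_bins_rejected(self, axis):
        model = np.zeros(axis.n_bins)
        model[:3] = 10.0
        hist = DecayHistogram(counts=model.copy(), axis=axis)
        with pytest.raises(ValueError, match="undefined"):
            reduced_chi2(hist, model, n_free_params=4)


class TestFitBiexp:
    def test_noiseless_recovery(self, axis, irf, truth_params):
        mean = model_decay(truth_params, irf, axis)
        hist = DecayHistogram(counts=mean * (1e5 / mean.sum()), axis=axis)
        fit = fit_biexp(hist, irf, FitOptions(background=0.0))
        assert fit.a1_pct == pytest.approx(0.7, abs=1e-3)
        assert fit.params.tau1 == pytest.approx(0.4, abs=1e-3)
        assert fit.params.tau2 == pytest.approx(2.5, abs=1e-3)
        assert fit.converged

    def test_noisy_recovery_median_error(self, axis, irf, truth_params):
        """At 5,000 photons the median |a2% error| stays below 0.03 (100 seeds)."""
        errors = []
        for seed in range(100):
            hist = simulate_decay(truth_params, irf, axis, 5000, seed=seed)
            fit = fit_biexp(hist, irf, FitOptions(background=0.0))
            errors.append(abs(fit.a2_pct - 0.3))
        assert np.median(errors) < 0.03

    def test_insufficient_photons_is_explicit(self, axis, irf, truth_params):
        hist = simulate_decay(truth_params, irf, axis, 100, seed=0)
        with pytest.raises(InsufficientPhotonsError):
            fit_biexp(hist, irf, FitOptions(min_photons=300))

    def test_non_finite_counts_rejected(self, axis, irf):
        counts = np.full(axis.n_bins, 10.0)
        hist = DecayHistogram(counts=counts, axis=axis)
        object.__setattr__(hist, "counts", counts * np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            fit_biexp(hist, irf)

    def test_fraction_scale_invariance(self, axis, irf, truth_params):
        """Multiplying all counts by k leaves the amplitude fractions unchanged."""
        hist = simulate_decay(truth_params, irf, axis, 20000, seed=5)
        fit1 = fit_biexp(hist, irf, FitOptions(background=0.0))
        scaled = DecayHistogram(counts=hist.counts * 8.0, axis=axis)
        fit2 = fit_biexp(scaled, irf, FitOptions(background=0.0))
        assert fit2.a1_pct == pytest.approx(fit1.a1_pct, abs=2e-3)

    def test_canonicalization_of_swapped_labels(self, axis, irf):
        """Decays generated with swapped component labels fit to one canonical result."""
        forward = BiExpParams(a1=7000.0, a2=3000.0, tau1=0.4, tau2=2.5)
        swapped = BiExpParams(a1=3000.0, a2=7000.0, tau1=2.5, tau2=0.4)
        assert swapped.canonicalize() == forward
        mean_f = model_decay(forward, irf, axis)
        mean_s = model_decay(swapped.canonicalize(), irf, axis)
        np.testing.assert_allclose(mean_f, mean_s, rtol=1e-12)
        fit = fit_biexp(DecayHistogram(counts=mean_s, axis=axis), irf, FitOptions(background=0.0))
        assert fit.params.tau1 <= fit.params.tau2

    def test_degenerate_lifetimes_flagged(self, axis, irf):
        """A mono-exponential decay drives the two lifetimes together and is flagged."""
        mono = BiExpParams(a1=0.0, a2=5000.0, tau1=1.2, tau2=1.2)
        mean = model_decay(mono, irf, axis)
        fit = fit_biexp(
            DecayHistogram(counts=mean, axis=axis),
            irf,
            FitOptions(background=0.0, tau1_bounds=(0.05, 1.3), tau2_bounds=(1.1, 8.0)),
        )
        assert fit.degenerate or abs(fit.tau_m - 1.2) < 0.05

    def test_recovery_bias_across_truth_grid(self, axis, irf):
        """Bias of recovered a2% stays below 0.02 over the physiological truth grid."""
        rng_seeds = range(30)
        for a2_pct in (0.1, 0.5, 0.9):
            for tau1, tau2 in ((0.3, 2.0), (0.6, 3.5)):
                truth = BiExpParams(
                    a1=(1 - a2_pct) * 1e4, a2=a2_pct * 1e4, tau1=tau1, tau2=tau2
                )
                errs = []
                for seed in rng_seeds:
                    hist = simulate_decay(truth, irf, axis, 10_000, seed=seed)
                    fit = fit_biexp(hist, irf, FitOptions(background=0.0))
                    errs.append(fit.a2_pct - a2_pct)
                assert abs(np.mean(errs)) < 0.02


class TestFitImage:
    def test_maps_and_photon_floor(self, irf):
        axis = TimeAxis(n_bins=128, period=12.5)
        truth = BiExpParams(a1=700.0, a2=300.0, tau1=0.4, tau2=2.5)
        mean = model_decay(truth, irf, axis)
        bright = mean * (3000 / mean.sum())
        rng = np.random.default_rng(0)
        cube = np.zeros((128, 2, 2))
        cube[:, 0, 0] = rng.poisson(bright)
        cube[:, 0, 1] = rng.poisson(bright)
        cube[:, 1, 0] = rng.poisson(bright * 0.01)  # below floor
        cube[:, 1, 1] = rng.poisson(bright)
        maps = fit_image(cube, irf, axis, FitOptions(background=0.0))
        assert maps["converged"][0, 0] == 1.0
        assert np.isnan(maps["a2_pct"][1, 0])
        assert maps["a2_pct"][0, 0] == pytest.approx(0.3, abs=0.05)

    def test_spatial_binning_sums_neighbourhood(self):
        cube = np.ones((4, 6, 6))
        binned = bin_spatial(cube, kernel=1)
        assert binned[0, 3, 3] == pytest.approx(9.0)
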