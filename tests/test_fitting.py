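"""Lifetime-fitting tests: window rules, reconvolution, tail regression, chi2."""

import numpy as np
import pytest

from flimbench.core import DecayHistogram, DecayModelParams, expected_counts
from flimbench.fitting import (
    FitWindow,
    WindowError,
    find_window,
    fit_reconvolution,
    fit_tail,
    reduced_chi_squared,
)
from flimbench.synthetic import (
    ReemissionParams,
    simulate_decay,
    simulate_decay_from_kernel,
    simulate_irf,
    simulate_reemission_decay,
)


class TestFindWindow:
    def test_reconvolution_thresholds_read_at_whole_bins(self):
        counts = np.array([0, 80, 100, 50, 10, 1, 0])
        w = find_window(counts, "reconvolution", 0.80, 0.01)
        assert (w.start_bin, w.end_bin) == (1, 5)

    def test_tail_thresholds_read_at_whole_bins(self):
        counts = np.array([0, 50, 100, 95, 85, 40, 19, 5])
        w = find_window(counts, "tail", 0.90, 0.20)
        assert (w.start_bin, w.end_bin) == (4, 5)

    def test_missing_threshold_error_names_the_threshold(self):
        with pytest.raises(WindowError, match="0.01"):
            find_window(np.array([0, 100, 0, 0]), "reconvolution", 0.80, 0.01)

    def test_idempotent(self, bench, bench_irf):
        d = simulate_decay(DecayModelParams(2.43, 1e5), bench_irf, bench, seed=1)
        w1 = find_window(d.counts)
        w2 = find_window(d.counts)
        assert w1 == w2

    def test_window_brackets_peak_on_simulated_decay(self, bench, bench_irf):
        """On a realistic decay the 80%/1% window starts before the peak and
        ends where counts are between 0.5% and 2% of the maximum."""
        d = simulate_decay(DecayModelParams(2.43, 1e5), bench_irf, bench, seed=3)
        w = find_window(d.counts)
        peak = int(np.argmax(d.counts))
        assert w.start_bin <= peak < w.end_bin
        end_frac = d.counts[w.end_bin] / d.counts[peak]
        assert 0.005 <= end_frac <= 0.02

    def test_peak_tie_breaks_earliest(self):
        counts = np.array([0, 100, 100, 50, 1])
        w = find_window(counts, "reconvolution", 0.80, 0.01)
        assert w.start_bin == 1


class TestReducedChiSquared:
    def test_exact_model_gives_zero(self):
        c = np.array([5.0, 9.0, 2.0])
        assert reduced_chi_squared(c, c, FitWindow(0, 2), 0) == 0.0

    def test_hand_arithmetic(self):
        counts = np.array([4.0, 9.0])
        model = np.array([2.0, 6.0])
        assert reduced_chi_squared(counts, model, FitWindow(0, 1), 0) == pytest.approx(1.0)

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            reduced_chi_squared(np.ones(3), np.ones(3), FitWindow(0, 2), 3)

    def test_well_specified_fit_has_unit_chi2(self, bench, bench_irf):
        """Over seeded Poisson realizations at 1e5 photons, the mean reduced
        chi-squared of the reconvolution fit lies in [0.9, 1.1]."""
        params = DecayModelParams(tau=2.43, amplitude=1e5)
        chi2 = []
        for seed in range(40):
            d = simulate_decay(params, bench_irf, bench, seed=seed)
            chi2.append(fit_reconvolution(d, bench_irf).chi2_reduced)
        assert 0.9 < np.mean(chi2) < 1.1


class TestFitReconvolution:
    def test_noise_free_self_consistency(self, bench):
        """Fitting the exact expected-counts curve (delta IRF) recovers tau
        to 1e-6 relative with chi2 ~ 0."""
        from test_core import delta_irf

        irf = delta_irf(bench, bin_index=40)
        params = DecayModelParams(tau=2.5, amplitude=1e5)
        mu = expected_counts(params, irf, bench)
        d = DecayHistogram(bench, mu)
        r = fit_reconvolution(d, irf)
        assert r.converged
        assert r.tau == pytest.approx(2.5, rel=1e-6)
        assert r.chi2_reduced < 1e-6

    def test_grid_mismatch_rejected(self, bench, camera, camera_irf):
        d = DecayHistogram(bench, np.ones(bench.n_bins, dtype=int))
        with pytest.raises(ValueError):
            fit_reconvolution(d, camera_irf)

    @pytest.mark.parametrize("tau_true", [0.80, 3.61])
    def test_monte_carlo_recovery(self, bench, bench_irf, tau_true):
        """Median relative error below 2% over seeded Poisson replicates at
        the protocol photon budget."""
        params = DecayModelParams(tau=tau_true, amplitude=1e5)
        errors = []
        for seed in range(25):
            d = simulate_decay(params, bench_irf, bench, seed=seed)
            r = fit_reconvolution(d, bench_irf)
            errors.append(abs(r.tau - tau_true) / tau_true)
        assert np.median(errors) < 0.02


class TestFitTail:
    def test_exact_exponential_recovered_to_machine_precision(self, bench):
        tau = 2.0
        counts = 1000.0 * np.exp(-bench.centers / tau)
        d = DecayHistogram(bench, counts)
        r = fit_tail(d)
        assert r.tau == pytest.approx(tau, rel=1e-12)

    def test_scale_invariance_of_noise_free_fit(self, bench):
        counts = 500.0 * np.exp(-bench.centers / 1.3)
        r1 = fit_tail(DecayHistogram(bench, counts))
        r2 = fit_tail(DecayHistogram(bench, 7.0 * counts))
        assert r2.tau == pytest.approx(r1.tau, rel=1e-9)
        assert r2.amplitude == pytest.approx(7.0 * r1.amplitude, rel=1e-9)

    def test_too_few_positive_bins_rejected(self, camera):
        counts = np.zeros(camera.n_bins)
        counts[3] = 100
        counts[4] = 50
        counts[5] = 30
        d = DecayHistogram(camera, counts)
        with pytest.raises((ValueError, WindowError)):
            fit_tail(d, window=FitWindow(6, 10))

    def test_short_lifetime_tail_fit_biased_high_vs_reconvolution(self, bench):
        """With tau comparable to a wide (740 ps, two camera bins) IRF, the
        IRF-free tail fit overestimates the lifetime relative to the
        reconvolution fit on the same realizations."""
        tau = 0.80
        irf = simulate_irf(bench, fwhm=0.74, center=2.0)
        params = DecayModelParams(tau=tau, amplitude=1e5)
        tail_err, recon_err = [], []
        for seed in range(15):
            d = simulate_decay(params, irf, bench, seed=seed)
            tail_err.append(fit_tail(d).tau - tau)
            recon_err.append(fit_reconvolution(d, irf).tau - tau)
        assert np.median(tail_err) > abs(np.median(recon_err))

    def test_long_lifetime_estimators_agree(self, bench):
        """When tau >> IRF width both estimators agree within 1%."""
        irf = simulate_irf(bench, fwhm=0.25, center=1.0)
        params = DecayModelParams(tau=8.0, amplitude=2e5)
        taus_t, taus_r = [], []
        for seed in range(10):
            d = simulate_decay(params, irf, bench, seed=seed)
            taus_t.append(fit_tail(d).tau)
            taus_r.append(fit_reconvolution(d, irf).tau)
        assert np.median(taus_t) == pytest.approx(np.median(taus_r), rel=0.01)

    def test_reemission_cascade_lengthens_fitted_tail(self, bench):
        """A p = 0.3 cascade at tau = 2 ns fits to a longer lifetime than
        2 ns, bounded by the mixture mean tau/(1-p)."""
        dens = simulate_reemission_decay(2.0, ReemissionParams(0.3), bench)
        d = simulate_decay_from_kernel(dens, None, bench, amplitude=1e6, seed=2)
        r = fit_tail(d)
        assert 2.0 < r.tau <= 2.0 / (1 - 0.3) * 1.05
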