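"""Generator tests: IRFs, Poisson decays, re-emission cascades, layouts, series."""

import numpy as np
import pytest

from flimbench.core import DecayModelParams, TimeAxis, camera_axis
from flimbench.qc import cumulative_dose
from flimbench.synthetic import (
    PHANTOM_LIBRARY,
    PhantomLayout,
    PhantomSpec,
    ReemissionParams,
    dye_quantity_to_reemission,
    make_bar_target_layout,
    make_quadrant_layout,
    sample_reemission_arrivals,
    simulate_decay,
    simulate_flim_cube,
    simulate_irf,
    simulate_photostability_series,
    simulate_reemission_decay,
)

FOUR_SPECS = tuple(PHANTOM_LIBRARY[n] for n in ("purple", "yellow", "magenta", "orange"))


class TestSimulateIrf:
    def test_normalized_for_any_width(self, bench):
        for fwhm in [0.02, 0.25, 2.0]:
            irf = simulate_irf(bench, fwhm=fwhm, center=5.0)
            assert irf.weights.sum() == pytest.approx(1.0, rel=1e-12)

    def test_narrow_limit_concentrates_mass(self, bench):
        irf = simulate_irf(bench, fwhm=bench.bin_width, center=5.0)
        top3 = np.sort(irf.weights)[-3:].sum()
        assert top3 > 0.99

    def test_generated_fwhm_matches_request(self):
        """250 ps request on a ~12.2 ps grid: measured width within one bin."""
        axis = TimeAxis(bin_width=50.0 / 4096, n_bins=4096, period=50.0)
        irf = simulate_irf(axis, fwhm=0.25, center=5.0)
        half = irf.weights.max() / 2
        above = np.nonzero(irf.weights >= half)[0]
        measured = (above[-1] - above[0] + 1) * axis.bin_width
        assert abs(measured - 0.25) <= axis.bin_width

    def test_fwhm_out_of_range_rejected(self, bench):
        with pytest.raises(ValueError):
            simulate_irf(bench, fwhm=bench.period / 2, center=5.0)


class TestSimulateDecay:
    def test_zero_amplitude_zero_background_is_empty(self, bench, bench_irf):
        d = simulate_decay(
            DecayModelParams(tau=2.0, amplitude=0.0), bench_irf, bench, seed=0
        )
        assert d.total == 0

    def test_fixed_seed_is_bit_identical(self, bench, bench_irf):
        params = DecayModelParams(tau=2.43, amplitude=1e5)
        a = simulate_decay(params, bench_irf, bench, seed=42)
        b = simulate_decay(params, bench_irf, bench, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_total_counts_unbiased(self, bench, bench_irf):
        """Mean total over 200 seeded replicates within 3 SE of the 1e5
        amplitude (Poisson totals: SE = sqrt(A / n))."""
        params = DecayModelParams(tau=2.43, amplitude=1e5)
        totals = [
            simulate_decay(params, bench_irf, bench, seed=s).total for s in range(200)
        ]
        se = np.sqrt(1e5 / 200)
        assert abs(np.mean(totals) - 1e5) < 3 * se


class TestReemission:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            ReemissionParams(p=1.0)

    def test_no_reemission_reduces_to_monoexp(self, bench):
        from flimbench.core import monoexp_kernel

        dens = simulate_reemission_decay(2.0, ReemissionParams(0.0), bench)
        np.testing.assert_allclose(dens, monoexp_kernel(2.0, bench), rtol=1e-9)

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_mean_arrival_time_is_tau_over_one_minus_p(self, bench, p):
        """Closed-form mean of the geometric-Erlang cascade: tau/(1-p)."""
        tau = 2.0
        dens = simulate_reemission_decay(tau, ReemissionParams(p), bench)
        mean = (bench.centers * dens).sum()
        assert mean == pytest.approx(tau / (1 - p), rel=2e-3)

    def test_monte_carlo_sampler_agrees_with_density_mean(self, bench):
        tau, p, n = 2.0, 0.5, 40_000
        arrivals = sample_reemission_arrivals(tau, ReemissionParams(p), n, seed=9)
        expected = tau / (1 - p)
        se = arrivals.std() / np.sqrt(n)
        assert abs(arrivals.mean() - expected) < 4 * se

    def test_mean_strictly_increases_with_p(self, bench):
        means = [
            (bench.centers * simulate_reemission_decay(2.0, ReemissionParams(p), bench)).sum()
            for p in [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        ]
        assert np.all(np.diff(means) > 0)

    def test_dye_quantity_map_saturates(self):
        ps = [dye_quantity_to_reemission(m) for m in [0, 80, 160, 320, 640, 1e9]]
        assert ps[0] == 0
        assert np.all(np.diff(ps) > 0)
        assert ps[-1] <= 0.3


class TestLayouts:
    def test_quadrant_pixel_accounting(self):
        layout = make_quadrant_layout((4, 4), FOUR_SPECS)
        for spec in FOUR_SPECS:
            assert (layout.tau == spec.tau).sum() == 4

    def test_bar_target_binary_without_blur(self):
        layout = make_bar_target_layout((4, 32), bar_period_px=8, blur_sigma_px=0.0)
        assert set(np.unique(layout.intensity)) <= {
            0.0,
            PHANTOM_LIBRARY["orange"].relative_intensity,
        }

    def test_heavy_blur_kills_modulation(self):
        sharp = make_bar_target_layout((2, 64), 16, blur_sigma_px=0.0)
        blurred = make_bar_target_layout((2, 64), 16, blur_sigma_px=16.0)
        def depth(lay):
            row = lay.intensity[0]
            return row.max() - row.min()
        assert depth(blurred) < 0.05 * depth(sharp)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_bar_target_layout((4, 8), bar_period_px=1)
        with pytest.raises(ValueError):
            make_quadrant_layout((1, 4), FOUR_SPECS)


class TestSimulateFlimCube:
    def test_zero_photon_budget_gives_empty_cube(self, camera, camera_irf):
        layout = make_quadrant_layout((8, 8), FOUR_SPECS)
        cube = simulate_flim_cube(layout, camera, 0.0, camera_irf, seed=0)
        assert cube.counts.sum() == 0

    def test_defect_mask_accounting(self, camera, camera_irf):
        layout = make_quadrant_layout((10, 10), FOUR_SPECS)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:2, :5] = True  # 10% of pixels
        cube = simulate_flim_cube(layout, camera, 100, camera_irf, seed=0,
                                  defect_mask=mask)
        assert (~cube.valid_mask).sum() == 10
        assert cube.counts[mask].sum() == 0

    def test_seed_determinism(self, camera, camera_irf):
        layout = make_quadrant_layout((8, 8), FOUR_SPECS)
        a = simulate_flim_cube(layout, camera, 500, camera_irf, seed=5)
        b = simulate_flim_cube(layout, camera, 500, camera_irf, seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestPhotostabilitySeries:
    DOSES = np.array([cumulative_dose(1.35, h) for h in range(11)])

    def test_noise_free_series_is_exactly_flat(self):
        s = simulate_photostability_series(
            2.43, 2.48, self.DOSES, lifetime_noise=0.0, intensity_noise=0.0, seed=0
        )
        assert np.ptp(s.lifetimes) == 0
        assert np.ptp(s.intensity) == 0

    def test_bleach_half_life(self):
        d_half = self.DOSES[-1] / 2
        s = simulate_photostability_series(
            2.43, 1.0, self.DOSES, bleach_rate=np.log(2) / d_half,
            lifetime_noise=0.0, intensity_noise=0.0, seed=0,
        )
        i_half = np.argmin(np.abs(self.DOSES - d_half))
        assert s.intensity[i_half] == pytest.approx(0.5, rel=1e-6)

    def test_stable_dye_preset_change_is_small(self):
        """Under default noise, a drift-free series shows change% of the
        same order as a photostable material (<= ~8%), checked as a
        Monte-Carlo 90th percentile over 100 seeded series."""
        from flimbench.qc import photostability_metrics

        changes = []
        for seed in range(100):
            s = simulate_photostability_series(3.61, 2.29, self.DOSES, seed=seed)
            m = photostability_metrics(s)
            changes.append(m.loc[m.quantity == "lifetime_ns", "change_percent"].item())
        assert np.percentile(changes, 90) < 8.0

    def test_negative_or_unsorted_doses_rejected(self):
        with pytest.raises(ValueError):
            simulate_photostability_series(2.0, 1.0, np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_photostability_series(2.0, 1.0, np.array([1.0, 2.0, 3.0]))
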