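"""Generator contracts: IRF geometry, Poisson statistics, phantom truth."""

import numpy as np
import pytest

import fgflim as fg
from fgflim.core import ConvolvedDecayModel
from fgflim.synthetic_data import (fg_like_cross_section, phantom_labels,
                                   reference_like_cross_section,
                                   wavelength_grid)


class TestMakeIrf:
    def test_default_fwhm_within_one_bin(self, irf_default):
        measured = fg.measure_fwhm(irf_default.values, irf_default.bin_width)
        assert abs(measured - 100.0) <= irf_default.bin_width

    def test_fine_grid_fwhm_matches_gaussian_closed_form(self):
        # 1 ps bins: interpolated FWHM must hit the requested width sharply
        irf = fg.make_irf(fwhm=100.0, bin_width=1.0, n_bins=4096,
                          center=2000.0)
        measured = fg.measure_fwhm(irf.values, 1.0)
        assert abs(measured - 100.0) <= 0.5

    def test_unit_area_even_when_nearly_uniform(self):
        irf = fg.make_irf(fwhm=48.828125 * 1000, bin_width=48.828125,
                          n_bins=256, center=6250.0)
        assert abs(irf.values.sum() - 1.0) < 1e-9
        assert irf.values.std() / irf.values.mean() < 0.5

    def test_unresolvable_fwhm_is_an_error(self):
        with pytest.raises(ValueError, match="not resolvable"):
            fg.make_irf(fwhm=10.0, bin_width=48.828125, n_bins=256,
                        center=1250.0)

    def test_center_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fg.make_irf(fwhm=100.0, bin_width=10.0, n_bins=64, center=1e6)


class TestSimulateDecay:
    def test_seed_fixes_output_bit_for_bit(self, fg_params, irf_default, acq):
        h1 = fg.simulate_decay(fg_params, irf_default, acq(seed=13))
        h2 = fg.simulate_decay(fg_params, irf_default, acq(seed=13))
        h3 = fg.simulate_decay(fg_params, irf_default, acq(seed=14))
        assert np.array_equal(h1.counts, h2.counts)
        assert not np.array_equal(h1.counts, h3.counts)

    def test_zero_photons_gives_empty_histogram(self, fg_params, irf_default,
                                                acq):
        h = fg.simulate_decay(fg_params, irf_default, acq(total_photons=0))
        assert h.total == 0

    def test_expected_counts_conserve_photons(self, irf_default):
        params = fg.DecayModelParams.biexp(0.6, 0.3, 2.0, baseline=7.0)
        model = ConvolvedDecayModel(irf_default)
        expected = model.expected(params, 1e6)
        target = 1e6 + 256 * 7.0
        assert abs(expected.sum() - target) <= 1e-6 * target

    def test_mean_arrival_time_matches_wrapped_exponential(self, irf_delta,
                                                           acq):
        # closed form for a delta response at c with period T:
        #   E[t] = c + tau - T q/(1-q) - T * P(wrap past T-c)
        tau_ps, period = 2300.0, 12500.0
        params = fg.DecayModelParams.mono(2.3)
        h = fg.simulate_decay(params, irf_delta, acq(seed=7))
        q = np.exp(-period / tau_ps)
        c = irf_delta.center
        p_wrap = (np.exp(-(period - c) / tau_ps) - q) / (1.0 - q)
        oracle = c + tau_ps - period * q / (1.0 - q) - period * p_wrap
        empirical = float(h.time_axis @ h.counts / h.total)
        assert abs(empirical - oracle) < 30.0  # ps; MC error ~2 ps

    def test_poisson_variance_matches_mean(self, irf_default):
        # per-bin variance ~= per-bin mean across 1000 seeded repeats
        params = fg.DecayModelParams.mono(2.0)
        reps = np.stack([
            fg.simulate_decay(params, irf_default,
                              fg.AcquisitionSettings(256, 12.5, 20_000, s)
                              ).counts
            for s in range(1000)])
        hot = np.argsort(reps.mean(axis=0))[-10:]   # 10-bin toy
        mean = reps[:, hot].mean(axis=0)
        var = reps[:, hot].var(axis=0, ddof=1)
        # s^2 ~ Normal(lam, 2 lam^2 / n) at these counts
        tol = 3.0 * mean * np.sqrt(2.0 / 999)
        assert np.all(np.abs(var - mean) < tol)

    def test_mismatched_irf_length_is_an_error(self, fg_params, acq):
        short_irf = fg.make_irf(100.0, 48.828125, 128, center=1250.0)
        with pytest.raises(ValueError, match="bins"):
            fg.simulate_decay(fg_params, short_irf, acq())


class TestPhantoms:
    def test_empty_phantom_is_all_background(self, irf_default, acq,
                                             bg_params):
        phantom = fg.ScenePhantom(shape=(1, 8, 8), background_decay=bg_params,
                                  photons_per_pixel=2000)
        ds, truth = fg.simulate_flim_image(phantom, irf_default, acq(seed=3))
        assert truth.n_cells == 0
        assert np.all(truth.labels == 0)
        assert np.allclose(truth.mean_lifetime, 1.35)
        assert ds.data.shape == (1, 8, 8, 256)

    def test_disjoint_spheres_give_exactly_that_many_components(self):
        from scipy import ndimage as ndi
        cells = tuple(
            fg.CellSpec(center=(10, 6 + 11 * (i // 5), 6 + 11 * (i % 5)),
                        radii=(3.0, 3.0, 3.0), decay=fg.fg_decay_params())
            for i in range(20))
        phantom = fg.ScenePhantom(shape=(20, 50, 60), cells=cells,
                                  photons_per_pixel=100)
        labels, overlap = phantom_labels(phantom)
        assert not overlap
        n_components = ndi.label(labels > 0, np.ones((3, 3, 3)))[1]
        assert n_components == 20
        assert len(np.unique(labels)) == 21

    def test_overlapping_cells_are_flagged(self, irf_default, acq):
        decay = fg.fg_decay_params()
        cells = (fg.CellSpec((0, 8.0, 8.0), (1.0, 4.0, 4.0), decay),
                 fg.CellSpec((0, 8.0, 11.0), (1.0, 4.0, 4.0), decay))
        phantom = fg.ScenePhantom(shape=(1, 16, 16), cells=cells,
                                  photons_per_pixel=500)
        ds, truth = fg.simulate_flim_image(phantom, irf_default, acq(seed=1))
        assert truth.has_overlap
        assert ds.metadata["has_overlap"]

    def test_cell_center_outside_volume_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fg.ScenePhantom(shape=(1, 8, 8),
                            cells=(fg.CellSpec((0, 20.0, 2.0), (1, 2, 2),
                                               fg.fg_decay_params()),))


class TestSpectralSimulation:
    def test_noiseless_ratio_equals_cross_section_ratio(self):
        wl = wavelength_grid()
        s_truth = fg_like_cross_section(wl)
        r_truth = reference_like_cross_section(wl)
        fs, fr = fg.simulate_spectral_series(s_truth, r_truth, 2.0, 0.5,
                                             noise_cv=0.0, seed=0)
        expect = (s_truth.sigma * 2.0) / (r_truth.sigma * 0.5)
        assert np.allclose(fs.intensity / fr.intensity, expect)

    def test_doubling_power_quadruples_signal(self):
        wl = wavelength_grid()
        s_truth = fg_like_cross_section(wl)
        r_truth = reference_like_cross_section(wl)
        power = np.ones_like(wl)
        power2 = power.copy()
        power2[3] = 2.0
        f1, _ = fg.simulate_spectral_series(s_truth, r_truth, 1, 1,
                                            laser_power=power, seed=0)
        f2, _ = fg.simulate_spectral_series(s_truth, r_truth, 1, 1,
                                            laser_power=power2, seed=0)
        ratio = f2.intensity / f1.intensity
        assert ratio[3] == pytest.approx(4.0)
        assert np.allclose(np.delete(ratio, 3), 1.0)

    def test_grid_mismatch_is_an_error(self):
        s_truth = fg_like_cross_section(np.array([720.0, 730.0, 740.0]))
        r_truth = reference_like_cross_section(np.array([720.0, 731.0,
                                                         740.0]))
        with pytest.raises(ValueError, match="grid"):
            fg.simulate_spectral_series(s_truth, r_truth, 1, 1)


class TestPowerSeries:
    @pytest.mark.parametrize("exponent", [2.0, 1.0])
    def test_noiseless_loglog_slope_is_exact(self, exponent):
        df = fg.simulate_power_series(1.0, 1.0, np.geomspace(1, 30, 8),
                                      exponent=exponent)
        slope = np.polyfit(np.log(df["power_mW"]), np.log(df["intensity"]),
                           1)[0]
        assert slope == pytest.approx(exponent, abs=1e-12)

    def test_noisy_slope_close_to_two(self):
        df = fg.simulate_power_series(1.0, 1.0, np.geomspace(1, 20, 10),
                                      exponent=2.0, noise_cv=0.01, seed=4)
        res = fg.power_exponent(df["power_mW"].to_numpy(),
                                df["intensity"].to_numpy())
        assert res.slope == pytest.approx(2.0, abs=0.05)
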