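"""Decay model and fitter checks, including brute-force oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fgflim as fg
from fgflim.core import ConvolvedDecayModel, DecayHistogram
from fgflim.decay_fit import FitOptions, amplitudes_for_intensity_mean

BW = 12500.0 / 256.0


def _noiseless_hist(params, irf, photons=1e6):
    expected = ConvolvedDecayModel(irf).expected(params, photons)
    return DecayHistogram(expected, irf.bin_width)


class TestModelDecay:
    def test_delta_irf_mono_equals_sampled_exponential(self, irf_delta):
        params = fg.DecayModelParams.mono(2.0)
        out = fg.model_decay(params, irf_delta, n_photons=1.0)
        # reconstruct analytically: wrapped exponential rolled to the delta
        t = (np.arange(256) + 0.5) * BW
        period = 256 * BW
        d = np.exp(-t / 2000.0) / (1 - np.exp(-period / 2000.0))
        d /= d.sum()
        shift_bins = int(round(irf_delta.center / BW - 0.5))
        assert np.allclose(out, np.roll(d, shift_bins), atol=1e-12)

    def test_one_bin_shift_rolls_the_curve(self, irf_delta):
        params = fg.DecayModelParams.mono(1.5)
        base = fg.model_decay(params, irf_delta, n_photons=1e5)
        shifted = fg.model_decay(params, irf_delta, shift_ps=BW,
                                 n_photons=1e5)
        assert np.allclose(shifted, np.roll(base, 1), atol=1e-6 * base.max())

    def test_two_component_model_conserves_photons(self, irf_default):
        params = fg.DecayModelParams.biexp(0.8, 0.1, 2.3, baseline=3.0)
        out = fg.model_decay(params, irf_default, n_photons=1e6)
        target = 1e6 + 256 * 3.0
        assert abs(out.sum() - target) <= 1e-9 * target

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fg.DecayModelParams.mono(-1.0)


class TestMonoexponentialFit:
    def test_noiseless_background_recovered_exactly(self, irf_delta):
        hist = _noiseless_hist(fg.DecayModelParams.mono(1.35), irf_delta)
        r = fg.fit_monoexponential(hist, irf_delta)
        assert r.converged
        assert r.params.lifetimes_ns[0] == pytest.approx(1.35, rel=1e-6)

    def test_flat_histogram_is_flagged(self, irf_default):
        hist = DecayHistogram(np.full(256, 5000), BW)
        r = fg.fit_monoexponential(hist, irf_default)
        assert not r.converged
        assert r.metadata.get("tau_at_bound") or r.metadata.get(
            "amplitude_collapsed")

    def test_low_count_histogram_rejected(self, irf_default):
        hist = DecayHistogram(np.full(256, 1), BW)
        with pytest.raises(ValueError, match="below the minimum"):
            fg.fit_monoexponential(hist, irf_default)

    def test_estimator_unbiased_over_poisson_replicates(self, irf_default,
                                                        acq):
        # mean fitted lifetime within 0.5% of truth at 1e6 photons
        truth = fg.DecayModelParams.mono(1.35)
        taus = []
        for seed in range(100):
            h = fg.simulate_decay(truth, irf_default, acq(seed=seed))
            r = fg.fit_monoexponential(h, irf_default)
            assert r.converged
            taus.append(r.params.lifetimes_ns[0])
        assert np.mean(taus) == pytest.approx(1.35, rel=0.005)


class TestBiexponentialFit:
    def test_noiseless_exact_recovery(self, irf_delta):
        truth = fg.DecayModelParams.biexp(0.7, 0.4, 2.3)
        hist = _noiseless_hist(truth, irf_delta)
        r = fg.fit_biexponential(hist, irf_delta)
        assert r.converged
        assert r.params.lifetimes_ns == pytest.approx(truth.lifetimes_ns,
                                                      rel=1e-6)
        assert r.params.amplitudes == pytest.approx(truth.amplitudes,
                                                    rel=1e-5)

    def test_canonical_ordering_enforced(self, irf_default, fg_params, acq):
        h = fg.simulate_decay(fg_params, irf_default, acq(seed=5))
        r = fg.fit_biexponential(h, irf_default)
        t1, t2 = r.params.lifetimes_ns
        assert t1 <= t2

    def test_grid_search_oracle_agreement(self):
        # coarse-to-fine exhaustive search on a 64-bin noiseless toy must
        # land on the same optimum as the optimizer, within grid resolution
        bw = 12500.0 / 64.0
        irf = fg.delta_irf(bw, 64, center=bw)
        truth = fg.DecayModelParams.biexp(0.75, 0.45, 2.25)
        expected = ConvolvedDecayModel(irf).expected(truth, 1e6)
        hist = DecayHistogram(expected, bw)

        model = ConvolvedDecayModel(irf)
        tau1_grid = np.arange(0.25, 0.70, 0.05)
        tau2_grid = np.arange(1.75, 2.80, 0.05)
        a1_grid = np.arange(0.55, 0.96, 0.05)
        best, best_sse = None, np.inf
        for t1 in tau1_grid:
            for t2 in tau2_grid:
                for a1 in a1_grid:
                    cand = model.expected(
                        fg.DecayModelParams.biexp(a1, t1, t2), 1e6)
                    sse = float(((expected - cand) ** 2
                                 / np.maximum(cand, 1.0)).sum())
                    if sse < best_sse:
                        best, best_sse = (t1, t2, a1), sse

        r = fg.fit_biexponential(hist, irf, FitOptions(fit_shift=False))
        assert abs(r.params.lifetimes_ns[0] - best[0]) <= 0.05
        assert abs(r.params.lifetimes_ns[1] - best[1]) <= 0.05
        assert abs(r.params.amplitudes[0] - best[2]) <= 0.05

    def test_identifiability_collapse_to_mono(self, irf_default, acq):
        # equal lifetimes cannot support two components
        truth = fg.DecayModelParams.mono(1.8)
        h = fg.simulate_decay(truth, irf_default, acq(seed=21))
        r = fg.fit_biexponential(
            h, irf_default, FitOptions(identifiability_rtol=0.05))
        if r.metadata.get("collapsed_from_biexp"):
            assert r.params.n_components == 1
            assert r.params.lifetimes_ns[0] == pytest.approx(1.8, rel=0.02)
        else:
            # fit kept two components: the intensity mean must still match
            assert fg.mean_lifetime(r.params) == pytest.approx(1.8, rel=0.02)

    def test_short_component_recovery_improves_with_narrower_irf(self, acq):
        # recovery error of the sub-IRF component shrinks monotonically as
        # the instrument response narrows from 200 ps to 10 ps
        truth = fg.fg_decay_params()
        bw = 12500.0 / 1024.0
        errors = []
        for fwhm in (200.0, 50.0, 10.0):
            irf = fg.make_irf(fwhm, bw, 1024, center=1250.0)
            errs = []
            for seed in range(8):
                h = fg.simulate_decay(truth, irf,
                                      acq(seed=seed, n_bins=1024))
                r = fg.fit_biexponential(h, irf)
                errs.append(abs(r.params.lifetimes_ns[0]
                                - truth.lifetimes_ns[0]))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]


class TestMeanLifetime:
    def test_single_component_in_both_modes(self):
        p = fg.DecayModelParams.mono(1.2)
        assert fg.mean_lifetime(p, "amplitude") == pytest.approx(1.2)
        assert fg.mean_lifetime(p, "intensity") == pytest.approx(1.2)

    def test_equal_amplitudes_arithmetic(self):
        p = fg.DecayModelParams.biexp(0.5, 1.0, 3.0)
        assert fg.mean_lifetime(p, "amplitude") == pytest.approx(2.0)
        assert fg.mean_lifetime(p, "intensity") == pytest.approx(2.5)

    def test_fg_amplitude_split_solves_weighted_mean(self):
        # brute-force scan oracle for the amplitude split producing a
        # 1.4 ns intensity-weighted mean with 0.1/2.3 ns components
        a1_scan = np.linspace(1e-4, 1 - 1e-4, 200_001)
        means = ((a1_scan * 0.1 ** 2 + (1 - a1_scan) * 2.3 ** 2)
                 / (a1_scan * 0.1 + (1 - a1_scan) * 2.3))
        oracle_a1 = a1_scan[np.argmin(np.abs(means - 1.4))]
        a1, a2 = amplitudes_for_intensity_mean(0.1, 2.3, 1.4)
        assert a1 == pytest.approx(oracle_a1, abs=1e-4)
        assert a1 == pytest.approx(0.941, abs=0.001)
        assert a2 == pytest.approx(0.059, abs=0.001)
        p = fg.DecayModelParams((a1, a2), (0.1, 2.3))
        assert fg.mean_lifetime(p, "intensity") == pytest.approx(1.4,
                                                                 abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(a1=st.floats(0.01, 0.99),
           tau1=st.floats(0.01, 5.0),
           ratio=st.floats(1.01, 50.0))
    def test_mean_bounded_by_component_lifetimes(self, a1, tau1, ratio):
        p = fg.DecayModelParams.biexp(a1, tau1, tau1 * ratio)
        lo, hi = p.lifetimes_ns
        for mode in ("amplitude", "intensity"):
            m = fg.mean_lifetime(p, mode)
            assert lo - 1e-12 <= m <= hi + 1e-12


class TestReducedChiSquared:
    def test_perfect_agreement_is_zero(self):
        x = np.arange(1.0, 100.0)
        assert fg.reduced_chi_squared(x, x, 10) == 0.0

    def test_calibrated_near_one_for_correct_model(self, irf_default,
                                                   fg_params, acq):
        model = ConvolvedDecayModel(irf_default)
        expected = model.expected(fg_params, 1e6)
        n_used = int((expected >= 1.0).sum())
        values = []
        for seed in range(200):
            h = fg.simulate_decay(fg_params, irf_default, acq(seed=seed))
            values.append(fg.reduced_chi_squared(h.counts, expected, n_used))
        assert 0.9 <= np.mean(values) <= 1.1

    def test_misspecified_mono_fit_fails_loudly(self, irf_default, fg_params,
                                                acq):
        h = fg.simulate_decay(fg_params, irf_default, acq(seed=9))
        r = fg.fit_monoexponential(h, irf_default)
        assert r.chi2_reduced > 10.0
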