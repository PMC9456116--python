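"""Havriliak–Negami evaluation and spectral fitting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supercool import (DielectricSpectrum, HNParams, build_relaxation_map,
                       fit_hn_spectrum, gen_hn_spectrum, hn_loss,
                       hn_peak_frequency)
from supercool.constants import EPS0
from supercool.exceptions import DataValidationError, InitializationError

PARAM_NAMES = ("sigma0", "eps_inf", "delta_eps", "tau_alpha", "xi", "delta")


def numeric_peak_frequency(params, n=200_001):
    """Independent oracle: argmax of the loss on a dense log grid around 1/(2 pi tau)."""
    f0 = 1.0 / (2.0 * np.pi * params.tau_alpha)
    f = np.logspace(np.log10(f0) - 3, np.log10(f0) + 3, n)
    clean = dataclasses.replace(params, sigma0=0.0)
    _, loss = hn_loss(f, clean)
    return f[np.argmax(loss)]


class TestHNLoss:
    def test_debye_limit_peak_value(self):
        """At xi = delta = 1 the loss peaks at delta_eps/2 where 2 pi f tau = 1."""
        p = HNParams(sigma0=0.0, eps_inf=2.0, delta_eps=1.0,
                     tau_alpha=1.0 / (2.0 * np.pi), xi=1.0, delta=1.0)
        real, imag = hn_loss(1.0, p)
        assert imag == pytest.approx(0.5, rel=1e-12)
        assert real == pytest.approx(2.5, rel=1e-12)

    def test_debye_reduces_to_analytic_form(self):
        f = np.logspace(-1, 4, 60)
        p = HNParams(sigma0=0.0, eps_inf=2.0, delta_eps=3.0, tau_alpha=1e-2,
                     xi=1.0, delta=1.0)
        real, imag = hn_loss(f, p)
        wt = 2.0 * np.pi * f * p.tau_alpha
        np.testing.assert_allclose(imag, p.delta_eps * wt / (1.0 + wt**2), rtol=1e-12)
        np.testing.assert_allclose(real, p.eps_inf + p.delta_eps / (1.0 + wt**2),
                                   rtol=1e-12)

    def test_no_relaxation_strength_gives_flat_spectrum(self):
        p = HNParams(sigma0=0.0, eps_inf=4.0, delta_eps=1e-30, tau_alpha=1.0,
                     xi=0.9, delta=0.9)
        real, imag = hn_loss(np.logspace(-2, 6, 50), p)
        np.testing.assert_allclose(real, 4.0, atol=1e-28)
        np.testing.assert_allclose(imag, 0.0, atol=1e-28)

    def test_conductivity_dominated_low_frequency_slope(self):
        """At very low f the loss approaches sigma0/(2 pi f eps0): slope -1 in log-log."""
        p = HNParams(sigma0=1e-8, eps_inf=3.0, delta_eps=3.0, tau_alpha=1e-3,
                     xi=0.85, delta=0.6)
        f = np.array([1e-4, 1e-3])
        _, imag = hn_loss(f, p)
        np.testing.assert_allclose(imag, p.sigma0 / (2.0 * np.pi * f * EPS0),
                                   rtol=1e-3)
        slope = np.diff(np.log10(imag)) / np.diff(np.log10(f))
        assert slope[0] == pytest.approx(-1.0, abs=1e-3)

    def test_peak_frequency_closed_form_matches_numeric_argmax(self, hn_truth):
        f_closed = hn_peak_frequency(hn_truth)
        f_numeric = numeric_peak_frequency(hn_truth)
        assert f_closed == pytest.approx(f_numeric, rel=1e-4)

    def test_rejects_nonpositive_frequency(self, hn_truth):
        with pytest.raises(DataValidationError):
            hn_loss(np.array([0.0, 1.0]), hn_truth)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(xi=st.floats(0.3, 1.0), delta=st.floats(0.3, 1.0),
           log_tau=st.floats(-6.0, 0.0))
    def test_loss_single_peaked_without_conductivity(self, xi, delta, log_tau):
        """eps'' of one HN process has exactly one local maximum over f."""
        p = HNParams(sigma0=0.0, eps_inf=2.0, delta_eps=2.0,
                     tau_alpha=10.0**log_tau, xi=xi, delta=delta)
        f0 = 1.0 / (2.0 * np.pi * p.tau_alpha)
        f = np.logspace(np.log10(f0) - 4, np.log10(f0) + 4, 2000)
        _, loss = hn_loss(f, p)
        assert np.all(loss > 0)
        sign_changes = np.diff(np.sign(np.diff(loss)))
        assert np.count_nonzero(sign_changes < 0) == 1

    def test_eps_real_monotone_nonincreasing_without_conductivity(self, hn_truth):
        p = dataclasses.replace(hn_truth, sigma0=0.0)
        real, _ = hn_loss(np.logspace(-4, 8, 4000), p)
        assert np.all(np.diff(real) <= 1e-12)


class TestHNParamsInvariants:
    @pytest.mark.parametrize("kwargs", [
        {"sigma0": -1e-12}, {"eps_inf": 0.5}, {"delta_eps": 0.0},
        {"tau_alpha": -1.0}, {"xi": 1.2}, {"xi": 0.0},
        {"xi": 0.9, "delta": 1.5},  # xi*delta > 1
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(sigma0=0.0, eps_inf=2.0, delta_eps=1.0, tau_alpha=1e-3,
                    xi=0.8, delta=0.8)
        base.update(kwargs)
        with pytest.raises(DataValidationError):
            HNParams(**base)


class TestFitHNSpectrum:
    def test_noiseless_round_trip_recovers_all_six_parameters(
            self, hn_truth, noiseless_spectrum):
        res = fit_hn_spectrum(noiseless_spectrum)
        assert res.converged
        for name in PARAM_NAMES:
            truth = getattr(hn_truth, name)
            est = getattr(res.params, name)
            assert est == pytest.approx(truth, rel=1e-6), name

    def test_covariance_symmetric_psd(self, noiseless_spectrum):
        cov = fit_hn_spectrum(noiseless_spectrum).covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-20)
        assert np.min(np.linalg.eigvalsh(cov)) >= -1e-18

    def test_noisy_recovery_median_log_tau_error(self, hn_truth, freq_grid):
        """1% relative loss noise: median |d log10 tau| < 0.02 over 50 seeds."""
        errors = []
        for seed in range(50):
            sp = gen_hn_spectrum(hn_truth, freq_grid, 0.01, seed)
            res = fit_hn_spectrum(sp)
            errors.append(abs(np.log10(res.params.tau_alpha)
                              - np.log10(hn_truth.tau_alpha)))
        assert np.median(errors) < 0.02

    def test_conductivity_orthogonal_to_tau(self, hn_truth, freq_grid):
        """Two spectra differing only in sigma0 give the same tau_alpha."""
        sp_a = gen_hn_spectrum(dataclasses.replace(hn_truth, sigma0=0.0),
                               freq_grid, 0.0, 0)
        sp_b = gen_hn_spectrum(dataclasses.replace(hn_truth, sigma0=1e-9),
                               freq_grid, 0.0, 0)
        tau_a = fit_hn_spectrum(sp_a).params.tau_alpha
        tau_b = fit_hn_spectrum(sp_b).params.tau_alpha
        assert tau_a == pytest.approx(tau_b, rel=1e-6)

    def test_loss_rescaling_only_rescales_strengths(self, hn_truth, freq_grid):
        """Scaling eps'' by c scales delta_eps and sigma0 by c; tau, xi, delta fixed."""
        sp = gen_hn_spectrum(hn_truth, freq_grid, 0.0, 0)
        scaled = DielectricSpectrum(sp.temperature, sp.frequencies,
                                    5.0 * sp.eps_imag)
        base = fit_hn_spectrum(DielectricSpectrum(sp.temperature, sp.frequencies,
                                                  sp.eps_imag))
        res = fit_hn_spectrum(scaled)
        assert res.params.tau_alpha == pytest.approx(base.params.tau_alpha, rel=1e-8)
        assert res.params.xi == pytest.approx(base.params.xi, rel=1e-8)
        assert res.params.delta == pytest.approx(base.params.delta, rel=1e-8)
        assert res.params.delta_eps == pytest.approx(5.0 * base.params.delta_eps,
                                                     rel=1e-6)
        assert res.params.sigma0 == pytest.approx(5.0 * base.params.sigma0, rel=1e-4)

    def test_peak_window_fit_consistent_with_full_fit(self, hn_truth, freq_grid):
        """On single-process data (no dc tail) a peak-only window gives the
        same tau_alpha as the full spectrum."""
        clean = dataclasses.replace(hn_truth, sigma0=0.0)
        sp = gen_hn_spectrum(clean, freq_grid, 0.0, 0)
        full = fit_hn_spectrum(sp)
        f_peak = hn_peak_frequency(clean)
        windowed = fit_hn_spectrum(sp, fit_window=(f_peak / 100, f_peak * 100))
        assert windowed.params.tau_alpha == pytest.approx(full.params.tau_alpha,
                                                          rel=1e-6)

    def test_unfittable_flat_spectrum_raises(self):
        f = np.logspace(0, 4, 40)
        sp = DielectricSpectrum(300.0, f, np.full_like(f, 1e-3))
        with pytest.raises(InitializationError):
            fit_hn_spectrum(sp)

    def test_too_few_points_rejected(self, hn_truth):
        f = np.logspace(0, 2, 5)
        sp = gen_hn_spectrum(hn_truth, f, 0.0, 0)
        with pytest.raises(DataValidationError):
            fit_hn_spectrum(sp)


class TestBuildRelaxationMap:
    def test_composition_round_trip_and_filtering(self, hn_truth, freq_grid):
        fits = []
        taus = [1e-1, 1e-3, 1e-5]
        for temperature, tau in zip([338.0, 358.0, 378.0], taus):
            sp = gen_hn_spectrum(dataclasses.replace(hn_truth, tau_alpha=tau),
                                 freq_grid, 0.0, 0)
            fits.append((temperature, fit_hn_spectrum(sp)))
        rmap = build_relaxation_map(fits)
        assert len(rmap) == 3
        np.testing.assert_allclose(rmap.tau_alpha, taus[::1], rtol=1e-6)
        assert np.all(np.diff(rmap.temperatures) > 0)

        # single converged entry -> single-row map
        assert len(build_relaxation_map(fits[:1])) == 1

        # a non-converged entry is dropped with a warning
        bad = dataclasses.replace(fits[0][1], converged=False)
        with pytest.warns(UserWarning, match="non-converged"):
            rmap2 = build_relaxation_map([fits[1], (fits[0][0], bad)])
        assert len(rmap2) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(DataValidationError):
            build_relaxation_map([])
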