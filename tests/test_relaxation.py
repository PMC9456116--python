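"""VFT parametrization, dielectric Tg, fragility, and windowed Arrhenius energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from supercool import (RelaxationMap, VFTParams, apparent_activation_energy,
                       classify_fragility, fit_vft, gen_relaxation_series,
                       isobaric_fragility, tg_at_timescale, vft_tau)
from supercool.constants import LOG10E, R_GAS
from supercool.exceptions import DataValidationError, FitConvergenceError
from supercool.reference import VFT_PARAMS

TEMPS = np.linspace(330.0, 380.0, 12)


def tg_oracle(vft, tau_ref=100.0):
    """Independent root-solve of log10 tau(T) = log10 tau_ref."""
    def f(T):
        return (vft.log10_tau0 + vft.A / (np.log(10.0) * (T - vft.T_VFT))
                - np.log10(tau_ref))
    return brentq(f, vft.T_VFT + 1e-6, 2000.0, xtol=1e-12)


class TestGenerator:
    def test_constant_when_A_is_zero(self):
        vft = VFTParams(log10_tau0=-3.0, A=0.0, T_VFT=200.0)
        rmap = gen_relaxation_series(vft, TEMPS)
        np.testing.assert_allclose(rmap.tau_alpha, 1e-3, rtol=1e-15)

    def test_etb_reaches_100s_at_dielectric_tg(self):
        """The pure-drug VFT curve passes tau_alpha = 100 s at ~328.06 K."""
        vft = VFT_PARAMS["pure ETB"]
        tau = vft_tau(328.06, vft)
        assert tau == pytest.approx(100.0, rel=0.01)

    def test_acmal_direct_evaluation(self):
        """log10 tau at 338 K equals the closed-form value for pure acMAL."""
        vft = VFT_PARAMS["pure acMAL"]
        expected = -12.3 + 1400.0 / (np.log(10.0) * (338.0 - 285.0))
        assert np.log10(vft_tau(338.0, vft)) == pytest.approx(expected, rel=1e-12)

    def test_rejects_temperature_at_or_below_vogel(self):
        vft = VFT_PARAMS["pure ETB"]
        with pytest.raises(DataValidationError):
            gen_relaxation_series(vft, [260.0, 340.0])


class TestFitVFT:
    @pytest.mark.parametrize("material", sorted(VFT_PARAMS))
    def test_noiseless_round_trip_per_material(self, material):
        truth = VFT_PARAMS[material]
        rmap = gen_relaxation_series(truth, TEMPS)
        fit = fit_vft(rmap)
        assert fit.log10_tau0 == pytest.approx(truth.log10_tau0, rel=1e-6)
        assert fit.A == pytest.approx(truth.A, rel=1e-6)
        assert fit.T_VFT == pytest.approx(truth.T_VFT, rel=1e-6)

    def test_arrhenius_limit_fits_with_vanishing_vogel_temperature(self):
        truth = VFTParams(log10_tau0=-14.0, A=20000.0, T_VFT=0.0)
        rmap = gen_relaxation_series(truth, TEMPS)
        fit = fit_vft(rmap)
        assert fit.T_VFT == pytest.approx(0.0, abs=1e-3)
        assert fit.A == pytest.approx(truth.A, rel=1e-4)

    def test_refuses_vogel_temperature_near_data(self):
        # steep divergence right below the coldest point
        truth = VFTParams(log10_tau0=-10.0, A=50.0, T_VFT=329.5)
        tau = truth.tau0 * np.exp(truth.A / (TEMPS - truth.T_VFT))
        with pytest.raises((FitConvergenceError, DataValidationError)):
            fit_vft(RelaxationMap(TEMPS, tau))

    def test_requires_enough_points_and_spread(self, etb_vft):
        small = gen_relaxation_series(etb_vft, TEMPS[:3])
        with pytest.raises(DataValidationError):
            fit_vft(small)
        narrow = gen_relaxation_series(etb_vft, np.linspace(370, 372, 8))
        with pytest.raises(DataValidationError):
            fit_vft(narrow)

    def test_noisy_parameter_recovery_within_two_standard_errors(self, etb_vft):
        """0.05-decade log noise, 15 points: each parameter lands inside its
        reported 2-SE interval in >= 90% of 200 seeds."""
        temps = np.linspace(335.0, 380.0, 15)
        clean = np.log10(vft_tau(temps, etb_vft))
        truth = np.array([etb_vft.log10_tau0, etb_vft.A, etb_vft.T_VFT])
        covered = np.zeros(3)
        n_fits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            tau = 10.0 ** (clean + 0.05 * rng.standard_normal(len(temps)))
            try:
                fit = fit_vft(RelaxationMap(temps, tau))
            except FitConvergenceError:
                continue
            est = np.array([fit.log10_tau0, fit.A, fit.T_VFT])
            se = np.sqrt(np.diag(fit.covariance))
            covered += np.abs(est - truth) <= 2.0 * se
            n_fits += 1
        assert n_fits >= 190  # the fit itself almost always succeeds
        assert np.all(covered / 200 >= 0.90)


class TestTgAndFragility:
    def test_tg_matches_root_solve_oracle(self):
        for material in ("pure ETB", "pure acMAL"):
            vft = VFT_PARAMS[material]
            tg, _ = tg_at_timescale(vft)
            assert tg == pytest.approx(tg_oracle(vft), rel=1e-10)

    def test_etb_and_acmal_tg_values(self):
        tg_etb, _ = tg_at_timescale(VFT_PARAMS["pure ETB"])
        tg_acmal, _ = tg_at_timescale(VFT_PARAMS["pure acMAL"])
        assert tg_etb == pytest.approx(328.1, abs=0.1)
        assert tg_acmal == pytest.approx(327.5, abs=0.1)

    def test_tg_errors(self):
        with pytest.raises(DataValidationError):
            tg_at_timescale(VFTParams(log10_tau0=-5.0, A=0.0, T_VFT=200.0))
        with pytest.raises(DataValidationError):
            # tau_ref below tau0: no solution
            tg_at_timescale(VFTParams(log10_tau0=3.0, A=1000.0, T_VFT=200.0),
                            tau_ref=100.0)

    def test_fragility_values_and_classes(self):
        tg_etb, _ = tg_at_timescale(VFT_PARAMS["pure ETB"])
        m_etb = isobaric_fragility(VFT_PARAMS["pure ETB"], tg_etb)
        assert m_etb == pytest.approx(98.0, abs=1.0)
        assert classify_fragility(m_etb) == "moderately fragile"

        tg_ac, _ = tg_at_timescale(VFT_PARAMS["pure acMAL"])
        m_ac = isobaric_fragility(VFT_PARAMS["pure acMAL"], tg_ac)
        assert m_ac == pytest.approx(110.0, abs=1.0)
        assert classify_fragility(m_ac) == "fragile"

    def test_class_boundaries_closed_as_printed(self):
        assert classify_fragility(30.0) == "strong"
        assert classify_fragility(30.0001) == "moderately fragile"
        assert classify_fragility(99.9999) == "moderately fragile"
        assert classify_fragility(100.0) == "fragile"

    def test_arrhenius_limit_minimal_fragility_identity(self):
        """At T_VFT = 0, m_p = A/(ln10 Tg) = log10(tau(Tg)/tau0)."""
        vft = VFTParams(log10_tau0=-14.0, A=12000.0, T_VFT=0.0)
        tg, _ = tg_at_timescale(vft)
        m = isobaric_fragility(vft, tg)
        assert m == pytest.approx(vft.A / (np.log(10.0) * tg), rel=1e-12)
        assert m == pytest.approx(2.0 - vft.log10_tau0, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(log10_tau0=st.floats(-20.0, -10.0), A=st.floats(500.0, 5000.0),
           t_vft=st.floats(150.0, 280.0))
    def test_fragility_closed_form_equals_numeric_derivative(self, log10_tau0, A,
                                                             t_vft):
        """m_p = d log10 tau / d(Tg/T) at Tg, checked against a centered difference."""
        vft = VFTParams(log10_tau0=log10_tau0, A=A, T_VFT=t_vft)
        try:
            tg, _ = tg_at_timescale(vft)
        except DataValidationError:
            return
        m_closed = isobaric_fragility(vft, tg)
        h = 1e-6

        def log10_tau_of_x(x):  # x = Tg/T
            return np.log10(vft_tau(tg / x, vft))

        m_numeric = (log10_tau_of_x(1.0 + h) - log10_tau_of_x(1.0 - h)) / (2.0 * h)
        assert m_closed == pytest.approx(m_numeric, rel=1e-6)

    def test_invariant_under_tau0_reexpression(self, etb_vft):
        """Tg and m_p agree whether tau0 enters as 10**log10_tau0 or directly."""
        vft2 = VFTParams(log10_tau0=np.log10(etb_vft.tau0), A=etb_vft.A,
                         T_VFT=etb_vft.T_VFT)
        assert tg_at_timescale(vft2)[0] == pytest.approx(
            tg_at_timescale(etb_vft)[0], rel=1e-12)


class TestApparentActivationEnergy:
    def test_etb_window_value_against_local_derivative_oracle(self, etb_vft):
        """E_alpha over 361.15-373.15 K ~ 293-295 kJ/mol (local value at midpoint)."""
        e = apparent_activation_energy(etb_vft, (361.15, 373.15))
        t_mid = 367.15
        local = (etb_vft.A * t_mid**2 / (t_mid - etb_vft.T_VFT) ** 2
                 * R_GAS / 1000.0)
        assert 293.0 <= e <= 295.0
        assert e == pytest.approx(local, rel=0.01)

    def test_true_arrhenius_input_window_independent(self):
        vft = VFTParams(log10_tau0=-12.0, A=1000.0, T_VFT=0.0)
        e1 = apparent_activation_energy(vft, (300.0, 350.0))
        e2 = apparent_activation_energy(vft, (200.0, 260.0))
        assert e1 == pytest.approx(1000.0 * R_GAS / 1000.0, rel=1e-10)
        assert e2 == pytest.approx(e1, rel=1e-10)

    def test_shrinking_window_converges_to_local_derivative(self, etb_vft):
        t_star = 365.0
        local = (etb_vft.A * t_star**2 / (t_star - etb_vft.T_VFT) ** 2
                 * R_GAS / 1000.0)
        for half in (5.0, 1.0, 0.1):
            e = apparent_activation_energy(etb_vft, (t_star - half, t_star + half))
        assert e == pytest.approx(local, rel=1e-5)

    def test_convexity_bounds_between_window_edge_energies(self, etb_vft):
        """VFT is convex in 1/T: windowed slope lies between the edge slopes."""
        lo, hi = 355.0, 375.0

        def local_e(T):
            return (etb_vft.A * T**2 / (T - etb_vft.T_VFT) ** 2) * R_GAS / 1000.0

        e = apparent_activation_energy(etb_vft, (lo, hi))
        assert local_e(hi) <= e <= local_e(lo)

    def test_map_point_mode(self, etb_vft):
        temps = np.linspace(361.0, 374.0, 8)
        rmap = gen_relaxation_series(etb_vft, temps)
        e_map = apparent_activation_energy(rmap, (361.15, 373.15))
        e_vft = apparent_activation_energy(etb_vft, (361.15, 373.15))
        assert e_map == pytest.approx(e_vft, rel=0.01)

    def test_invalid_windows_rejected(self, etb_vft):
        with pytest.raises(DataValidationError):
            apparent_activation_energy(etb_vft, (373.0, 361.0))
        with pytest.raises(DataValidationError):
            apparent_activation_energy(etb_vft, (260.0, 280.0))  # below T_VFT
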