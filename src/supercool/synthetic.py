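"""Synthetic instrument-data generators with known ground truth.

Every analysis stage in this package has a matching generator here, so the
whole chain — spectral fitting, VFT parametrization, onset detection,
Arrhenius refits, mixture-Tg determination — can be exercised end to end
against controlled ground truth without any instrument data. All generators
take an explicit integer seed; identical seed and parameters give bitwise
identical output, and zero noise gives the exact model curve.

Noise models follow each observable's dynamic range: multiplicative
lognormal on the dielectric loss (which spans decades), additive Gaussian on
refractive index and heat flow, and Gaussian in log10 space for onset times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EPS0, LOG10E, R_GAS
from .crystallization import CENSORED, DETECTED, NucleationFit, OnsetTable, RITimeTrace
from .dielectric import DielectricSpectrum, HNParams, hn_loss
from .exceptions import DataValidationError
from .mixing import DSCTrace, RITempTrace
from .relaxation import RelaxationMap, VFTParams, vft_tau

__all__ = [
    "HNGroundTruth",
    "CrystTraceSpec",
    "BilinearTraceSpec",
    "gen_hn_spectrum",
    "gen_relaxation_series",
    "gen_ri_crystallization_trace",
    "gen_ri_cooling_trace",
    "gen_dsc_trace",
    "gen_onset_table",
]

# the ground-truth parameter bundle is exactly the HN parameter set
HNGroundTruth = HNParams


@dataclass(frozen=True)
class CrystTraceSpec:
    """Ground truth for one isothermal RI(t) crystallization trace.

    Pre-onset the index drifts linearly (slow densification); after the onset
    it decays by an Avrami-type transformation law, so the noiseless trace has
    its global maximum exactly at ``t_onset_true`` — the morphology of a
    refractometric crystallization run (a maximum preceding a sharp drop).
    """

    temperature: float  # K
    ri_start: float
    drift_rate: float  # 1/s, pre-onset drift
    t_onset_true: float  # s
    ri_drop: float  # total RI drop amplitude
    kinetic_rate: float  # 1/s^n
    avrami_n: float
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.t_onset_true <= 0:
            raise DataValidationError("t_onset_true must be > 0")
        if self.ri_drop < 0:
            raise DataValidationError("ri_drop must be >= 0")
        if self.avrami_n <= 0:
            raise DataValidationError("avrami_n must be > 0")
        if self.noise_sd < 0:
            raise DataValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class BilinearTraceSpec:
    """Ground truth for a cooling-scan RI(T) trace with a slope break at Tg."""

    tg_true: float  # K
    slope_liquid: float  # 1/K, above Tg
    slope_glass: float  # 1/K, below Tg
    ri_at_tg: float
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.slope_liquid == self.slope_glass:
            raise DataValidationError("slopes must differ for a detectable break")
        if self.noise_sd < 0:
            raise DataValidationError("noise_sd must be >= 0")


def gen_hn_spectrum(truth: HNGroundTruth, freq_grid, noise_rel: float,
                    seed: int) -> DielectricSpectrum:
    """Evaluate the HN + conductivity model on ``freq_grid`` and add noise.

    Multiplicative lognormal noise of relative scale ``noise_rel`` is applied
    to the loss eps''; eps' is returned noiseless (the loss is the fit target
    downstream). ``noise_rel = 0`` gives the exact model curve.
    """
    f = np.asarray(freq_grid, dtype=float)
    if np.any(f <= 0) or np.any(np.diff(f) <= 0):
        raise DataValidationError("freq_grid must be positive and ascending")
    if noise_rel < 0:
        raise DataValidationError("noise_rel must be >= 0")
    eps_real, eps_imag = hn_loss(f, truth)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        eps_imag = eps_imag * np.exp(noise_rel * rng.standard_normal(len(f)))
    return DielectricSpectrum(temperature=float("nan"), frequencies=f,
                              eps_imag=eps_imag, eps_real=eps_real)


def gen_relaxation_series(vft: VFTParams, temperatures) -> RelaxationMap:
    """Exact tau_alpha(T) = tau0 exp(A/(T - T_VFT)) at the given temperatures."""
    T = np.asarray(temperatures, dtype=float)
    tau = vft_tau(T, vft)  # rejects T <= T_VFT
    return RelaxationMap(temperatures=T, tau_alpha=tau)


def gen_ri_crystallization_trace(spec: CrystTraceSpec, time_grid,
                                 seed: int) -> RITimeTrace:
    """Linear drift to the onset, then an Avrami-type decay, plus RI noise."""
    t = np.asarray(time_grid, dtype=float)
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise DataValidationError("time_grid must be ascending and start at >= 0")
    ri = spec.ri_start + spec.drift_rate * np.minimum(t, spec.t_onset_true)
    after = t > spec.t_onset_true
    dt = t[after] - spec.t_onset_true
    ri[after] -= spec.ri_drop * (1.0 - np.exp(-spec.kinetic_rate * dt**spec.avrami_n))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        ri = ri + spec.noise_sd * rng.standard_normal(len(t))
    return RITimeTrace(temperature=spec.temperature, times=t, ri=ri)


def gen_ri_cooling_trace(spec: BilinearTraceSpec, temp_grid, seed: int) -> RITempTrace:
    """Piecewise-linear RI(T) with the slope break at ``tg_true`` plus noise."""
    T = np.asarray(temp_grid, dtype=float)
    if np.any(np.diff(T) >= 0):
        raise DataValidationError("temp_grid must be strictly descending (cooling scan)")
    dT = T - spec.tg_true
    ri = spec.ri_at_tg + np.where(dT >= 0, spec.slope_liquid, spec.slope_glass) * dT
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        ri = ri + spec.noise_sd * rng.standard_normal(len(T))
    return RITempTrace(temperatures=T, ri=ri, scan_direction="cooling")


def gen_dsc_trace(tg_true: float, step_height: float, width: float,
                  heating_rate: float, temp_grid, seed: int,
                  noise_sd: float = 0.0, baseline_slope: float = 0.0) -> DSCTrace:
    """Sigmoidal heat-flow step centered at ``tg_true``.

    The step is a logistic in temperature with scale ``width/4`` (so ``width``
    approximates the visible transition width); the half-height point of the
    noiseless trace is exactly ``tg_true``.
    """
    T = np.asarray(temp_grid, dtype=float)
    if np.any(np.diff(T) <= 0):
        raise DataValidationError("temp_grid must be strictly ascending")
    if width <= 0:
        raise DataValidationError("width must be > 0")
    scale = width / 4.0
    hf = baseline_slope * (T - T[0]) + step_height / (1.0 + np.exp(-(T - tg_true) / scale))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        hf = hf + noise_sd * rng.standard_normal(len(T))
    return DSCTrace(heating_rate=heating_rate, temperatures=T, heat_flow=hf)


def gen_onset_table(nucl: NucleationFit, temperatures, noise_log_sd: float,
                    seed: int) -> OnsetTable:
    """Arrhenius onset times, optionally with Gaussian noise in log10 space."""
    T = np.asarray(temperatures, dtype=float)
    if np.any(T <= 0):
        raise DataValidationError("temperatures must be > 0 K")
    if noise_log_sd < 0:
        raise DataValidationError("noise_log_sd must be >= 0")
    log10_t = nucl.log10_t_onset0 + nucl.e_nucl * 1000.0 / (R_GAS * T) * LOG10E
    if noise_log_sd > 0:
        rng = np.random.default_rng(seed)
        log10_t = log10_t + noise_log_sd * rng.standard_normal(len(T))
    return OnsetTable(temperatures=T, t_onset=10.0**log10_t,
                      flags=[DETECTED] * len(T))
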