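"""Isothermal crystallization-onset kinetics from refractometry time traces.

Under isothermal annealing above Tg, the refractive index of a supercooled
liquid drifts slowly (densification), passes through a well-defined maximum
and then drops sharply as the sample crystallizes. The time of that maximum
is the crystallization onset time t_onset — an estimate of the nucleation lag
time. Across temperatures the onset times follow a base-10 Arrhenius law::

    log10 t_onset = log10 t_onset0 + E_nucl / (R T) * log10(e)

whose slope yields the activation energy for nucleation E_nucl. Comparing
E_nucl with the apparent activation energy E_alpha of the structural
relaxation over the *same* temperature window gives the coupling parameter
S = E_nucl / E_alpha, which measures how strongly crystallization tracks
global molecular mobility (S = 1: fully mobility-controlled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .constants import LOG10E, R_GAS
from .exceptions import DataValidationError

__all__ = [
    "RITimeTrace",
    "OnsetTable",
    "NucleationFit",
    "CouplingReport",
    "detect_onset",
    "fit_nucleation_arrhenius",
    "predict_onset_time",
    "coupling_parameter",
]

DETECTED = "detected"
CENSORED = "censored"


@dataclass
class RITimeTrace:
    """Refractive index vs time at one fixed temperature."""

    temperature: float  # K
    times: np.ndarray  # s, strictly ascending
    ri: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ri = np.asarray(self.ri, dtype=float)
        if self.times.shape != self.ri.shape:
            raise DataValidationError("times and ri must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DataValidationError("times must be strictly ascending")
        if np.any((self.ri <= 1.0) | (self.ri >= 2.0)):
            raise DataValidationError("refractive index must lie in (1, 2)")


@dataclass
class OnsetTable:
    """Per-temperature onset times; censored rows mark runs that never crystallized."""

    temperatures: np.ndarray  # K
    t_onset: np.ndarray  # s; NaN for censored rows
    flags: list  # "detected" | "censored" per row

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.t_onset = np.asarray(self.t_onset, dtype=float)
        self.flags = list(self.flags)
        if not (len(self.temperatures) == len(self.t_onset) == len(self.flags)):
            raise DataValidationError("onset table columns must have equal length")
        for t, fl in zip(self.t_onset, self.flags):
            if fl == DETECTED and not t > 0:
                raise DataValidationError("detected rows require t_onset > 0")
            if fl not in (DETECTED, CENSORED):
                raise DataValidationError(f"unknown flag {fl!r}")

    def detected(self):
        m = np.array([fl == DETECTED for fl in self.flags])
        return self.temperatures[m], self.t_onset[m]

    def __len__(self):
        return len(self.temperatures)


@dataclass(frozen=True)
class NucleationFit:
    """Arrhenius fit of log10 t_onset vs 1/T."""

    log10_t_onset0: float  # intercept, log10(s)
    e_nucl: float  # activation energy for nucleation, kJ/mol
    covariance: np.ndarray | None = None  # 2x2 over (log10_t_onset0, e_nucl)

    @property
    def e_nucl_sd(self) -> float | None:
        if self.covariance is None:
            return None
        return float(np.sqrt(max(self.covariance[1, 1], 0.0)))


@dataclass(frozen=True)
class CouplingReport:
    """Dynamics–crystallization coupling over a shared temperature window."""

    e_nucl: float  # kJ/mol
    e_alpha: float  # kJ/mol
    s_coupling: float  # E_nucl / E_alpha
    window: tuple  # (T_low, T_high), K
    s_sd: float | None = None


def detect_onset(trace: RITimeTrace, smooth_width: int = 11, drop_factor: float = 10.0):
    """Locate the crystallization onset in one RI(t) trace.

    The trace is smoothed with a centered rolling median; the noise scale is
    1.4826*MAD/sqrt(2) of the first differences of the trace head (first 10%
    of samples, at least 50) — differencing cancels the slow pre-onset drift
    and sqrt(2) converts a difference MAD back to the per-sample scale.
    Crystallization is declared iff the smoothed trace
    later falls more than ``drop_factor`` times that scale below its running
    maximum; t_onset is the global maximum of the smoothed trace before the
    drop. Without a qualifying drop the run is censored.

    Returns
    -------
    (t_onset, flag) — t_onset is NaN when flag == "censored".
    """
    n = len(trace.times)
    if n < 50:
        raise DataValidationError("trace too short: need >= 50 points")
    width = max(int(smooth_width), 1)
    smooth = median_filter(trace.ri, size=width, mode="nearest")

    head_n = max(50, n // 10)
    diffs = np.diff(trace.ri[:head_n])
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sigma = 1.4826 * mad / np.sqrt(2.0)

    running_max = np.maximum.accumulate(smooth)
    deficit = running_max - smooth
    below = np.nonzero(deficit > drop_factor * sigma)[0]
    if len(below) == 0:
        return float("nan"), CENSORED
    drop_idx = int(below[0])
    onset_idx = int(np.argmax(smooth[:drop_idx])) if drop_idx > 0 else 0
    # refine to the raw maximum within one smoothing window: the median filter
    # can shift an asymmetric peak by a few samples
    lo = max(onset_idx - width, 0)
    hi = min(onset_idx + width + 1, drop_idx if drop_idx > 0 else n)
    if hi > lo:
        onset_idx = lo + int(np.argmax(trace.ri[lo:hi]))
    return float(trace.times[onset_idx]), DETECTED


def fit_nucleation_arrhenius(table: OnsetTable) -> NucleationFit:
    """OLS of log10 t_onset on 1/T; slope converts to E_nucl = slope*R/log10(e).

    Censored rows are excluded with a warning; at least three detected rows at
    distinct temperatures are required.
    """
    n_censored = sum(fl == CENSORED for fl in table.flags)
    if n_censored:
        warnings.warn(f"excluding {n_censored} censored onset row(s) from the "
                      "Arrhenius fit", stacklevel=2)
    temps, onsets = table.detected()
    if len(np.unique(temps)) < 3:
        raise DataValidationError(
            "need >= 3 detected onset rows at distinct temperatures"
        )
    x = 1.0 / temps
    y = np.log10(onsets)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov_lin = s2 * np.linalg.inv(X.T @ X)  # over (intercept, slope)

    slope_to_energy = R_GAS / LOG10E / 1000.0  # K -> kJ/mol
    e_nucl = float(beta[1] * slope_to_energy)
    J = np.array([[1.0, 0.0], [0.0, slope_to_energy]])
    cov = J @ cov_lin @ J.T
    return NucleationFit(log10_t_onset0=float(beta[0]), e_nucl=e_nucl, covariance=cov)


def predict_onset_time(fit: NucleationFit, temperature: float) -> float:
    """Forward-evaluate the Arrhenius law: onset time in seconds at ``temperature``."""
    if temperature <= 0:
        raise DataValidationError("temperature must be > 0 K")
    log10_t = fit.log10_t_onset0 + fit.e_nucl * 1000.0 / (R_GAS * temperature) * LOG10E
    return float(10.0**log10_t)


def coupling_parameter(
    e_nucl: float,
    e_alpha: float,
    window: tuple,
    window_alpha: tuple | None = None,
    e_nucl_sd: float | None = None,
    e_alpha_sd: float | None = None,
) -> CouplingReport:
    """Coupling parameter S = E_nucl / E_alpha over a shared temperature window.

    Both activation energies must refer to the same window — a ratio of
    energies from different temperature ranges is not meaningful — so a
    mismatching ``window_alpha`` is rejected.
    """
    if e_nucl <= 0 or e_alpha <= 0:
        raise DataValidationError("both activation energies must be > 0")
    if window_alpha is not None and tuple(window_alpha) != tuple(window):
        raise DataValidationError(
            f"temperature windows differ: {tuple(window)} vs {tuple(window_alpha)}"
        )
    s = e_nucl / e_alpha
    s_sd = None
    if e_nucl_sd is not None and e_alpha_sd is not None:
        s_sd = s * float(np.hypot(e_nucl_sd / e_nucl, e_alpha_sd / e_alpha))
    return CouplingReport(e_nucl=float(e_nucl), e_alpha=float(e_alpha),
                          s_coupling=float(s), window=tuple(window), s_sd=s_sd)
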