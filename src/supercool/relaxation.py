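"""Vogel–Fulcher–Tammann (VFT) parametrization of the relaxation map.

The structural relaxation time of a fragile glass former follows

    tau_alpha(T) = tau0 * exp(A / (T - T_VFT))

which diverges at the Vogel temperature T_VFT. From a fitted VFT curve the
module derives the dielectric glass-transition temperature (conventionally the
temperature at which tau_alpha reaches 100 s), the isobaric fragility

    m_p = d log10 tau_alpha / d(Tg/T) at T = Tg = A * Tg / (ln10 * (Tg - T_VFT)^2),

Angell's strong/fragile classification, and the apparent Arrhenius activation
energy E_alpha of log10 tau_alpha vs 1/T over a stated temperature window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .constants import LOG10E, R_GAS
from .exceptions import DataValidationError, FitConvergenceError

__all__ = [
    "VFTParams",
    "RelaxationMap",
    "FragilityReport",
    "vft_tau",
    "fit_vft",
    "tg_at_timescale",
    "isobaric_fragility",
    "classify_fragility",
    "apparent_activation_energy",
    "fragility_report",
]

#: closed fragility-class boundaries: m_p <= 30 strong, m_p >= 100 fragile
STRONG_MAX = 30.0
FRAGILE_MIN = 100.0


@dataclass(frozen=True)
class VFTParams:
    """VFT parameters in log10 form: tau_alpha = 10**log10_tau0 * exp(A/(T-T_VFT))."""

    log10_tau0: float  # log10(tau0 / s)
    A: float  # strength parameter, K
    T_VFT: float  # Vogel temperature, K
    covariance: np.ndarray | None = None  # 3x3 over (log10_tau0, A, T_VFT)

    def __post_init__(self):
        if self.A < 0:
            raise DataValidationError("A must be >= 0")
        if self.T_VFT < 0:
            raise DataValidationError("T_VFT must be >= 0")

    @property
    def tau0(self) -> float:
        return 10.0**self.log10_tau0


@dataclass
class RelaxationMap:
    """(T, tau_alpha) points extracted from dielectric loss spectra."""

    temperatures: np.ndarray  # K
    tau_alpha: np.ndarray  # s
    tau_sd: np.ndarray | None = None  # s, optional 1-sigma uncertainties

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.tau_alpha = np.asarray(self.tau_alpha, dtype=float)
        if self.tau_sd is not None:
            self.tau_sd = np.asarray(self.tau_sd, dtype=float)
            if self.tau_sd.shape != self.temperatures.shape:
                raise DataValidationError("tau_sd length differs from temperatures")
        if self.tau_alpha.shape != self.temperatures.shape:
            raise DataValidationError("tau_alpha length differs from temperatures")
        if len(np.unique(self.temperatures)) != len(self.temperatures):
            raise DataValidationError("temperatures must be unique")
        if np.any(self.tau_alpha <= 0):
            raise DataValidationError("tau_alpha must be > 0")

    def __len__(self):
        return len(self.temperatures)


@dataclass
class FragilityReport:
    """Derived glass-transition descriptors from one VFT parametrization."""

    tg_dielectric: float  # K, at the reference timescale
    tau_ref: float  # s
    m_p: float  # isobaric fragility
    class_label: str  # strong | moderately fragile | fragile
    tg_sd: float | None = None
    e_alpha: float | None = None  # kJ/mol, apparent Arrhenius energy
    e_alpha_window: tuple[float, float] | None = None


def vft_tau(temperatures, vft: VFTParams) -> np.ndarray:
    """Evaluate tau_alpha(T); rejects T <= T_VFT where the timescale diverges."""
    T = np.asarray(temperatures, dtype=float)
    if np.any(T <= vft.T_VFT):
        raise DataValidationError("temperatures must exceed T_VFT")
    return vft.tau0 * np.exp(vft.A / (T - vft.T_VFT))


def _log10_tau(T, log10_tau0, A, T_VFT):
    return log10_tau0 + A / (np.log(10.0) * (T - T_VFT))


def fit_vft(map: RelaxationMap, init: VFTParams | None = None) -> VFTParams:
    """Least-squares VFT fit of log10 tau_alpha vs T.

    T_VFT is profiled first (for fixed T_VFT the model is linear in the other
    two parameters, solved exactly), then all three parameters are polished by
    bounded least squares. Raises FitConvergenceError when the fitted Vogel
    temperature comes within 1 K of the coldest data point — extrapolations
    from such a fit are not trustworthy.
    """
    T = map.temperatures
    y = np.log10(map.tau_alpha)
    if len(T) < 4:
        raise DataValidationError("need >= 4 relaxation-map points")
    if y.max() - y.min() < 2.0:
        raise DataValidationError("relaxation map must span >= 2 decades of tau_alpha")
    t_min = float(T.min())

    def profile_sse(t0):
        x = 1.0 / (T - t0)
        X = np.column_stack([np.ones_like(x), x])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    hi = t_min - 1.0
    if init is not None and 0.0 < init.T_VFT < hi:
        t0_start = init.T_VFT
    else:
        sol = minimize_scalar(profile_sse, bounds=(0.0, hi), method="bounded",
                              options={"xatol": 1e-10})
        t0_start = float(sol.x)
    x = 1.0 / (T - t0_start)
    X = np.column_stack([np.ones_like(x), x])
    b0, b1 = np.linalg.lstsq(X, y, rcond=None)[0]
    theta0 = [b0, max(b1 * np.log(10.0), 1e-6), t0_start]

    def residuals(theta):
        lt0, A, t0 = theta
        return _log10_tau(T, lt0, A, t0) - y

    sol = least_squares(residuals, theta0,
                        bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, hi]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    lt0, A, t0 = sol.x
    if t0 > t_min - 1.0 - 1e-9:
        raise FitConvergenceError(
            f"fitted T_VFT = {t0:.2f} K is within 1 K of the coldest point "
            f"({t_min:.2f} K); VFT extrapolation refused"
        )
    dof = max(len(T) - 3, 1)
    s2 = 2.0 * sol.cost / dof
    cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
    return VFTParams(log10_tau0=float(lt0), A=float(A), T_VFT=float(t0), covariance=cov)


def tg_at_timescale(vft: VFTParams, tau_ref: float = 100.0):
    """Glass-transition temperature where the VFT curve reaches ``tau_ref``.

    Closed-form inversion Tg = T_VFT + A / ln(tau_ref/tau0); a delta-method
    standard deviation is returned alongside when the fit carries a covariance.

    Returns
    -------
    (tg, tg_sd) — tg_sd is None without covariance.
    """
    if vft.A == 0:
        raise DataValidationError("A = 0: tau_alpha is constant, Tg undefined")
    log_ratio = np.log(tau_ref) - vft.log10_tau0 * np.log(10.0)
    if log_ratio <= 0:
        raise DataValidationError("tau_ref must exceed tau0 for a Tg solution")
    tg = vft.T_VFT + vft.A / log_ratio
    tg_sd = None
    if vft.covariance is not None:
        # gradient of Tg wrt (log10_tau0, A, T_VFT)
        g = np.array([vft.A * np.log(10.0) / log_ratio**2, 1.0 / log_ratio, 1.0])
        tg_sd = float(np.sqrt(max(g @ vft.covariance @ g, 0.0)))
    return float(tg), tg_sd


def isobaric_fragility(vft: VFTParams, tg: float) -> float:
    """Isobaric fragility m_p = A*Tg / (ln10 * (Tg - T_VFT)^2) at the given Tg."""
    if tg <= vft.T_VFT:
        raise DataValidationError("Tg must exceed T_VFT")
    return float(vft.A * tg / (np.log(10.0) * (tg - vft.T_VFT) ** 2))


def classify_fragility(m_p: float) -> str:
    """Angell classification with closed boundaries: <=30 strong, >=100 fragile."""
    if m_p <= 0:
        raise DataValidationError("m_p must be > 0")
    if m_p <= STRONG_MAX:
        return "strong"
    if m_p >= FRAGILE_MIN:
        return "fragile"
    return "moderately fragile"


def apparent_activation_energy(
    vft_or_map,
    window: tuple[float, float],
    n_samples: int = 9,
) -> float:
    """Apparent Arrhenius activation energy E_alpha (kJ/mol) over a T window.

    A line is fitted to log10 tau_alpha vs 1/T using either points sampled
    evenly in 1/T from a VFT curve (default mode) or the relaxation-map points
    falling inside the window; the slope converts as E = slope * R / log10(e).
    """
    t_lo, t_hi = window
    if not t_lo < t_hi:
        raise DataValidationError("window must satisfy T_low < T_high")
    if isinstance(vft_or_map, VFTParams):
        if t_lo <= vft_or_map.T_VFT:
            raise DataValidationError("window extends to or below T_VFT")
        n = max(int(n_samples), 6)
        inv_t = np.linspace(1.0 / t_hi, 1.0 / t_lo, n)
        y = _log10_tau(1.0 / inv_t, vft_or_map.log10_tau0, vft_or_map.A, vft_or_map.T_VFT)
    elif isinstance(vft_or_map, RelaxationMap):
        m = (vft_or_map.temperatures >= t_lo) & (vft_or_map.temperatures <= t_hi)
        if np.count_nonzero(m) < 2:
            raise DataValidationError("fewer than 2 map points inside the window")
        inv_t = 1.0 / vft_or_map.temperatures[m]
        y = np.log10(vft_or_map.tau_alpha[m])
    else:
        raise TypeError("expected VFTParams or RelaxationMap")
    slope = np.polyfit(inv_t, y, 1)[0]  # K (decades per 1/K)
    return float(slope * R_GAS / LOG10E / 1000.0)


def fragility_report(
    vft: VFTParams,
    tau_ref: float = 100.0,
    e_alpha_window: tuple[float, float] | None = None,
) -> FragilityReport:
    """Convenience bundle: Tg at tau_ref, m_p, class label, optional E_alpha."""
    tg, tg_sd = tg_at_timescale(vft, tau_ref)
    m_p = isobaric_fragility(vft, tg)
    e_alpha = None
    if e_alpha_window is not None:
        e_alpha = apparent_activation_energy(vft, e_alpha_window)
    return FragilityReport(
        tg_dielectric=tg,
        tau_ref=tau_ref,
        m_p=m_p,
        class_label=classify_fragility(m_p),
        tg_sd=tg_sd,
        e_alpha=e_alpha,
        e_alpha_window=e_alpha_window,
    )
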