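"""Havriliak–Negami (HN) spectral analysis of broadband dielectric spectra.

The complex permittivity of a supercooled liquid near the glass transition is
modeled as a single structural (alpha) relaxation process plus an ohmic
dc-conductivity contribution::

    eps*(f) = -i sigma0 / (2 pi f eps0) + eps_inf + delta_eps / [1 + (i 2 pi f tau)^xi]^delta

where ``xi`` is the symmetric-broadening exponent, ``delta`` the asymmetry
exponent (``xi = delta = 1`` recovers Debye relaxation), and ``tau`` the
structural relaxation time tau_alpha read from the loss-peak position.

Fitting is performed on log10 of the dielectric loss eps'' by default, which
weights every decade of the spectrum equally; eps' can be included jointly.
Because eps'' does not depend on eps_inf, the default mode recovers eps_inf
afterwards from eps' by its exact additive offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import least_squares

from .constants import EPS0
from .exceptions import DataValidationError, FitConvergenceError, InitializationError

__all__ = [
    "HNParams",
    "DielectricSpectrum",
    "HNFitResult",
    "hn_complex_permittivity",
    "hn_loss",
    "hn_peak_frequency",
    "fit_hn_spectrum",
    "build_relaxation_map",
]


@dataclass(frozen=True)
class HNParams:
    """Parameters of one HN process plus dc conductivity.

    Serves both as generator ground truth and as a fit estimate.

    Attributes
    ----------
    sigma0 : dc conductivity, S/m (>= 0).
    eps_inf : high-frequency limit permittivity (>= 1).
    delta_eps : relaxation strength of the alpha process (> 0).
    tau_alpha : structural relaxation time, s (> 0).
    xi : symmetric-broadening exponent, 0 < xi <= 1.
    delta : asymmetry exponent; physical region requires 0 < xi*delta <= 1.
    """

    sigma0: float
    eps_inf: float
    delta_eps: float
    tau_alpha: float
    xi: float
    delta: float

    def __post_init__(self):
        if self.sigma0 < 0:
            raise DataValidationError("sigma0 must be >= 0")
        if self.eps_inf < 1:
            raise DataValidationError("eps_inf must be >= 1")
        if self.delta_eps <= 0:
            raise DataValidationError("delta_eps must be > 0")
        if self.tau_alpha <= 0:
            raise DataValidationError("tau_alpha must be > 0")
        if not 0 < self.xi <= 1:
            raise DataValidationError("xi must satisfy 0 < xi <= 1")
        if not 0 < self.xi * self.delta <= 1 + 1e-12:
            raise DataValidationError("xi*delta must satisfy 0 < xi*delta <= 1")


@dataclass
class DielectricSpectrum:
    """One temperature's permittivity record.

    ``eps_real`` is optional: loss-only measurements are common and the loss
    alone carries the relaxation time.
    """

    temperature: float  # K
    frequencies: np.ndarray  # Hz, strictly ascending
    eps_imag: np.ndarray  # dielectric loss eps''
    eps_real: np.ndarray | None = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        if self.eps_real is not None:
            self.eps_real = np.asarray(self.eps_real, dtype=float)
            if self.eps_real.shape != self.frequencies.shape:
                raise DataValidationError("eps_real length differs from frequencies")
        if self.frequencies.ndim != 1 or len(self.frequencies) == 0:
            raise DataValidationError("frequencies must be a non-empty 1-D array")
        if np.any(self.frequencies <= 0):
            raise DataValidationError("frequencies must be positive")
        if np.any(np.diff(self.frequencies) <= 0):
            raise DataValidationError("frequencies must be strictly ascending")
        if self.eps_imag.shape != self.frequencies.shape:
            raise DataValidationError("eps_imag length differs from frequencies")


@dataclass
class HNFitResult:
    """Outcome of an HN spectral fit.

    ``covariance`` is 6x6 over the natural parameter order
    (sigma0, eps_inf, delta_eps, tau_alpha, xi, delta).
    """

    params: HNParams
    covariance: np.ndarray
    residual_norm: float  # RMS residual of log10 eps'' over the fit window
    converged: bool

    @property
    def tau_alpha_sd(self) -> float:
        return float(np.sqrt(max(self.covariance[3, 3], 0.0)))


def hn_complex_permittivity(f, params: HNParams) -> np.ndarray:
    """Evaluate the complex permittivity eps*(f) = eps' - i eps''."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DataValidationError("frequency must be positive")
    omega_tau = 2j * np.pi * f * params.tau_alpha
    hn = params.delta_eps / (1.0 + omega_tau**params.xi) ** params.delta
    cond = -1j * params.sigma0 / (2.0 * np.pi * f * EPS0)
    return cond + params.eps_inf + hn


def hn_loss(f, params: HNParams):
    """Return (eps', eps'') of the HN + conductivity model at frequencies f."""
    eps = hn_complex_permittivity(f, params)
    return eps.real, -eps.imag


def hn_peak_frequency(params: HNParams) -> float:
    """Closed-form loss-peak frequency of a single HN process (sigma0 ignored).

    2 pi f_max tau = [sin(pi xi / (2 (delta+1))) / sin(pi xi delta / (2 (delta+1)))]^(1/xi)
    """
    xi, d = params.xi, params.delta
    num = np.sin(np.pi * xi / (2.0 * (d + 1.0)))
    den = np.sin(np.pi * xi * d / (2.0 * (d + 1.0)))
    return (num / den) ** (1.0 / xi) / (2.0 * np.pi * params.tau_alpha)


# ---------------------------------------------------------------------------
# fitting


def _estimate_init(spectrum: DielectricSpectrum) -> HNParams:
    """Heuristic starting point: peak position and height of the smoothed loss,
    conductivity from the lowest decade when its log-log slope approaches -1."""
    f = spectrum.frequencies
    loss = spectrum.eps_imag
    n = len(f)
    width = min(5, n if n % 2 else n - 1)
    smooth = median_filter(loss, size=max(width, 1), mode="nearest") if n >= 5 else loss

    # conductivity: slope of log10 eps'' vs log10 f over the lowest decade
    sigma0 = 0.0
    low = f <= f[0] * 10.0
    if np.count_nonzero(low) >= 3:
        slope = np.polyfit(np.log10(f[low]), np.log10(np.maximum(smooth[low], 1e-300)), 1)[0]
        if slope < -0.8:
            sigma0 = float(loss[0] * 2.0 * np.pi * f[0] * EPS0)

    # peak: interior maximum of the smoothed loss after removing the estimated tail
    resid = smooth - sigma0 / (2.0 * np.pi * f * EPS0)
    interior = slice(1, n - 1)
    if n >= 3 and np.any(resid[interior] > 0):
        ipk = 1 + int(np.argmax(resid[interior]))
        if resid[ipk] > resid[0] and resid[ipk] > resid[-1]:
            f_peak = f[ipk]
            return HNParams(
                sigma0=sigma0,
                eps_inf=1.0,
                delta_eps=float(2.0 * resid[ipk]),
                tau_alpha=float(1.0 / (2.0 * np.pi * f_peak)),
                xi=0.8,
                delta=0.8,
            )
    raise InitializationError(
        "un-initializable spectrum: no loss peak detectable and no init supplied"
    )


def fit_hn_spectrum(
    spectrum: DielectricSpectrum,
    init: HNParams | None = None,
    fit_window: tuple[float, float] | None = None,
    fit_real: bool = False,
) -> HNFitResult:
    """Fit the HN + conductivity model to one spectrum.

    Parameters
    ----------
    spectrum : the measured record; eps'' is the primary fit target.
    init : optional starting parameters; derived from the data when omitted.
    fit_window : optional (f_min, f_max) restriction in Hz.
    fit_real : include eps' jointly (then eps_inf is a free parameter);
        by default eps' only supplies the closed-form eps_inf offset.

    Returns
    -------
    HNFitResult with natural-parameter covariance; ``converged`` is False when
    the optimizer fails or ends on a bound (the xi = 1 / xi*delta = 1 Debye
    boundary excepted, as it is a legitimate physical limit).
    """
    f = spectrum.frequencies
    loss = spectrum.eps_imag
    mask = np.ones_like(f, dtype=bool)
    if fit_window is not None:
        lo, hi = fit_window
        mask = (f >= lo) & (f <= hi)
    if np.count_nonzero(mask) < 8:
        raise DataValidationError("need >= 8 points inside the fit window")
    if np.any(loss[mask] <= 0):
        raise DataValidationError("eps_imag must be > 0 where fitted")
    fw = f[mask]
    lw = loss[mask]
    rw = spectrum.eps_real[mask] if spectrum.eps_real is not None else None

    if init is None:
        init = _estimate_init(
            DielectricSpectrum(spectrum.temperature, fw, lw,
                               eps_real=rw if rw is not None else None)
        )

    free_sigma = init.sigma0 > 0
    free_epsinf = fit_real and rw is not None

    # internal vector: [log10 sigma0?, eps_inf?, log10 delta_eps, log10 tau, xi, xi*delta]
    theta0, lb, ub, labels = [], [], [], []
    if free_sigma:
        theta0.append(np.log10(init.sigma0)); lb.append(-25.0); ub.append(2.0)
        labels.append("lsig")
    if free_epsinf:
        theta0.append(max(init.eps_inf, 1.0)); lb.append(1.0); ub.append(np.inf)
        labels.append("einf")
    theta0 += [np.log10(init.delta_eps), np.log10(init.tau_alpha),
               min(max(init.xi, 1e-3), 1.0), min(max(init.xi * init.delta, 1e-3), 1.0)]
    lf = np.log10(fw)
    lb += [-8.0, float(-lf[-1] - np.log10(2 * np.pi) - 5.0), 1e-3, 1e-3]
    ub += [8.0, float(-lf[0] - np.log10(2 * np.pi) + 5.0), 1.0, 1.0]
    labels += ["ldeps", "ltau", "xi", "xid"]
    theta0 = np.clip(np.asarray(theta0, float), lb, ub)

    def unpack(theta):
        i = 0
        sigma0 = 0.0
        eps_inf = 1.0
        if free_sigma:
            sigma0 = 10.0 ** theta[i]; i += 1
        if free_epsinf:
            eps_inf = theta[i]; i += 1
        ldeps, ltau, xi, xid = theta[i:i + 4]
        return sigma0, eps_inf, 10.0**ldeps, 10.0**ltau, xi, xid / xi

    def residuals(theta):
        sigma0, eps_inf, deps, tau, xi, delta = unpack(theta)
        omega_tau = 2j * np.pi * fw * tau
        hn = deps / (1.0 + omega_tau**xi) ** delta
        model_loss = sigma0 / (2.0 * np.pi * fw * EPS0) - hn.imag
        res = np.log10(np.maximum(model_loss, 1e-300)) - np.log10(lw)
        if free_epsinf:
            model_real = eps_inf + hn.real
            res = np.concatenate([res, (model_real - rw) / np.mean(np.abs(rw))])
        return res

    sol = least_squares(residuals, theta0, bounds=(lb, ub),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)

    sigma0, eps_inf, deps, tau, xi, delta = unpack(sol.x)

    # closed-form eps_inf from eps' when it was not fitted jointly:
    # eps' = eps_inf + Re[HN], so eps_inf is the mean additive offset.
    einf_var = 0.0
    if not free_epsinf and rw is not None:
        omega_tau = 2j * np.pi * fw * tau
        hn_real = (deps / (1.0 + omega_tau**xi) ** delta).real
        offs = rw - hn_real
        eps_inf = float(np.mean(offs))
        einf_var = float(np.var(offs, ddof=1) / len(offs)) if len(offs) > 1 else 0.0

    params = HNParams(sigma0=sigma0, eps_inf=max(eps_inf, 1.0), delta_eps=deps,
                      tau_alpha=tau, xi=xi, delta=delta)

    # bound-hit check; the Debye boundary xi = xid = 1 is allowed
    tol = 1e-8
    hit = False
    for v, lo, hi, lab in zip(sol.x, lb, ub, labels):
        upper_ok = lab in ("xi", "xid") and abs(hi - 1.0) < 1e-12
        if v - lo < tol * max(1.0, abs(lo)):
            hit = True
        if np.isfinite(hi) and hi - v < tol * max(1.0, abs(hi)) and not upper_ok:
            hit = True
    converged = bool(sol.success) and not hit

    # covariance: internal Gauss-Newton estimate, delta-method to natural params
    n_res = len(sol.fun)
    dof = max(n_res - len(sol.x), 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    cov_int = s2 * np.linalg.pinv(jtj)

    ln10 = np.log(10.0)
    M = np.zeros((6, len(sol.x)))  # rows: sigma0, eps_inf, delta_eps, tau, xi, delta
    col = {lab: k for k, lab in enumerate(labels)}
    if free_sigma:
        M[0, col["lsig"]] = ln10 * sigma0
    if free_epsinf:
        M[1, col["einf"]] = 1.0
    M[2, col["ldeps"]] = ln10 * deps
    M[3, col["ltau"]] = ln10 * tau
    M[4, col["xi"]] = 1.0
    M[5, col["xi"]] = -(xi * delta) / xi**2
    M[5, col["xid"]] = 1.0 / xi
    cov = M @ cov_int @ M.T
    if not free_epsinf:
        cov[1, 1] = einf_var

    rms = float(np.sqrt(np.mean(residuals(sol.x)[: len(fw)] ** 2)))
    return HNFitResult(params=params, covariance=cov, residual_norm=rms, converged=converged)


def build_relaxation_map(fits):
    """Assemble per-temperature HN fits into a relaxation map.

    Parameters
    ----------
    fits : iterable of (temperature_K, HNFitResult).

    Non-converged fits are dropped with a warning; rows come out sorted by
    descending inverse temperature (i.e. ascending temperature).
    """
    from .relaxation import RelaxationMap

    fits = list(fits)
    if not fits:
        raise DataValidationError("empty fit list")
    rows = []
    for temperature, fit in fits:
        if not fit.converged:
            warnings.warn(
                f"dropping non-converged HN fit at T = {temperature} K", stacklevel=2
            )
            continue
        rows.append((float(temperature), fit.params.tau_alpha, fit.tau_alpha_sd))
    if not rows:
        raise FitConvergenceError("no converged fits to build a relaxation map from")
    rows.sort(key=lambda r: r[0])
    t, tau, sd = (np.array(x) for x in zip(*rows))
    return RelaxationMap(temperatures=t, tau_alpha=tau, tau_sd=sd)
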