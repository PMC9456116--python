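"""Mixture glass-transition prediction and Tg determination from scans.

The Couchman–Karasz rule predicts the Tg of a binary amorphous mixture from
the component Tg values weighted by mass fractions and the heat-capacity-jump
ratio K = dCp_excipient / dCp_drug::

    Tg = (w_d * Tg_d + K * w_e * Tg_e) / (w_d + K * w_e)

A measured Tg that sits *below* the prediction (negative divergence) — and in
particular an interior minimum of Tg vs composition — signals specific
drug–excipient interactions rather than simple plasticization, which is the
behavior of interest for crystallization-inhibiting excipients.

Two experimental Tg conventions are implemented: the midpoint of the DSC
heat-flow step, and the intersection of the two straight lines fitted to a
refractive-index-vs-temperature scan above and below the slope break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.signal import savgol_filter

from .exceptions import DataValidationError, NoTransitionError

__all__ = [
    "ComponentThermo",
    "MixtureThermo",
    "DSCTrace",
    "RITempTrace",
    "BilinearTgResult",
    "CKDivergence",
    "k_from_delta_cp",
    "couchman_karasz_tg",
    "ck_divergence",
    "tg_from_bilinear",
    "tg_from_dsc_step",
]


@dataclass(frozen=True)
class ComponentThermo:
    """Pure-component calorimetric parameters."""

    name: str
    tg: float  # K
    delta_cp: float  # heat-capacity jump at Tg, J/(g K)

    def __post_init__(self):
        if self.tg <= 0:
            raise DataValidationError("tg must be > 0")
        if self.delta_cp <= 0:
            raise DataValidationError("delta_cp must be > 0")


@dataclass
class MixtureThermo:
    """One mixture composition with its Couchman–Karasz prediction."""

    w_drug: float
    w_excipient: float
    k: float
    tg_predicted: float  # K
    tg_observed: float | None = None  # K
    divergence: float | None = None  # tg_observed - tg_predicted, K

    def __post_init__(self):
        if abs(self.w_drug + self.w_excipient - 1.0) > 1e-12:
            raise DataValidationError("weight fractions must sum to 1")
        if self.k <= 0:
            raise DataValidationError("K must be > 0")


@dataclass
class DSCTrace:
    """Normalized heat flow vs temperature at a fixed heating rate."""

    heating_rate: float  # K/min
    temperatures: np.ndarray  # K, ascending
    heat_flow: np.ndarray  # W/g

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.temperatures.shape != self.heat_flow.shape:
            raise DataValidationError("temperatures and heat_flow must match in length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise DataValidationError("temperatures must be strictly ascending")


@dataclass
class RITempTrace:
    """Refractive index vs temperature from a cooling (or heating) scan."""

    temperatures: np.ndarray  # K, monotone
    ri: np.ndarray
    scan_direction: str = "cooling"

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ri = np.asarray(self.ri, dtype=float)
        if self.temperatures.shape != self.ri.shape:
            raise DataValidationError("temperatures and ri must match in length")
        d = np.diff(self.temperatures)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DataValidationError("temperatures must be strictly monotone")
        if np.any((self.ri <= 1.0) | (self.ri >= 2.0)):
            raise DataValidationError("refractive index must lie in (1, 2)")


@dataclass
class BilinearTgResult:
    tg: float  # K, intersection of the two fitted lines
    slope_glass: float  # 1/K (low-T side)
    slope_liquid: float  # 1/K (high-T side)
    tg_sd: float | None = None


@dataclass
class CKDivergence:
    """Observed-vs-predicted mixture Tg table."""

    table: pd.DataFrame  # columns: w_excipient, tg_observed_K, tg_predicted_K, divergence_K
    interior_minimum: bool  # an interior composition sits below both neighbors


def k_from_delta_cp(dcp_excipient: float, dcp_drug: float) -> float:
    """Interaction measure K = dCp_excipient / dCp_drug."""
    if dcp_excipient <= 0 or dcp_drug <= 0:
        raise DataValidationError("heat-capacity jumps must be > 0")
    return dcp_excipient / dcp_drug


def couchman_karasz_tg(w_excipient: float, tg_drug: float, tg_excipient: float,
                       k: float) -> float:
    """Couchman–Karasz mixture Tg at excipient mass fraction ``w_excipient``."""
    if not 0.0 <= w_excipient <= 1.0:
        raise DataValidationError("w_excipient must lie in [0, 1]")
    if k <= 0:
        raise DataValidationError("K must be > 0")
    w_d = 1.0 - w_excipient
    return (w_d * tg_drug + k * w_excipient * tg_excipient) / (w_d + k * w_excipient)


def ck_divergence(observed, tg_drug: float, tg_excipient: float, k: float) -> CKDivergence:
    """Tabulate Tg_obs - Tg_CK per composition and flag interior-minimum behavior.

    Parameters
    ----------
    observed : iterable of (w_excipient, tg_observed_K), sorted or not.
    """
    rows = sorted((float(w), float(tg)) for w, tg in observed)
    recs = []
    for w, tg_obs in rows:
        tg_pred = couchman_karasz_tg(w, tg_drug, tg_excipient, k)
        recs.append((w, tg_obs, tg_pred, tg_obs - tg_pred))
    table = pd.DataFrame(recs, columns=["w_excipient", "tg_observed_K",
                                        "tg_predicted_K", "divergence_K"])
    tg_vals = table["tg_observed_K"].to_numpy()
    interior_min = any(
        tg_vals[i] < tg_vals[i - 1] and tg_vals[i] < tg_vals[i + 1]
        for i in range(1, len(tg_vals) - 1)
    )
    return CKDivergence(table=table, interior_minimum=interior_min)


def _line_fit(x, y):
    """OLS line fit returning (intercept, slope, cov2x2)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(x) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta[0], beta[1], cov


def tg_from_bilinear(trace: RITempTrace, exclusion_halfwidth: float = 2.0,
                     min_side_points: int = 10) -> BilinearTgResult:
    """Tg as the intersection of the glass- and liquid-side RI(T) lines.

    Candidate breakpoints are scanned over the interior temperature grid;
    for each, straight lines are fitted to the points lying more than
    ``exclusion_halfwidth`` kelvin away on either side (the transition region
    itself is curved in real scans) and the candidate minimizing the total SSE
    wins. Statistically indistinguishable slopes (95% overlap) raise
    NoTransitionError.
    """
    order = np.argsort(trace.temperatures)
    T = trace.temperatures[order]
    y = trace.ri[order]
    n = len(T)
    best = None
    for tc in T[1:-1]:
        lo = T < tc - exclusion_halfwidth
        hi = T > tc + exclusion_halfwidth
        if np.count_nonzero(lo) < min_side_points or np.count_nonzero(hi) < min_side_points:
            continue
        a1, b1, c1 = _line_fit(T[lo], y[lo])
        a2, b2, c2 = _line_fit(T[hi], y[hi])
        sse = (np.sum((y[lo] - (a1 + b1 * T[lo])) ** 2)
               + np.sum((y[hi] - (a2 + b2 * T[hi])) ** 2))
        if best is None or sse < best[0]:
            best = (sse, a1, b1, c1, a2, b2, c2)
    if best is None:
        raise DataValidationError(
            f"need >= {min_side_points} points on each side of a candidate breakpoint"
        )
    _, a1, b1, c1, a2, b2, c2 = best
    slope_se = np.sqrt(max(c1[1, 1], 0.0) + max(c2[1, 1], 0.0))
    if abs(b1 - b2) <= 1.959964 * slope_se:
        raise NoTransitionError("no transition detected: slopes are statistically equal")
    tg = (a2 - a1) / (b1 - b2)
    # delta-method sd of the intersection of two independent fitted lines
    d = b1 - b2
    g1 = np.array([-1.0 / d, -tg / d])  # d tg / d(a1, b1)
    g2 = np.array([1.0 / d, tg / d])  # d tg / d(a2, b2)
    tg_var = g1 @ c1 @ g1 + g2 @ c2 @ g2
    return BilinearTgResult(tg=float(tg), slope_glass=float(b1), slope_liquid=float(b2),
                            tg_sd=float(np.sqrt(max(tg_var, 0.0))))


def tg_from_dsc_step(trace: DSCTrace, baseline_fraction: float = 1.0 / 3.0,
                     min_step_snr: float = 5.0):
    """Midpoint Tg of a DSC glass-transition step.

    Linear baselines are fitted over the outer ``baseline_fraction`` of the
    scan on each side; Tg is where the signal crosses the half-height between
    the extrapolated baselines. The crossing is refined on a cubic spline of
    the (lightly smoothed) normalized signal.

    Returns
    -------
    (tg, step_height) — step height in W/g at Tg.
    """
    T = trace.temperatures
    y = trace.heat_flow
    n = len(T)
    if n < 20:
        raise DataValidationError("DSC trace too short: need >= 20 points")
    k = max(int(n * baseline_fraction), 3)
    a_lo, b_lo, _ = _line_fit(T[:k], y[:k])
    a_hi, b_hi, _ = _line_fit(T[-k:], y[-k:])
    base_lo = a_lo + b_lo * T
    base_hi = a_hi + b_hi * T
    gap = base_hi - base_lo
    mid = 0.5 * (T[0] + T[-1])
    step_mid = (a_hi + b_hi * mid) - (a_lo + b_lo * mid)
    noise = float(np.std(y[:k] - (a_lo + b_lo * T[:k]), ddof=2)) if k > 2 else 0.0
    if abs(step_mid) <= min_step_snr * noise or abs(step_mid) == 0.0:
        raise NoTransitionError("no detectable heat-flow step")
    if np.any(np.abs(gap) < 0.1 * abs(step_mid)):
        raise NoTransitionError("baselines cross inside the scan; step ill-defined")

    r = (y - base_lo) / gap  # 0 on the low baseline, 1 on the high one
    window = min(11, n if n % 2 else n - 1)
    rs = savgol_filter(r, window_length=window, polyorder=3) if n >= 11 else r

    above = rs >= 0.75
    below = rs <= 0.25
    if not above.any() or not below.any():
        raise NoTransitionError("signal never clears both quarter-height levels")
    i_hi = int(np.argmax(above))  # first index at >= 0.75
    lows = np.nonzero(below[:i_hi])[0]
    if len(lows) == 0:
        raise NoTransitionError("no low plateau precedes the step")
    i_lo = int(lows[-1])
    spline = CubicSpline(T, rs - 0.5)
    seg = np.nonzero((rs[i_lo:i_hi] - 0.5) * (rs[i_lo + 1:i_hi + 1] - 0.5) <= 0)[0]
    if len(seg) == 0:
        raise NoTransitionError("no half-height crossing found")
    j = i_lo + int(seg[0])
    tg = brentq(spline, T[j], T[j + 1], xtol=1e-12)
    step_height = float((a_hi + b_hi * tg) - (a_lo + b_lo * tg))
    return float(tg), step_height
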