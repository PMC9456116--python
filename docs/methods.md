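# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `supercool`. Everything quantitative stated here is
computed by the test suite or the examples; nothing is asserted that the code
does not reproduce.

## Dielectric stage

**Model.** One structural (alpha) relaxation process per spectrum, described
by the Havriliak–Negami (HN) function plus a purely ohmic dc-conductivity
term:

    eps*(f) = -i sigma0/(2 pi f eps0) + eps_inf + d_eps/[1 + (i 2 pi f tau_a)^xi]^delta

Parameters and defaults: sigma0 >= 0 S/m (0 when no low-frequency tail is
present); eps_inf >= 1; d_eps > 0; tau_alpha > 0 s; 0 < xi <= 1 and
0 < xi*delta <= 1 (the physical HN region; delta itself is not bounded above,
only the product). xi = delta = 1 is the Debye limit. The conductivity
exponent is fixed at 1; fractional-exponent conductivity, electrode
polarization, and secondary (beta/gamma) relaxations are out of scope — the
supercooled-liquid alpha process is the only target.

**Fit target.** Residuals are formed on log10 eps'' (the loss spans many
decades; log-space weighting equalizes them). eps' does not depend on
eps_inf through the loss, so in the default mode eps_inf is recovered
afterwards in closed form as the mean of eps' minus the real part of the
fitted HN term — eps_inf enters eps' purely additively, making this exact.
A joint eps' + eps'' mode (`fit_real=True`) treats eps_inf as a free
parameter instead. Without eps' data, eps_inf is reported as the initial
value (default 1) and carries no information.

**Optimizer.** Bounded trust-region least squares (scipy) over
(log10 sigma0, log10 d_eps, log10 tau, xi, xi*delta): the log scales handle
parameters spanning decades, and the product parametrization turns the
nonlinear constraint xi*delta <= 1 into a box bound. Tolerances are set to
1e-15 so noiseless synthetic spectra are recovered to better than 1e-6
relative in all six parameters (verified in the suite). Initialization
follows the data: tau from the smoothed-loss peak position (1/(2 pi f_peak)),
d_eps = 2 * peak height, xi = delta = 0.8, and sigma0 from the lowest-decade
amplitude when the low-frequency log-log slope is steeper than -0.8,
otherwise sigma0 is fixed at zero and excluded from the fit. A spectrum with
no detectable interior peak and no user initialization is rejected. Fits
ending on a bound are flagged non-converged, except on the xi = 1 or
xi*delta = 1 boundary, which is the legitimate Debye limit.

**Covariance.** Gauss–Newton covariance in the internal parametrization,
delta-method-transformed to the natural parameters; the closed-form eps_inf
contributes its own mean-standard-error on the diagonal. tau uncertainties
from this matrix feed the relaxation map.

## Relaxation map and VFT stage

log10 tau_alpha vs T is fitted with the Vogel–Fulcher–Tammann law,
tau = tau0 exp(A/(T - T_VFT)), by profiling: for fixed T_VFT the model is
linear in (log10 tau0, A/ln10) and solved exactly, the 1-D profile over
T_VFT is minimized, and a final bounded least-squares polish yields the
parameters and covariance. Unweighted residuals in log10 tau are the
default; a fit needs >= 4 points spanning >= 2 decades. A fitted T_VFT
within 1 K of the coldest data point raises an error rather than returning
an untrustworthy extrapolation.

Derived quantities, all closed-form with delta-method uncertainties:

* **Dielectric Tg**: Tg = T_VFT + A/ln(tau_ref/tau0) at the conventional
  reference timescale tau_ref = 100 s (configurable).
* **Isobaric fragility**: m_p = A*Tg/(ln10 (Tg - T_VFT)^2), which the suite
  checks against the numeric d log10 tau / d(Tg/T) derivative to 1e-6.
  Class boundaries are closed exactly as conventionally printed: m_p <= 30
  strong, 30 < m_p < 100 moderately fragile, m_p >= 100 fragile.
* **Apparent activation energy** E_alpha over a window [T_low, T_high]: a
  line through log10 tau vs 1/T, E = slope * R * ln10, reported in kJ/mol.
  By default the points are sampled from the fitted VFT curve at >= 6
  positions evenly spaced in 1/T (a measured map rarely has many points
  inside a narrow window); a raw-map-point mode is provided. VFT convexity
  in 1/T brackets any windowed E_alpha between the local Arrhenius energies
  at the window edges, which the suite asserts.

## Crystallization-onset stage

**Onset definition.** t_onset is the time of the global maximum of the
(rolling-median-smoothed, width 11) RI trace before the crystallization
drop — the refractometric convention. The drop criterion and noise handling
are this package's own: the per-sample noise scale is estimated as
1.4826*MAD/sqrt(2) of the first differences of the trace head (first 10% of
samples, >= 50; differencing cancels the slow densification drift), and
crystallization is declared only if the smoothed trace falls more than
drop_factor (default 10) noise scales below its running maximum. The
detected index is refined to the raw-trace maximum within one smoothing
window, which makes noiseless recovery exact while leaving noisy recovery
bounded by the window. Traces with no qualifying drop are *censored*, and
censoring is monotone in drop_factor. With 10 s sampling and 5e-5 RI noise
the suite recovers a 6 h onset with a median error under 2 minutes.

**Arrhenius fit.** Ordinary least squares of log10 t_onset on 1/T (censored
rows excluded with a warning; >= 3 detected temperatures required), slope
converted by E = slope * R * ln10. Energies are kJ/mol externally and J/mol
internally; R = 8.314 J/(mol K). Unweighted OLS is the default since onset
tables rarely carry usable per-point errors.

**Coupling.** S = E_nucl/E_alpha with both energies referred to the *same*
temperature window (a mismatch is an error, not a warning — the ratio is
meaningless across different ranges), with propagated uncertainty when both
standard errors are supplied.

## Mixture-Tg stage

Couchman–Karasz: Tg = (w_d Tg_d + K w_e Tg_e)/(w_d + K w_e) with
K = dCp_e/dCp_d from the calorimetric heat-capacity jumps; K = 1 reduces
exactly to linear mixing. Mass fractions throughout. The divergence table
reports Tg_obs - Tg_CK per composition and flags an interior minimum
(a composition sitting below both neighbors) — the fingerprint that rules
out anti-plasticization as the stabilization mechanism.

**Bilinear scan Tg.** Candidate breakpoints are scanned over the interior
temperature grid; for each, lines are fitted to the points more than
exclusion_halfwidth (default 2 K) away on either side — real scans are
curved through the transition — and the total-SSE minimizer wins. Tg is the
intersection of the two lines; slopes indistinguishable at 95% raise a
no-transition error. On noiseless piecewise-linear input the recovery is
exact for any interior breakpoint.

**DSC step Tg.** Linear baselines over the outer thirds of the scan,
normalized signal (y - base_low)/(base_high - base_low), light
Savitzky–Golay smoothing (window 11, order 3), and the half-height crossing
located between the last quarter-height and first three-quarter-height
points, refined by root-finding on a cubic spline. A step smaller than 5
baseline noise standard deviations (or zero) raises a no-transition error.

## Synthetic generators

The generators emulate the qualitative morphology of each instrument record,
with explicit seeds and bitwise-reproducible output:

* **Dielectric**: exact HN + conductivity curves on 1e-2 to 1e6 Hz at 13
  points/decade (the standard spectrometer range), multiplicative lognormal
  noise on the loss (matching its decade-spanning range); eps' is returned
  noiseless since the loss is the downstream fit target.
* **RI(t) crystallization**: linear pre-onset drift plus an Avrami-type
  post-onset decay ri_drop*(1 - exp(-k (t-t0)^n)) — the standard isothermal
  transformation form, guaranteeing the maximum-then-drop morphology with
  the global maximum exactly at the construction onset. Defaults used in the
  tests (drift 5e-7 /s, drop 0.015, noise 5e-5 RI units, 10 s sampling) are
  chosen to match the visible scale of published refractograms; the real
  instruments' noise level and point density are not published, so these are
  realistic choices, not inferences.
* **RI(T) cooling scan**: piecewise-linear with liquid/glass slopes -4e-4
  and -1.2e-4 per K in the tests (typical dn/dT magnitudes for organic
  melts), additive Gaussian noise at the 1e-4 resolution of a bench
  refractometer.
* **DSC**: logistic step of scale width/4 centered at Tg (so the noiseless
  half-height point is exactly Tg), optional linear baseline slope, additive
  Gaussian noise.
* **Onset tables**: exact base-10 Arrhenius values with optional Gaussian
  noise in log10 space.

What the generators do *not* emulate — and therefore what passing tests do
not demonstrate on real data: secondary relaxations and electrode
polarization in spectra, curvature and enthalpy-overshoot structure around
real DSC steps, temperature drift during isothermal runs, and
partial/two-step crystallization. The estimators' defaults (smoothing
widths, drop_factor, exclusion zones) exist precisely because real traces
violate the idealized forms.

## Reproducibility and problem sizes

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`). The Monte-Carlo recovery studies in the suite
use 50 seeds (HN noise study), 100 seeds (onset, bilinear, DSC), and 200
seeds (VFT coverage) at the trace sizes quoted above; the whole suite runs
in well under a minute on one core. The acceptance script's recomputations
are noiseless and deterministic: five onset temperatures for the Arrhenius
round trip and 12 temperatures spanning 330–380 K for the VFT round trips.

## Known limitations

* Single-process dielectric fitting only; spectra whose loss peak lies
  entirely outside the measured window cannot be initialized automatically.
* The VFT covariance is a Gauss–Newton linearization; for this strongly
  correlated three-parameter family the joint 2-sigma box is slightly
  anti-conservative even though per-parameter coverage is nominal.
* Onset detection assumes a single monotone drop; oscillatory or two-stage
  transformations will trigger on the first qualifying drop.
* Couchman–Karasz handles binary mixtures only; no Gordon–Taylor
  density-based K, no ternary systems, no enthalpy-relaxation corrections.
* Heating-rate dependence of the DSC Tg is treated as metadata, not modeled.
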