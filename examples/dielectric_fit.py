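"""Fit the Havriliak-Negami + dc-conductivity model to one dielectric spectrum.

Builds a synthetic loss spectrum with known parameters (an asymmetric alpha
peak riding on a weak conductivity tail, as measured on a supercooled drug
melt), fits it, and compares estimate to truth.
"""

import numpy as np

from supercool import HNParams, fit_hn_spectrum, gen_hn_spectrum

truth = HNParams(sigma0=1e-10, eps_inf=3.0, delta_eps=3.0, tau_alpha=1e-3,
                 xi=0.85, delta=0.6)
freqs = np.logspace(-2, 6, 105)  # 10 mHz - 1 MHz, 13 points/decade
spectrum = gen_hn_spectrum(truth, freqs, noise_rel=0.01, seed=1)

result = fit_hn_spectrum(spectrum)
p = result.params
print(f"converged: {result.converged}")
print(f"tau_alpha = {p.tau_alpha:.4g} s  (truth 1e-3; the structural relaxation time)")
print(f"delta_eps = {p.delta_eps:.3f}   (relaxation strength)")
print(f"xi = {p.xi:.3f}, delta = {p.delta:.3f}  (peak broadening / asymmetry)")
print(f"sigma0 = {p.sigma0:.3g} S/m  (dc conductivity)")
# tau_alpha is the quantity carried forward to the relaxation map: its
# temperature dependence encodes the approach to the glass transition.
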