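"""Published characterization values for etoricoxib (ETB) and octaacetylmaltose (acMAL).

Literature fixtures for the worked examples and round-trip tests: calorimetric
glass-transition temperatures, heat-capacity jumps, VFT parametrizations of
the dielectric relaxation maps, and the Arrhenius nucleation fit obtained from
refractometric isothermal crystallization of the pure drug. Experimental
values are fixtures, not quantities this package computes.
"""

from __future__ import annotations

from .crystallization import NucleationFit
from .relaxation import VFTParams

#: Calorimetric Tg (K) at 10 K/min heating for the ETB-acMAL system.
DSC_TG_K = {
    "pure ETB": 330.0,
    "ETB + 10 wt% acMAL": 329.0,
    "ETB + 20 wt% acMAL": 327.0,
    "ETB + 50 wt% acMAL": 326.0,
    "pure acMAL": 332.0,
}

#: Heat-capacity jumps at Tg, J/(g K).
DELTA_CP = {"ETB": 0.347, "acMAL": 0.350}

#: VFT parametrizations (log10 tau0 / s, A / K, T_VFT / K) of the dielectric
#: relaxation maps, per composition.
VFT_PARAMS = {
    "pure ETB": VFTParams(log10_tau0=-16.8, A=2730.0, T_VFT=265.0),
    "ETB + 20 wt% acMAL": VFTParams(log10_tau0=-19.3, A=4000.0, T_VFT=244.0),
    "ETB + 30 wt% acMAL": VFTParams(log10_tau0=-17.6, A=3200.0, T_VFT=254.0),
    "ETB + 40 wt% acMAL": VFTParams(log10_tau0=-16.7, A=2880.0, T_VFT=258.0),
    "ETB + 50 wt% acMAL": VFTParams(log10_tau0=-16.0, A=2635.0, T_VFT=261.0),
    "pure acMAL": VFTParams(log10_tau0=-12.3, A=1400.0, T_VFT=285.0),
}

#: Arrhenius nucleation fit for supercooled pure ETB (refractometric onsets).
NUCLEATION_ETB = NucleationFit(log10_t_onset0=-19.9, e_nucl=171.0)

#: Reported nucleation activation energy for celecoxib (kJ/mol), for comparison.
E_NUCL_CEL_KJ_MOL = 217.0

#: Temperatures (K) of the isothermal crystallization runs on pure ETB.
CRYSTALLIZATION_TEMPS_K = (361.0, 363.0, 366.0, 368.0, 373.0)

#: Apparent Arrhenius activation energy of the ETB structural relaxation
#: (kJ/mol) over the crystallization window, and that window.
E_ALPHA_ETB_KJ_MOL = 290.0
E_ALPHA_WINDOW_K = (361.15, 373.15)
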