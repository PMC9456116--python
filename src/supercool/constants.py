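"""Physical constants used throughout the package.

These are fixed CODATA values, never user-settable: changing them would
silently change every activation energy and conductivity in a report.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the physical constants the models depend on."""

    eps0: float = 8.8541878128e-12  # vacuum permittivity, F/m
    R: float = 8.314  # gas constant, J/(mol K)
    log10e: float = 0.4342944819  # log10(e); appears in base-10 Arrhenius forms


CONSTANTS = PhysicalConstants()

EPS0 = CONSTANTS.eps0
R_GAS = CONSTANTS.R
LOG10E = CONSTANTS.log10e
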