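import numpy as np
import pytest

from supercool import (CrystTraceSpec, HNParams, gen_hn_spectrum,
                       gen_ri_crystallization_trace, predict_onset_time, vft_tau)
from supercool.reference import (CRYSTALLIZATION_TEMPS_K, NUCLEATION_ETB,
                                 VFT_PARAMS)


@pytest.fixture
def etb_vft():
    """Literature VFT parametrization of pure etoricoxib."""
    return VFT_PARAMS["pure ETB"]


@pytest.fixture
def acmal_vft():
    return VFT_PARAMS["pure acMAL"]


@pytest.fixture
def hn_truth():
    """A typical asymmetric alpha-loss process riding on a weak dc tail."""
    return HNParams(sigma0=1e-10, eps_inf=3.0, delta_eps=3.0, tau_alpha=1e-3,
                    xi=0.85, delta=0.6)


@pytest.fixture
def freq_grid():
    """10^-2 to 10^6 Hz at 13 points/decade (typical spectrometer range)."""
    return np.logspace(-2, 6, 105)


@pytest.fixture
def noiseless_spectrum(hn_truth, freq_grid):
    return gen_hn_spectrum(hn_truth, freq_grid, 0.0, seed=0)


@pytest.fixture
def etb_onset_trace():
    """Noiseless 368 K crystallization trace with the literature onset time."""
    t_onset = predict_onset_time(NUCLEATION_ETB, 368.0)
    spec = CrystTraceSpec(temperature=368.0, ri_start=1.528, drift_rate=5e-7,
                          t_onset_true=t_onset, ri_drop=0.015, kinetic_rate=1e-7,
                          avrami_n=2.0, noise_sd=0.0)
    times = np.arange(0.0, 1.5 * t_onset, 10.0)
    return gen_ri_crystallization_trace(spec, times, seed=0), t_onset
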