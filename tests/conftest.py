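import numpy as np
import pytest
from hypothesis import settings

from stdpnet import EXCITATORY, INHIBITORY, LayerState

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def exc_params():
    return EXCITATORY


@pytest.fixture
def inh_params():
    return INHIBITORY


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_neuron(exc_params):
    """One excitatory neuron at rest."""
    return LayerState.at_rest(1, exc_params)


def closed_form_isi_ms(params, I_ext_nA):
    """Analytic inter-spike interval of a noise-free LIF under constant
    current: refractory period plus the exponential rise time from the
    reset potential to threshold toward V_inf = V_0 + I/g_0."""
    v_inf = params.v0_mV + 1000.0 * I_ext_nA / params.g0_nS
    rise = params.tau_m_ms * np.log(
        (v_inf - params.vH_mV) / (v_inf - params.theta_mV)
    )
    return params.tau_R_ms + rise
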