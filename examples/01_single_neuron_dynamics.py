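"""Conductance-based LIF basics: relaxation and constant-current firing.

Integrates a single excitatory pyramidal cell with Forward-Euler at
dt = 0.02 ms and compares against the closed-form solutions.
"""

import numpy as np

from stdpnet import EXCITATORY, LayerState, step_membrane

DT = 0.02

# --- passive relaxation from a perturbed potential ----------------------
state = LayerState.at_rest(1, EXCITATORY)
state.V[:] = -60.0
for _ in range(int(20.0 / DT)):
    step_membrane(state, EXCITATORY, 0.0, DT)
analytic = EXCITATORY.v0_mV + (-60.0 - EXCITATORY.v0_mV) * np.exp(-20.0 / EXCITATORY.tau_m_ms)
print(f"V after 20 ms of relaxation: {state.V[0]:.3f} mV (closed form {analytic:.3f} mV)")
# The membrane decays exponentially back to rest with tau_m = C_m/g_0 = 20 ms.

# --- constant 1 nA current injection ------------------------------------
state = LayerState.at_rest(1, EXCITATORY)
state.I_ext_nA[:] = 1.0
spikes = []
for step in range(int(1000.0 / DT)):
    step_membrane(state, EXCITATORY, 0.0, DT)
    if state.spike_flags[0]:
        spikes.append(step * DT)
v_inf = EXCITATORY.v0_mV + 1000.0 / EXCITATORY.g0_nS
isi = EXCITATORY.tau_R_ms + EXCITATORY.tau_m_ms * np.log(
    (v_inf - EXCITATORY.vH_mV) / (v_inf - EXCITATORY.theta_mV)
)
rate = (len(spikes) - 1) / ((spikes[-1] - spikes[0]) / 1000.0)
print(f"firing rate at 1 nA: {rate:.1f} Hz (closed-form ISI {isi:.2f} ms -> {1000/isi:.1f} Hz)")
# The cell charges toward V_inf = -34 mV and fires at ~172 Hz: the
# refractory period plus the exponential rise from reset to threshold.
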