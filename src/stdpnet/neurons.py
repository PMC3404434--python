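"""Conductance-based leaky integrate-and-fire membrane dynamics.

The membrane potential of neuron ``i`` obeys

    tau_m dV_i/dt = V_0 - V_i + R*I_i(t) + R*I_i_ext(t) + sigma * xi(t) * sqrt(tau_m)

where ``tau_m = C_m / g_0`` is the membrane time constant, ``R = 1/g_0`` the
membrane resistance, ``I_i`` the total synaptic current, ``I_i_ext`` a direct
current injection and ``xi`` Gaussian white noise of unit variance whose
amplitude is set by ``sigma = 0.015 * (Theta - V_H)``.  Integration uses
Forward-Euler with the noise term discretised Euler-Maruyama style:
each step adds ``sigma * N(0,1) * sqrt(dt/tau_m)`` millivolts.

A neuron that reaches the firing threshold ``Theta`` emits a spike, is reset
to the after-spike hyperpolarisation potential ``V_H`` and is then clamped at
``V_H`` for the absolute refractory period ``tau_R`` (no integration, no
noise while refractory).

Units throughout the package: millivolts, milliseconds, nanosiemens,
picoamps internally (injected currents are specified in nanoamps and
converted, 1 nA = 1000 pA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationParams",
    "LayerState",
    "EXCITATORY",
    "INHIBITORY",
    "step_membrane",
    "synaptic_current",
    "NumericalError",
]


class NumericalError(RuntimeError):
    """Raised when the membrane integration produces non-finite values."""


@dataclass(frozen=True)
class PopulationParams:
    """Cellular constants for one neuron class (excitatory or inhibitory).

    Parameters
    ----------
    class_label:
        ``"excitatory"`` or ``"inhibitory"``.
    c_m_pF:
        Somatic capacitance C_m (pF).
    g0_nS:
        Somatic leakage conductance g_0 (nS).
    v0_mV:
        Resting potential V_0 (mV).
    theta_mV:
        Firing threshold Theta (mV).
    vH_mV:
        After-spike hyperpolarisation potential V_H (mV).
    vhat_E_mV, vhat_I_mV:
        Reversal potentials of excitatory / inhibitory synapses onto this
        class (mV).
    tau_R_ms:
        Absolute refractory period (ms).
    sigma_coeff:
        Dimensionless noise coefficient; the membrane noise standard
        deviation is ``sigma_coeff * (theta_mV - vH_mV)`` millivolts.
    """

    class_label: str
    c_m_pF: float
    g0_nS: float
    v0_mV: float
    theta_mV: float
    vH_mV: float
    vhat_E_mV: float = 0.0
    vhat_I_mV: float = -70.0
    tau_R_ms: float = 2.0
    sigma_coeff: float = 0.015

    def __post_init__(self) -> None:
        if self.c_m_pF <= 0 or self.g0_nS <= 0:
            raise ValueError("capacitance and leak conductance must be positive")
        if not self.theta_mV > self.vH_mV:
            raise ValueError("firing threshold must exceed the reset potential")
        if not self.theta_mV > self.v0_mV:
            raise ValueError("firing threshold must exceed the resting potential")
        if self.tau_R_ms <= 0:
            raise ValueError("refractory period must be positive")

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant C_m / g_0 (ms)."""
        return self.c_m_pF / self.g0_nS

    @property
    def sigma_mV(self) -> float:
        """Membrane-noise standard deviation (mV)."""
        return self.sigma_coeff * (self.theta_mV - self.vH_mV)


#: Pyramidal-cell constants used in all simulations.
EXCITATORY = PopulationParams("excitatory", c_m_pF=500.0, g0_nS=25.0,
                              v0_mV=-74.0, theta_mV=-53.0, vH_mV=-57.0)

#: Interneuron constants used in all simulations.
INHIBITORY = PopulationParams("inhibitory", c_m_pF=214.0, g0_nS=18.0,
                              v0_mV=-82.0, theta_mV=-53.0, vH_mV=-58.0)


@dataclass
class LayerState:
    """Mutable per-neuron state of one population.

    ``refractory_steps`` counts the remaining whole integration steps for
    which the neuron is clamped at V_H; storing steps (rather than
    milliseconds) makes the refractory duration exact at any ``dt``.
    """

    V: np.ndarray
    refractory_steps: np.ndarray
    spike_flags: np.ndarray
    I_ext_nA: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.I_ext_nA is None:
            self.I_ext_nA = np.zeros_like(self.V)

    @classmethod
    def at_rest(cls, n: int, params: PopulationParams) -> "LayerState":
        return cls(
            V=np.full(n, params.v0_mV, dtype=float),
            refractory_steps=np.zeros(n, dtype=np.int64),
            spike_flags=np.zeros(n, dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.V)


def refractory_steps_for(params: PopulationParams, dt_ms: float) -> int:
    """Number of whole steps a neuron stays clamped after a spike.

    ``ceil(tau_R/dt)`` with a small guard against floating-point noise in
    the quotient (2.0/0.02 must give exactly 100 steps).
    """
    return int(np.ceil(params.tau_R_ms / dt_ms - 1e-9))


def step_membrane(
    state: LayerState,
    params: PopulationParams,
    I_syn_pA: np.ndarray | float,
    dt_ms: float,
    rng: np.random.Generator | None = None,
) -> LayerState:
    """Advance the membrane potentials by one Forward-Euler step (in place).

    Parameters
    ----------
    state:
        Population state; modified in place and returned.
    I_syn_pA:
        Total synaptic current per neuron (pA), e.g. from
        :func:`synaptic_current`.
    rng:
        Source of the Gaussian membrane noise.  ``None`` disables noise.

    Neurons whose potential reaches ``theta_mV`` emit a spike
    (``state.spike_flags``), are reset to ``vH_mV`` and stay clamped for
    the refractory period.  Refractory neurons do not integrate and
    receive no noise.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    V = state.V
    n = V.shape[0]
    tau = params.tau_m_ms
    a = dt_ms / tau

    I_total = np.asarray(I_syn_pA, dtype=float) + 1000.0 * state.I_ext_nA
    if not np.all(np.isfinite(I_total)):
        bad = int(np.flatnonzero(~np.isfinite(np.broadcast_to(I_total, V.shape)))[0])
        raise NumericalError(f"non-finite synaptic/injected current at neuron {bad}")

    dV = a * (params.v0_mV - V) + (a / params.g0_nS) * I_total
    if rng is not None and params.sigma_mV > 0:
        dV = dV + params.sigma_mV * np.sqrt(a) * rng.standard_normal(n)

    refractory = state.refractory_steps > 0
    V += dV
    V[refractory] = params.vH_mV
    state.refractory_steps[refractory] -= 1

    if not np.all(np.isfinite(V)):
        bad = int(np.flatnonzero(~np.isfinite(V))[0])
        raise NumericalError(f"non-finite membrane potential at neuron {bad}")

    fired = V >= params.theta_mV  # refractory neurons sit at vH < theta
    state.spike_flags = fired
    if fired.any():
        V[fired] = params.vH_mV
        state.refractory_steps[fired] = refractory_steps_for(params, dt_ms)
    return state


def synaptic_current(V_mV: np.ndarray, groups) -> np.ndarray:
    """Total synaptic current per postsynaptic neuron (pA).

    ``I_i = sum_gamma sum_j g_ij * (vhat_gamma - V_i)`` where ``gamma`` runs
    over the synapse groups (each with its own reversal potential
    ``vhat_mV``).  Inhibitory terms are negative whenever ``V_i`` is above
    the inhibitory reversal potential.

    Each group must expose ``conductance_onto()`` returning the summed
    conductance per postsynaptic neuron (nS) and a ``vhat_mV`` attribute.
    """
    V = np.asarray(V_mV, dtype=float)
    I = np.zeros_like(V)
    for grp in groups:
        g_tot = grp.conductance_onto()
        if g_tot.shape != V.shape:
            raise ValueError(
                f"synapse group targets {g_tot.shape[0]} neurons, layer has {V.shape[0]}"
            )
        I += g_tot * (grp.vhat_mV - V)
    return I
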