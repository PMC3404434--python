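"""Synaptic conductance dynamics with conduction delays.

Each synapse ``ij`` carries a conductance ``g_ij`` that decays with time
constant ``tau_g`` and jumps by ``lambda * Delta_g_ij`` whenever a
(delayed) presynaptic spike arrives:

    dg_ij/dt = -g_ij/tau_g + lambda * Delta_g_ij(t) * sum_l delta(t - dt_ij - t_j^l)

``lambda`` is a biological scaling constant (5 nS unless a projection's
printed conductance range dictates otherwise) and the efficacy
``Delta_g_ij`` lies in [0, 1].  In the discrete scheme the Dirac delta
absorbs the 1/dt factor, so a spike increments ``g`` by exactly
``lambda * Delta_g_ij``; the decay uses the Forward-Euler factor
``(1 - dt/tau_g)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque

import numpy as np

__all__ = ["SynapseGroup", "DelayLine", "step_conductances"]


@dataclass
class SynapseGroup:
    """One projection's per-synapse conductance state.

    ``g`` and ``delta_g`` are (n_target, n_source) arrays (``delta_g`` may
    be a scalar for non-plastic projections with uniform efficacy).
    ``vhat_mV`` is the reversal potential of this synapse class on the
    target neurons (0 mV excitatory, -70 mV inhibitory by default).
    """

    source_class: str
    target_class: str
    g: np.ndarray
    delta_g: np.ndarray | float
    lambda_nS: float
    tau_g_ms: float
    vhat_mV: float
    delay_ms: float = 0.0
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.tau_g_ms <= 0:
            raise ValueError("synaptic time constant tau_g must be positive")
        if self.delay_ms < 0:
            raise ValueError("conduction delay must be non-negative")
        dg = np.asarray(self.delta_g)
        if np.any(dg < 0) or np.any(dg > 1):
            raise ValueError("synaptic efficacies Delta_g must lie in [0, 1]")
        if np.any(np.asarray(self.g) < 0):
            raise ValueError("conductances must be non-negative")

    @property
    def n_target(self) -> int:
        return self.g.shape[0]

    @property
    def n_source(self) -> int:
        return self.g.shape[1]

    def conductance_onto(self) -> np.ndarray:
        """Summed conductance per postsynaptic neuron (nS)."""
        return self.g.sum(axis=1)


def step_conductances(
    group: SynapseGroup,
    presyn_spikes_delayed: np.ndarray,
    dt_ms: float,
) -> SynapseGroup:
    """Advance one projection's conductances by one step (in place).

    ``presyn_spikes_delayed`` is a boolean mask or an index array over the
    source population giving the spikes *arriving* this step (i.e. emitted
    ``delay_ms`` earlier; apply a :class:`DelayLine` upstream).
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    group.g *= 1.0 - dt_ms / group.tau_g_ms
    idx = np.asarray(presyn_spikes_delayed)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size:
        dg = group.delta_g
        if np.isscalar(dg) or np.asarray(dg).ndim == 0:
            group.g[:, idx] += group.lambda_nS * float(dg)
        else:
            group.g[:, idx] += group.lambda_nS * dg[:, idx]
    return group


@dataclass
class DelayLine:
    """Ring buffer delaying spike index arrays by a whole number of steps.

    A delay of ``d`` steps means spikes pushed at step ``t`` pop out at
    step ``t + d``.  The engine uses a minimum of one step (spikes detected
    at the end of a step are delivered at the start of the next), matching
    a conduction delay of 0 ms at the temporal resolution of the scheme.
    """

    steps: int
    _buf: deque = field(init=False)

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("delay line needs at least one step")
        empty = np.empty(0, dtype=np.int64)
        self._buf = deque([empty] * self.steps, maxlen=self.steps)

    @classmethod
    def from_delay(cls, delay_ms: float, dt_ms: float) -> "DelayLine":
        return cls(steps=max(1, int(round(delay_ms / dt_ms))))

    def push(self, spike_idx: np.ndarray) -> np.ndarray:
        """Insert this step's spikes; return the spikes arriving now."""
        out = self._buf[0]
        self._buf.append(np.asarray(spike_idx, dtype=np.int64))
        return out

    def clear(self) -> None:
        empty = np.empty(0, dtype=np.int64)
        self._buf = deque([empty] * self.steps, maxlen=self.steps)
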