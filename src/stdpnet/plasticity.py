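"""Multiplicative spike-time-dependent plasticity (STDP).

The plastic feed-forward synapses keep two exponentially decaying traces:

* ``C_j`` — recent presynaptic activity (interpretable as glutamate
  concentration in the cleft): decays with ``tau_C`` and jumps by
  ``alpha_C * (1 - C)`` at each *delayed* presynaptic spike.
* ``D_i`` — recent postsynaptic activity (proportion of unblocked NMDA
  receptors): decays with ``tau_D`` and jumps by ``alpha_D * (1 - D)`` at
  each postsynaptic spike (no conduction delay; the soma is at the
  synapse).

Weight updates are event driven and multiplicative, with learning rate
``rho = dt / tau_dg``:

* at a postsynaptic spike of neuron i:  ``dg_ij += rho * (1 - dg_ij) * C_j``   (LTP)
* at a delayed presynaptic spike of j:  ``dg_ij -= rho * dg_ij * D_i``          (LTD)

Both updates keep ``dg`` in [0, 1] by construction.  Because conduction
delays are uniform within a projection, the presynaptic trace is identical
across the synapses of one axon and is stored once per presynaptic neuron.
Within a step, trace jumps are processed before weight updates, so a
pre+post coincidence in the same dt bin uses the post-jump trace values;
LTP is applied before LTD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams",
    "PlasticityState",
    "step_traces",
    "apply_weight_updates",
    "weight_histogram",
]


@dataclass(frozen=True)
class PlasticityParams:
    """STDP constants.

    ``alpha_C``/``alpha_D`` are the fractional trace increments (0.5),
    ``tau_C``/``tau_D`` the trace time constants (defaults 15/25 ms), and
    ``rho`` the dimensionless learning rate (0.1).
    """

    alpha_C: float = 0.5
    alpha_D: float = 0.5
    tau_C_ms: float = 15.0
    tau_D_ms: float = 25.0
    rho: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_C < 1 and 0 <= self.alpha_D < 1):
            raise ValueError("alpha_C and alpha_D must lie in [0, 1) for bounded traces")
        if self.tau_C_ms <= 0 or self.tau_D_ms <= 0:
            raise ValueError("trace time constants must be positive")
        if self.rho <= 0:
            raise ValueError("learning rate rho must be positive")


@dataclass
class PlasticityState:
    """Trace state of one plastic projection.

    ``C``: presynaptic trace, shape (n_pre,) — shared across the synapses
    of each presynaptic axon (uniform conduction delay per projection).
    ``D``: postsynaptic trace, shape (n_post,).
    """

    C: np.ndarray
    D: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "PlasticityState":
        return cls(C=np.zeros(n_pre), D=np.zeros(n_post))


def _as_index(spikes: np.ndarray) -> np.ndarray:
    idx = np.asarray(spikes)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    return idx


def step_traces(
    state: PlasticityState,
    pre_spikes_delayed: np.ndarray,
    post_spikes: np.ndarray,
    params: PlasticityParams,
    dt_ms: float,
) -> PlasticityState:
    """Advance C and D by one step (in place): Euler decay, then jumps."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    state.C *= 1.0 - dt_ms / params.tau_C_ms
    state.D *= 1.0 - dt_ms / params.tau_D_ms
    pre = _as_index(pre_spikes_delayed)
    post = _as_index(post_spikes)
    if pre.size:
        state.C[pre] += params.alpha_C * (1.0 - state.C[pre])
    if post.size:
        state.D[post] += params.alpha_D * (1.0 - state.D[post])
    return state


def apply_weight_updates(
    delta_g: np.ndarray,
    state: PlasticityState,
    pre_spikes_delayed: np.ndarray,
    post_spikes: np.ndarray,
    params: PlasticityParams,
) -> np.ndarray:
    """Event-driven multiplicative weight updates (in place).

    ``delta_g`` has shape (n_post, n_pre).  Call after :func:`step_traces`
    for the same step so that updates see post-jump trace values.
    """
    pre = _as_index(pre_spikes_delayed)
    post = _as_index(post_spikes)
    rho = params.rho
    if post.size:  # LTP on the rows of spiking postsynaptic neurons
        delta_g[post, :] += rho * (1.0 - delta_g[post, :]) * state.C[np.newaxis, :]
    if pre.size:  # LTD on the columns of arriving presynaptic spikes
        delta_g[:, pre] -= rho * delta_g[:, pre] * state.D[:, np.newaxis]
    return delta_g


def weight_histogram(delta_g: np.ndarray, n_bins: int = 20):
    """Histogram of synaptic efficacies over equal-width bins on [0, 1].

    Returns ``(counts, bin_edges)``; counts sum to the number of synapses.
    """
    if n_bins < 2:
        raise ValueError("need at least two bins")
    return np.histogram(np.asarray(delta_g).ravel(), bins=n_bins, range=(0.0, 1.0))
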