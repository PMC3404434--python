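"""Preset experiment configurations.

Each preset bundles a network configuration, a stimulus set and
train/test schedules for one of the study conditions:

* CT conditions use fast feed-forward synapses (tau_EE = 2 ms, plastic cap
  4 nS) and highly overlapping transforms (13 per stimulus, 56 neurons
  wide, shifted by 12 -> 44 neurons of consecutive overlap).
* Trace conditions use slow feed-forward synapses (tau_EE = 150 ms, cap
  1.25 nS) and orthogonal transforms (10 per stimulus, 20 neurons wide,
  shifted by 20 -> no overlap), with the network allowed to settle
  between the two stimuli during training.

``scale_factor`` k builds a proportionally reduced network (n_e = 400/k,
n_i = 100/k, conductances scaled by k, stimulus geometry divided by k)
that preserves the qualitative behaviour at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import NetworkConfig
from .plasticity import PlasticityParams
from .stimuli import Schedule, StimulusSet, make_schedule, make_stimuli

__all__ = ["Preset", "preset", "PRESET_NAMES", "INHIBITION_SWEEP_NS"]

#: I->E conductance strengths explored in the inhibition sweeps (nS).
INHIBITION_SWEEP_NS = (0.5, 1.0, 1.5, 2.0, 2.5)

#: STDP time-constant pairs (tau_C, tau_D) in ms: fast / standard / slow.
STDP_FAST_MS = (3.0, 5.0)
STDP_STANDARD_MS = (15.0, 25.0)
STDP_SLOW_MS = (75.0, 125.0)

DEFAULT_EPOCHS = 5
N_STIMULI = 2

PRESET_NAMES = (
    "ct_baseline",
    "ct_stdp_fast",
    "ct_stdp_slow",
    "ct_inhibition_sweep",
    "ct_overlap_2nd",
    "ct_overlap_3rd",
    "ct_interleaved",
    "ct_randomized_interleaved",
    "trace_baseline",
    "trace_stdp_fast",
    "trace_stdp_slow",
    "trace_inhibition_sweep",
    "trace_interleaved",
    "trace_randomized",
)


@dataclass
class Preset:
    name: str
    config: NetworkConfig
    stimuli: StimulusSet
    train_schedule: Schedule
    test_schedule: Schedule
    seed: int


def _ct_stimuli(scale_factor: int, keep_every: int = 1) -> StimulusSet:
    f = scale_factor
    if 56 % f or 12 % f:
        raise ValueError("CT geometry requires a scale factor dividing 56 and 12")
    return make_stimuli(
        n_input=400 // f,
        n_stimuli=N_STIMULI,
        n_transforms=13,
        width=56 // f,
        shift=12 // f,
        keep_every=keep_every,
    )


def _trace_stimuli(scale_factor: int) -> StimulusSet:
    f = scale_factor
    if 20 % f:
        raise ValueError("trace geometry requires a scale factor dividing 20")
    return make_stimuli(
        n_input=400 // f,
        n_stimuli=N_STIMULI,
        n_transforms=10,
        width=20 // f,
        shift=20 // f,
    )


def preset(
    name: str,
    seed: int = 0,
    scale_factor: int = 1,
    epochs: int = DEFAULT_EPOCHS,
    g_IE_nS: float | None = None,
) -> Preset:
    """Build a fully specified experiment for one preset name.

    ``g_IE_nS`` overrides the I->E conductance strength (used with the
    ``*_inhibition_sweep`` presets; see ``INHIBITION_SWEEP_NS``).  The
    schedule randomness derives from ``seed`` independently of the
    network's weight/noise stream.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    regime_ct = name.startswith("ct_")
    sched_rng = np.random.default_rng([seed, 1])

    if regime_ct:
        cfg = NetworkConfig.ct(scale_factor, seed=seed)
    else:
        cfg = NetworkConfig.trace(scale_factor, seed=seed)

    tau_c, tau_d = STDP_STANDARD_MS
    if name.endswith("stdp_fast"):
        tau_c, tau_d = STDP_FAST_MS
    elif name.endswith("stdp_slow"):
        tau_c, tau_d = STDP_SLOW_MS
    if (tau_c, tau_d) != STDP_STANDARD_MS:
        cfg = replace(cfg, plasticity=PlasticityParams(tau_C_ms=tau_c, tau_D_ms=tau_d))

    if name.endswith("inhibition_sweep") and g_IE_nS is None:
        g_IE_nS = INHIBITION_SWEEP_NS[-1]  # standard strength; sweep externally
    if g_IE_nS is not None:
        cfg = cfg.with_inhibition(g_IE_nS)

    keep = {"ct_overlap_2nd": 2, "ct_overlap_3rd": 3}.get(name, 1)
    stimuli = _ct_stimuli(scale_factor, keep) if regime_ct else _trace_stimuli(scale_factor)

    regime = "sequential"
    if name.endswith("interleaved") and "randomized" not in name:
        regime = "interleaved"
    elif name == "ct_randomized_interleaved":
        regime = "randomized_interleaved"
    elif name == "trace_randomized":
        regime = "randomized"

    # Trace training settles between stimuli to sever temporal continuity
    # across stimulus boundaries — except when interleaving, whose point is
    # exactly that continuity.
    settle = (not regime_ct) and name != "trace_interleaved"

    train = make_schedule(
        stimuli,
        regime=regime,
        phase="train",
        epochs=epochs,
        rng=sched_rng,
        settle_between_stimuli=settle,
    )
    test = make_schedule(stimuli, phase="test")
    return Preset(
        name=name,
        config=cfg,
        stimuli=stimuli,
        train_schedule=train,
        test_schedule=test,
        seed=seed,
    )
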