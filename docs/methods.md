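# Methods

This note records the model as implemented, the numerical and design
choices made where more than one reasonable option existed, and what the
synthetic stimuli do and do not capture.

## Model and integration

Two layers, each with N_E = 400 excitatory and N_I = 100 inhibitory
conductance-based leaky integrate-and-fire neurons.  Within a layer the
excitatory pool and the inhibitory pool are fully reciprocally connected
(E→I, I→E) and the interneurons are fully connected to each other
(I→I); all lateral synapses are non-plastic.  The only inter-layer
projection is the fully connected, plastic feed-forward E→E pathway
(160,000 synapses at full size).  Input-layer pyramidal cells receive
external current only; inhibitory cells receive same-layer excitation
only.

All dynamics are integrated with Forward-Euler at dt = 0.02 ms.  Working
units are mV, ms, nS and pA (injected currents specified in nA).
Exponential decays use the Euler factor (1 − dt/τ), which at this dt is
within 1% of the exact exponential over the time constants used (the
test suite checks membrane, conductance and STDP-trace trajectories
against closed forms).  Threshold crossing is tested as V ≥ Θ after the
Euler update, with no sub-step interpolation; at dt = 0.02 ms the
crossing error is far below every other source of variability.

### Cellular parameters

| quantity | excitatory | inhibitory | units |
|---|---|---|---|
| C_m | 500 | 214 | pF |
| g_0 | 25 | 18 | nS |
| τ_m = C_m/g_0 | 20 | 11.89 | ms |
| V_0 | −74 | −82 | mV |
| Θ | −53 | −53 | mV |
| V_H | −57 | −58 | mV |
| V̂^E / V̂^I | 0 / −70 | 0 / −70 | mV |
| τ_R | 2 | 2 | ms |

τ_m is always computed from C_m/g_0 (the inhibitory value is 11.89 ms,
conventionally rounded to 12).  The refractory clamp lasts exactly
⌈τ_R/dt⌉ = 100 whole steps, stored as an integer count so that floating
error cannot stretch it.

### Membrane noise

The noise term is discretised Euler–Maruyama style: each step adds
σ·N(0,1)·√(dt/τ_m) mV, with σ = 0.015·(Θ − V_H) per class (0.060 mV
excitatory, 0.075 mV inhibitory).  This follows from reading ξ as the
increment of a Wiener process and keeps the stationary variance of the
free membrane proportional to σ² (property-tested).  Noise is applied to
both classes by default (each with its own σ; flags `noise_exc` /
`noise_inh` disable it per class) and is suppressed during the
refractory clamp, when V is pinned at V_H.

### Synapses and conduction delays

Per-synapse conductances decay with a projection-wide τ_g and jump by
λ·Δg_ij on each arriving spike (the discrete delta absorbs the 1/dt, so
the increment is exactly λ·Δg_ij).  Projection constants:

| projection | λ·Δg (nS) | τ_g (ms) |
|---|---|---|
| E→E feed-forward, CT | plastic, cap 4 | 2 |
| E→E feed-forward, trace | plastic, cap 1.25 | 150 |
| E→I | 5 | 2 |
| I→E | 2.5 (swept 0.5–2.5) | 5 |
| I→I | 5 | 5 |

Each projection carries its own scaling constant λ equal to its printed
conductance cap, with Δg ∈ [0, 1]; this reproduces the effective
conductance ranges exactly while keeping efficacies dimensionless.

Conduction delays are a per-projection constant, default 0 ms.  No
delay values are biologically pinned down for this circuit, so the
smallest assumption is made and the knob exposed (`delay_ms`, realised
as a spike ring buffer of ⌈delay/dt⌉ steps with a minimum of one step:
spikes detected at the end of one step act at the start of the next).

### Engine

The integrator keeps one *summed* synaptic conductance per postsynaptic
neuron and class rather than a conductance per synapse:

    G_i ← G_i·(1 − dt/τ_g) + λ·Σ_{j ∈ arrivals} Δg_ij

Because every synapse of a projection shares τ_g and its delay, this is
exactly equivalent to integrating all synapses individually and summing
— including during learning, since an increment uses Δg_ij at spike
time and later weight changes never retroactively alter conductance
already released.  A regression test runs a small network both ways
(aggregated engine vs naive per-synapse primitives) and requires
identical spike trains and matching potentials and weights.
Heterogeneous per-synapse delays would break the shared-trace argument;
the configuration therefore only accepts per-projection delays.

Update order within a step: (1) decay conductances and deliver arriving
spikes, (2) compute synaptic currents, (3) advance membranes, detect
spikes, reset and clamp, (4) STDP trace decay and jumps, then weight
updates.  This ordering is fixed by tests.

## Plasticity

Multiplicative STDP with presynaptic trace C (glutamate concentration)
and postsynaptic trace D (NMDA-receptor unblocking): C decays with τ_C
and jumps by α_C(1 − C) at each *delayed* presynaptic spike; D decays
with τ_D and jumps by α_D(1 − D) at each postsynaptic spike (no delay —
the soma is at the synapse).  α_C = α_D = 0.5; learning rate ρ = 0.1
(the instantaneous-update reading of dt/τ_Δg).  Defaults
τ_C/τ_D = 15/25 ms; the temporal-specificity experiments scale the pair
by 5 in both directions (3/5 and 75/125 ms).

Because delays are uniform within the projection, C_ij is identical for
every synapse of axon j and is stored once per presynaptic neuron.

Within a step, trace jumps are processed before weight updates, so a
pre+post coincidence in the same dt bin uses post-jump trace values; LTP
(row updates at postsynaptic spikes) is applied before LTD (column
updates at arriving presynaptic spikes).  Both updates are multiplicative
in the distance to the bound, so Δg can never leave [0, 1] regardless of
the spike train (property-tested), and a single pre→post pairing
potentiates while post→pre depresses, with magnitude decaying
exponentially in the lag.

Initial efficacies are Δg ~ Uniform(0, 1), drawn per synapse from the
seeded generator.

## Stimuli, schedules and resets

A stimulus is a contiguous block of `width` input neurons driven by a
constant 1 nA somatic current for the whole cue period (100 ms during
training, 250 ms during testing); successive transforms shift the block
by `shift` neurons inside the stimulus's private partition of the input
layer.  Consecutive overlap is therefore max(0, width − shift·k) when
every k-th transform is kept.  Geometries used: CT 13 × 56/12 (overlap
44; subsampled variants 7 × overlap 32 and 5 × overlap 20) and trace
10 × 20/20 (orthogonal).

Training regimes: `sequential` (random stimulus order each epoch,
transforms in order within a stimulus), `interleaved` (strict
alternation S1ᵗ¹, S2ᵗ¹, S1ᵗ², …), `randomized` (shuffled transform order
within each stimulus block) and `randomized_interleaved`.  Five epochs
by default.  The test phase presents every transform of every stimulus
in order for 250 ms with a reset before each presentation.

A reset ("allowing the network to settle") is implemented as an
instantaneous return to rest: V = V_0, all synaptic conductances, STDP
traces, refractory counters and in-flight spikes cleared; learned
efficacies untouched.  CT training uses no resets (continuity across
presentations is the point).  Trace training resets at stimulus-block
boundaries (`settle_between_stimuli`) so that the temporal trace cannot
associate the two stimuli — except in the trace-interleaving experiment,
whose purpose is precisely to let it.

## Information measures

Firing rates are spike counts per 250 ms test window.  Single-cell
stimulus-specific information I(s, R) = Σ_r P(r|s) log₂[P(r|s)/P(r)] is
computed per cell after discretising its rates into equal-width bins
spanning [0, max rate]; the bin count defaults to the number of
transforms per stimulus, tying response resolution to the trial count.
Stimuli are equiprobable and each transform is one equiprobable trial.
The reported value is the maximum over stimuli; a flat responder carries
0 bits by construction.

The multiple-cell measure decodes each presentation from an ensemble of
the best cells (up to five per stimulus ranked by per-stimulus
single-cell information, ≤ 10 total).  For a held-out presentation the
likelihood P(r_c|s′) of each cell's rate is a Gaussian fitted to that
cell's responses to the other transforms of s′ (leave-one-transform-out
for the true stimulus; standard deviations floored at 10⁻³ of the
table's peak rate so constant responders stay finite).  Log-likelihoods
are summed over cells, combined with a uniform prior and the argmax
(ties broken uniformly at random, seeded) fills a hard confusion table
P(s, s′), accumulated over 100 random ensemble samplings per ensemble
size; I(s, s′) is the mutual information of that table, reported against
ensemble size 1…10.  A soft variant (``soft=True``) accumulates the full
posterior instead of the argmax; the hard decoder is the default and the
reported measure.  Exhaustive-enumeration oracles for both measures
are part of the test suite.

A note on decoding nulls: the measure is only a chance-level (plus
limited-sampling bias) when responses are genuinely independent of the
stimulus; response patterns that are *correlated across stimuli per
transform* can be decoded above chance even without stimulus-selective
mean rates.

"Responsive" output rates (the ~50 vs ~200 spikes/s contrast between the
CT and trace regimes) are summarised as the mean over (cell, window)
entries at or above 20% of the table's peak rate — i.e. the typical rate
of a responding cell during its preferred presentations, excluding
silent cells and non-preferred windows.

Synchronised volleys are counted by clustering the stimulated
population's spike times greedily (a gap > 3 ms opens a new cluster) and
keeping clusters that involve at least half the population; the volley
rate is clusters per second of cue.

## Reduced-scale study conditions

Full-size runs (400+100 per layer) are used for the headline quantities
in `scripts/acceptance.py`.  The mechanism-dissociation grid in the test
suite uses quarter-size networks (N_E = 100, N_I = 25) with every
synaptic conductance scaled ×4, so each neuron receives the same total
drive; the stimulus geometry divides by 4 (CT 13 × 14/3, trace 10 × 5/5)
and training runs for 3 epochs.  Orderings (STDP time-constant
preference and its reversal between regimes, inhibition dependence,
interleaving tolerance/collapse, overlap dependence) are asserted on the
median over three seeds.  These reduced conditions preserve the
qualitative phenomena — volley pacing, the ~50 vs ~200 spikes/s rate
regimes, and all orderings — but absolute information values are noisier
than at full size (fewer cells and, for trace, only 5 neurons per
transform), which is why the grid asserts orderings rather than levels.

## What the synthetic stimuli do not capture

The translating blocks are idealised: binary, non-overlapping between
stimuli, constant-amplitude, and confined to disjoint partitions of a
1-D layer.  They isolate each learning mechanism cleanly — spatial
overlap can be removed exactly, temporal continuity can be severed
exactly — but they lack the distributed, graded, correlated structure of
natural images, multi-object scenes, and transforms other than
translation (rotation, scale, occlusion).  Passing tests therefore
demonstrate the mechanisms' operation and dissociation in this
controlled setting, not performance on natural stimuli.  Other known
limitations: single plastic layer (no hierarchy), no lateral excitation,
no firing-rate adaptation, and trace-regime output rates (~200 spikes/s)
at the edge of biological plausibility.
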