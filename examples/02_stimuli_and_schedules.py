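"""Translating-block stimuli and the training/testing schedules.

Shows how transform overlap is controlled by the block geometry and how
the presentation regimes order the same multiset of presentations.
"""

import numpy as np

from stdpnet import make_schedule, make_stimuli

# Two stimuli on a 400-neuron input layer; 13 transforms of 56 neurons
# shifted by 12 -> 44 neurons shared by consecutive transforms.
ct = make_stimuli(n_input=400, n_stimuli=2, n_transforms=13, width=56, shift=12)
print(f"CT geometry: {ct.n_transforms} transforms/stimulus, overlap {ct.consecutive_overlap}")
for keep in (2, 3):
    sub = make_stimuli(400, 2, 13, 56, 12, keep_every=keep)
    print(f"  keep every {keep}th -> {sub.n_transforms} transforms, overlap {sub.consecutive_overlap}")

# Orthogonal trace geometry: 10 transforms of 20 neurons, shifted by 20.
tr = make_stimuli(400, 2, 10, 20, 20)
print(f"trace geometry: {tr.n_transforms} transforms/stimulus, overlap {tr.consecutive_overlap}")

rng = np.random.default_rng(0)
seq = make_schedule(ct, "sequential", epochs=1, rng=rng)
inter = make_schedule(tr, "interleaved", epochs=1, rng=rng)
print("\nsequential first 6 events (stimulus, transform):",
      [(e.stimulus, e.transform) for e in list(seq)[:6]])
print("interleaved first 6 events:",
      [(e.stimulus, e.transform) for e in list(inter)[:6]])
# Sequential training presents each stimulus's transforms in succession;
# interleaving alternates the stimuli transform by transform, severing
# within-stimulus temporal continuity while preserving spatial overlap.

test = make_schedule(ct, phase="test")
print(f"\ntest phase: {len(test)} presentations of {test.events[0].duration_ms:.0f} ms, "
      f"all with reset_before={test.events[0].reset_before}")
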