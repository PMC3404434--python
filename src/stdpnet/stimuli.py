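"""Translating-block stimuli and presentation schedules.

A stimulus is modelled as a contiguous block of input-layer neurons driven
by direct current injection; successive *transforms* of the stimulus shift
the block across the layer, emulating a translating object.  The input
layer is divided into as many equal partitions as there are stimuli and
every transform of a stimulus stays inside its partition, so the degree of
spatial overlap between consecutive transforms is controlled exactly:

    overlap = max(0, width - shift * keep_every)

``keep_every`` subsamples the transform sequence (keeping every 2nd or 3rd
transform) which lowers the consecutive overlap while spanning the same
part of the layer.

Schedules list presentation events (stimulus, transform, duration, cue
amplitude, reset flag).  Training presents each stimulus's transforms in
succession (``sequential``), strictly alternating between stimuli
(``interleaved``), in shuffled order (``randomized``), or both
(``randomized_interleaved``).  Testing presents every transform of every
stimulus in order with a reset before each presentation so that responses
are independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "PresentationEvent",
    "Schedule",
    "make_stimuli",
    "make_schedule",
    "TRAIN_CUE_MS",
    "TEST_CUE_MS",
    "CUE_CURRENT_NA",
    "REGIMES",
]

TRAIN_CUE_MS = 100.0
TEST_CUE_MS = 250.0
CUE_CURRENT_NA = 1.0

REGIMES = ("sequential", "interleaved", "randomized", "randomized_interleaved")


@dataclass(frozen=True)
class StimulusSet:
    """Transforms of each stimulus as index sets into the input layer."""

    n_input: int
    transforms: tuple  # transforms[s][t] -> np.ndarray of neuron indices
    width: int
    shift: int
    keep_every: int = 1

    @property
    def n_stimuli(self) -> int:
        return len(self.transforms)

    @property
    def n_transforms(self) -> int:
        return len(self.transforms[0])

    @property
    def consecutive_overlap(self) -> int:
        """Neurons shared by consecutive transforms of one stimulus."""
        return max(0, self.width - self.shift * self.keep_every)

    def indices(self, stimulus: int, transform: int) -> np.ndarray:
        return self.transforms[stimulus][transform]


def make_stimuli(
    n_input: int,
    n_stimuli: int,
    n_transforms: int,
    width: int,
    shift: int,
    keep_every: int = 1,
) -> StimulusSet:
    """Build a deterministic translating-block stimulus set.

    ``n_transforms`` is the number of transforms *before* subsampling;
    ``keep_every=k`` keeps transforms 0, k, 2k, ...  Raises ``ValueError``
    if the geometry does not fit each stimulus's partition of the layer.
    """
    if n_stimuli < 1 or n_transforms < 1 or width < 1 or shift < 0 or keep_every < 1:
        raise ValueError("invalid stimulus geometry")
    if n_input % n_stimuli:
        raise ValueError(f"{n_input} input neurons not divisible into {n_stimuli} partitions")
    part = n_input // n_stimuli
    span = width + (n_transforms - 1) * shift
    if span > part:
        raise ValueError(
            f"transforms span {span} neurons but each stimulus partition has only {part}"
        )
    stim = []
    for s in range(n_stimuli):
        base = s * part
        kept = []
        for t in range(0, n_transforms, keep_every):
            start = base + t * shift
            kept.append(np.arange(start, start + width, dtype=np.int64))
        stim.append(tuple(kept))
    return StimulusSet(
        n_input=n_input,
        transforms=tuple(stim),
        width=width,
        shift=shift,
        keep_every=keep_every,
    )


@dataclass(frozen=True)
class PresentationEvent:
    stimulus: int
    transform: int
    duration_ms: float
    amplitude_nA: float = CUE_CURRENT_NA
    reset_before: bool = False

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("presentation duration must be positive")


@dataclass
class Schedule:
    """An ordered list of presentation events plus bookkeeping."""

    events: list
    phase: str  # "train" | "test"
    stimulus_set: StimulusSet = None  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def total_duration_ms(self) -> float:
        return float(sum(ev.duration_ms for ev in self.events))

    def event_starts_ms(self) -> np.ndarray:
        durs = np.array([ev.duration_ms for ev in self.events])
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    def to_frame(self) -> pd.DataFrame:
        starts = self.event_starts_ms()
        return pd.DataFrame(
            {
                "event_index": np.arange(len(self.events)),
                "stimulus": [ev.stimulus for ev in self.events],
                "transform": [ev.transform for ev in self.events],
                "t_start_ms": starts,
                "duration_ms": [ev.duration_ms for ev in self.events],
                "amplitude_nA": [ev.amplitude_nA for ev in self.events],
                "reset_before": [ev.reset_before for ev in self.events],
            }
        )

    def save_text(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _epoch_orders(
    stimset: StimulusSet,
    regime: str,
    rng: np.random.Generator,
) -> list:
    """(stimulus, transform) order for one training epoch."""
    n_s, n_t = stimset.n_stimuli, stimset.n_transforms
    orders = []
    for s in range(n_s):
        t_order = np.arange(n_t)
        if regime in ("randomized", "randomized_interleaved"):
            rng.shuffle(t_order)
        orders.append(t_order)
    if regime in ("interleaved", "randomized_interleaved"):
        # S1^t1, S2^t1, S1^t2, S2^t2, ... : round-robin over stimuli per rank
        return [(s, int(orders[s][k])) for k in range(n_t) for s in range(n_s)]
    # sequential / randomized: random stimulus order, blocks of transforms
    s_order = rng.permutation(n_s)
    return [(int(s), int(orders[s][k])) for s in s_order for k in range(n_t)]


def make_schedule(
    stimset: StimulusSet,
    regime: str = "sequential",
    phase: str = "train",
    epochs: int = 1,
    rng: np.random.Generator | None = None,
    duration_ms: float | None = None,
    amplitude_nA: float = CUE_CURRENT_NA,
    settle_between_stimuli: bool = False,
) -> Schedule:
    """Build a presentation schedule.

    Training epochs present every (stimulus, transform) pair exactly once
    according to ``regime``; ``settle_between_stimuli`` inserts a reset at
    each change of stimulus (used in trace-learning runs to sever temporal
    continuity between different stimuli).  The test phase ignores
    ``regime``: all transforms of all stimuli in order, 250 ms each, with
    a reset before every presentation.
    """
    if phase == "test":
        dur = TEST_CUE_MS if duration_ms is None else duration_ms
        events = [
            PresentationEvent(s, t, dur, amplitude_nA, reset_before=True)
            for s in range(stimset.n_stimuli)
            for t in range(stimset.n_transforms)
        ]
        return Schedule(events=events, phase="test", stimulus_set=stimset)
    if phase != "train":
        raise ValueError(f"unknown phase {phase!r}")
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    dur = TRAIN_CUE_MS if duration_ms is None else duration_ms
    events: list = []
    prev_stim: int | None = None
    for _ in range(epochs):
        for s, t in _epoch_orders(stimset, regime, rng):
            reset = settle_between_stimuli and s != prev_stim
            events.append(PresentationEvent(s, t, dur, amplitude_nA, reset_before=reset))
            prev_stim = s
    return Schedule(events=events, phase="train", stimulus_set=stimset)
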