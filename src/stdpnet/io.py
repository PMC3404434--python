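"""Delimited-text exports for audit and re-analysis.

Spike records, schedules and rate tables carry their own ``save_text``
methods; this module adds the remaining text formats: stimulus sets as
index-list files and weight histograms as (bin_left, bin_right, count)
tables.  Binary state snapshots live on :class:`stdpnet.Network`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .plasticity import weight_histogram
from .stimuli import StimulusSet

__all__ = [
    "save_stimulus_set",
    "load_stimulus_set",
    "save_weight_histogram",
    "load_weight_histogram",
]


def save_stimulus_set(stimset: StimulusSet, path) -> None:
    """One line per transform: ``stimulus transform i1,i2,...`` plus a
    header recording the geometry."""
    with open(path, "w") as fh:
        fh.write(
            f"# n_input={stimset.n_input} width={stimset.width} "
            f"shift={stimset.shift} keep_every={stimset.keep_every}\n"
        )
        fh.write("stimulus\ttransform\tindices\n")
        for s in range(stimset.n_stimuli):
            for t in range(stimset.n_transforms):
                idx = ",".join(map(str, stimset.indices(s, t)))
                fh.write(f"{s}\t{t}\t{idx}\n")


def load_stimulus_set(path) -> StimulusSet:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        fh.readline()  # column names
        stim: dict[int, dict[int, np.ndarray]] = {}
        for line in fh:
            s, t, idx = line.rstrip("\n").split("\t")
            stim.setdefault(int(s), {})[int(t)] = np.array(
                [int(x) for x in idx.split(",")], dtype=np.int64
            )
    transforms = tuple(
        tuple(stim[s][t] for t in sorted(stim[s])) for s in sorted(stim)
    )
    return StimulusSet(
        n_input=int(meta["n_input"]),
        transforms=transforms,
        width=int(meta["width"]),
        shift=int(meta["shift"]),
        keep_every=int(meta["keep_every"]),
    )


def save_weight_histogram(delta_g: np.ndarray, path, n_bins: int = 20) -> None:
    counts, edges = weight_histogram(delta_g, n_bins)
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(path, sep="\t", index=False)


def load_weight_histogram(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
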