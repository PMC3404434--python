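"""Matplotlib figures: rasters, information curves, weight histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .info import InfoResult
from .network import OUTPUT_EXC, POPULATIONS, SpikeRecord
from .plasticity import weight_histogram

__all__ = ["raster", "info_curves", "weight_distribution"]


def raster(record: SpikeRecord, pop: int = OUTPUT_EXC, ax=None, **scatter_kw):
    """Spike raster of one population (time vs neuron index)."""
    sel = record.select(pop=pop)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    scatter_kw.setdefault("s", 1)
    scatter_kw.setdefault("color", "k")
    ax.scatter(sel.t_ms, sel.neuron, marker="|", **scatter_kw)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    ax.set_title(f"{POPULATIONS[pop]} raster")
    return ax


def info_curves(info: InfoResult, axes=None):
    """Single-cell information vs cell rank and multiple-cell information
    vs ensemble size (both in bits)."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ranked = np.sort(info.single_cell)[::-1]
    axes[0].plot(np.arange(1, len(ranked) + 1), ranked)
    axes[0].set_xlabel("cell rank")
    axes[0].set_ylabel("single-cell information (bits)")
    axes[1].plot(info.ensemble_sizes, info.multi_cell, marker="o")
    axes[1].set_xlabel("ensemble size")
    axes[1].set_ylabel("multiple-cell information (bits)")
    for ax in axes:
        ax.set_ylim(bottom=0)
    return axes


def weight_distribution(delta_g: np.ndarray, n_bins: int = 20, ax=None, **bar_kw):
    """Histogram of plastic synaptic efficacies on [0, 1]."""
    counts, edges = weight_histogram(delta_g, n_bins)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", **bar_kw)
    ax.set_xlabel(r"synaptic efficacy $\Delta g$")
    ax.set_ylabel("synapses")
    return ax
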