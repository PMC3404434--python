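"""Firing-rate extraction and information-theoretic performance measures.

Two measures quantify how well the output layer has learned
transformation-invariant, stimulus-specific representations from the
firing rates recorded during testing (250 ms windows, one per transform
of each stimulus, network reset between presentations):

* **Single-cell stimulus-specific information**

      I(s, R) = sum_r P(r|s) log2[ P(r|s) / P(r) ]

  computed per cell from its discretised rate responses, with the
  transforms of each stimulus as equiprobable trials; the reported value
  is the maximum over stimuli.  A cell that responds in one rate bin to
  every transform of one stimulus and in another bin to everything else
  carries log2(N_S) bits.

* **Multiple-cell information** through Bayesian decoding: an ensemble of
  the highest-information cells (up to five per stimulus) is used to
  decode the stimulus of each held-out presentation from Gaussian
  likelihoods fitted to the remaining transforms, accumulating a
  confusion table P(s, s') whose mutual information

      I(s, s') = sum_{s,s'} P(s,s') log2[ P(s,s') / (P(s) P(s')) ]

  is reported as a function of ensemble size (ceiling log2 N_S).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import OUTPUT_EXC, SpikeRecord
from .stimuli import Schedule

__all__ = [
    "RateTable",
    "InfoResult",
    "rates_from_spikes",
    "single_cell_info",
    "multi_cell_info",
    "count_volleys",
    "mean_responsive_rate",
]


@dataclass
class RateTable:
    """Firing rate (spikes/s) per (cell, stimulus, transform)."""

    rates: np.ndarray  # shape (n_cells, n_stimuli, n_transforms)

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[1]

    @property
    def n_transforms(self) -> int:
        return self.rates.shape[2]

    def to_frame(self) -> pd.DataFrame:
        cells, stims, trans = np.indices(self.rates.shape)
        return pd.DataFrame(
            {
                "cell": cells.ravel(),
                "stimulus": stims.ravel(),
                "transform": trans.ravel(),
                "rate_hz": self.rates.ravel(),
            }
        )

    def save_text(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class InfoResult:
    """Single- and multiple-cell information values (bits)."""

    single_cell: np.ndarray  # (n_cells,) max-over-stimuli information
    single_cell_per_stimulus: np.ndarray  # (n_cells, n_stimuli)
    ensemble: np.ndarray  # cell indices of the decoding pool
    ensemble_sizes: np.ndarray  # (k,)
    multi_cell: np.ndarray  # (k,) information vs ensemble size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ensemble_size": self.ensemble_sizes, "info_bits": self.multi_cell}
        )


def rates_from_spikes(
    record: SpikeRecord,
    schedule: Schedule,
    pop: int = OUTPUT_EXC,
    n_cells: int | None = None,
) -> RateTable:
    """Bin test-phase spikes into rates per (cell, stimulus, transform).

    Requires a complete test grid: every (stimulus, transform) pair must
    appear exactly once in the schedule.
    """
    stimset = schedule.stimulus_set
    n_s, n_t = stimset.n_stimuli, stimset.n_transforms
    if n_cells is None:
        n_cells = int(record.neuron[record.pop == pop].max()) + 1 if len(record) else 0
        n_cells = max(n_cells, stimset.n_input)
    seen = np.zeros((n_s, n_t), dtype=int)
    event_of = {}
    for ev_id, ev in enumerate(schedule):
        seen[ev.stimulus, ev.transform] += 1
        event_of[ev_id] = (ev.stimulus, ev.transform, ev.duration_ms)
    if not np.all(seen == 1):
        raise ValueError("incomplete test grid: every (stimulus, transform) pair "
                         "must be presented exactly once")
    rates = np.zeros((n_cells, n_s, n_t))
    mask = record.pop == pop
    neurons = record.neuron[mask]
    events = record.event[mask]
    for ev_id, (s, t, dur) in event_of.items():
        counts = np.bincount(neurons[events == ev_id], minlength=n_cells)
        rates[:, s, t] = counts * (1000.0 / dur)
    return RateTable(rates=rates)


def _discretize(rates: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bins on [0, max rate]; a flat table maps to bin 0."""
    top = rates.max()
    if top <= 0:
        return np.zeros_like(rates, dtype=np.int64)
    codes = np.floor(rates / top * n_bins).astype(np.int64)
    return np.minimum(codes, n_bins - 1)


def single_cell_info(
    table: RateTable, n_rate_bins: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-specific information per output cell (bits).

    Returns ``(max_info, per_stimulus)`` where ``max_info[c] =
    max_s I(s, R)`` and ``per_stimulus[c, s] = I(s, R)`` for cell ``c``.
    Rates are discretised into ``n_rate_bins`` equal-width bins (default:
    the number of transforms per stimulus) *per cell*; stimuli are
    equiprobable and the transforms are the equiprobable trials within
    each stimulus.  A cell with a single response value carries 0 bits.
    """
    if n_rate_bins is None:
        n_rate_bins = table.n_transforms
    if n_rate_bins < 2:
        raise ValueError("need at least two rate bins")
    n_c, n_s, n_t = table.rates.shape
    per_stim = np.zeros((n_c, n_s))
    for cell in range(n_c):
        codes = _discretize(table.rates[cell], n_rate_bins)  # (n_s, n_t)
        # P(r|s): histogram of bins within each stimulus
        p_r_s = np.zeros((n_s, n_rate_bins))
        for s in range(n_s):
            p_r_s[s] = np.bincount(codes[s], minlength=n_rate_bins) / n_t
        p_r = p_r_s.mean(axis=0)  # equiprobable stimuli
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_r_s > 0, p_r_s / p_r, 1.0)
            per_stim[cell] = np.sum(
                np.where(p_r_s > 0, p_r_s * np.log2(ratio), 0.0), axis=1
            )
    return per_stim.max(axis=1), per_stim


def _loo_gaussian_params(
    rates: np.ndarray, var_floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-transform-out Gaussian fits.

    Returns ``mu, sd`` of shape (n_cells, n_s_decoded, n_s_true, n_t_held):
    the fit for hypothesis stimulus ``s'`` when presentation (s, t) is
    held out — the held-out transform is excluded from its own stimulus's
    fit, other stimuli use all transforms.
    """
    n_c, n_s, n_t = rates.shape
    mu_all = rates.mean(axis=2)  # (n_c, n_s)
    sd_all = rates.std(axis=2)
    # leave-one-out moments within each stimulus
    sum_all = rates.sum(axis=2, keepdims=True)
    sumsq_all = (rates**2).sum(axis=2, keepdims=True)
    mu_loo = (sum_all - rates) / (n_t - 1)  # (n_c, n_s, n_t)
    var_loo = (sumsq_all - rates**2) / (n_t - 1) - mu_loo**2
    sd_loo = np.sqrt(np.maximum(var_loo, 0.0))

    mu = np.broadcast_to(
        mu_all[:, :, None, None], (n_c, n_s, n_s, n_t)
    ).copy()  # [c, s', s, t]
    sd = np.broadcast_to(sd_all[:, :, None, None], (n_c, n_s, n_s, n_t)).copy()
    diag = np.arange(n_s)
    mu[:, diag, diag, :] = mu_loo
    sd[:, diag, diag, :] = sd_loo
    return mu, np.maximum(sd, var_floor)


def multi_cell_info(
    table: RateTable,
    ensemble_max: int = 10,
    top_per_stimulus: int = 5,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
    n_rate_bins: int | None = None,
    var_floor_frac: float = 1e-3,
    soft: bool = False,
) -> InfoResult:
    """Multiple-cell information via Gaussian-Bayesian decoding.

    The decoding pool holds the ``top_per_stimulus`` cells with the most
    single-cell information about each stimulus (<= ``ensemble_max``
    total).  For each ensemble size k, ``n_iterations`` random k-subsets
    of the pool decode every presentation (leave-one-transform-out fits,
    uniform prior, hard argmax with seeded uniform tie-breaks); the
    accumulated confusion table yields the mutual information.  With
    ``soft=True`` the full posterior P(s'|r) is accumulated into the
    confusion table instead of the argmax prediction.
    """
    if table.n_transforms < 2:
        raise ValueError("decoding needs at least two transforms per stimulus")
    if rng is None:
        rng = np.random.default_rng()
    max_info, per_stim = single_cell_info(table, n_rate_bins)
    n_c, n_s, n_t = table.rates.shape

    pool: list[int] = []
    for s in range(n_s):
        order = np.argsort(per_stim[:, s], kind="stable")[::-1]
        for cell in order[:top_per_stimulus]:
            if cell not in pool:
                pool.append(int(cell))
    pool_arr = np.array(sorted(pool, key=lambda cix: -max_info[cix]), dtype=np.int64)
    pool_arr = pool_arr[:ensemble_max]

    floor = var_floor_frac * max(table.rates.max(), 1e-12)
    mu, sd = _loo_gaussian_params(table.rates[pool_arr], floor)
    rates = table.rates[pool_arr]  # (n_pool, n_s, n_t)
    # log N(r_c; mu, sd) per (pool cell, s', s, t) for presentation (s, t)
    r = rates[:, None, :, :]  # observed rate of cell c at presentation (s, t)
    loglik_c = -0.5 * ((r - mu) / sd) ** 2 - np.log(sd)  # (n_pool, n_s', n_s, n_t)

    sizes = np.arange(1, min(ensemble_max, len(pool_arr)) + 1)
    multi = np.zeros(len(sizes))
    for k_i, k in enumerate(sizes):
        conf = np.zeros((n_s, n_s))
        for _ in range(n_iterations):
            chosen = rng.choice(len(pool_arr), size=k, replace=False)
            ll = loglik_c[chosen].sum(axis=0)  # (n_s', n_s, n_t)
            if soft:
                post = np.exp(ll - ll.max(axis=0, keepdims=True))
                post /= post.sum(axis=0, keepdims=True)
                conf += post.sum(axis=2).T  # accumulate P(s'|r) per true s
            else:
                for s in range(n_s):
                    for t in range(n_t):
                        col = ll[:, s, t]
                        best = np.flatnonzero(col == col.max())
                        pred = best[0] if len(best) == 1 else rng.choice(best)
                        conf[s, pred] += 1.0
        p = conf / conf.sum()
        ps = p.sum(axis=1, keepdims=True)
        psp = p.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / (ps * psp)), 0.0)
        multi[k_i] = terms.sum()
    return InfoResult(
        single_cell=max_info,
        single_cell_per_stimulus=per_stim,
        ensemble=pool_arr,
        ensemble_sizes=sizes,
        multi_cell=multi,
    )


def count_volleys(
    record: SpikeRecord,
    neuron_ids: np.ndarray,
    pop: int = 0,
    t_window_ms: tuple[float, float] | None = None,
    max_gap_ms: float = 3.0,
    min_fraction: float = 0.5,
) -> int:
    """Count synchronised spike volleys of a stimulated population.

    Spikes of the given neurons are clustered greedily in time (a gap of
    more than ``max_gap_ms`` starts a new cluster); a cluster counts as a
    volley when it involves at least ``min_fraction`` of the population.
    """
    ids = np.asarray(neuron_ids)
    mask = (record.pop == pop) & np.isin(record.neuron, ids)
    t = record.t_ms[mask]
    n = record.neuron[mask]
    if t_window_ms is not None:
        w = (t >= t_window_ms[0]) & (t < t_window_ms[1])
        t, n = t[w], n[w]
    if t.size == 0:
        return 0
    order = np.argsort(t, kind="stable")
    t, n = t[order], n[order]
    volleys = 0
    start = 0
    for i in range(1, len(t) + 1):
        if i == len(t) or t[i] - t[i - 1] > max_gap_ms:
            if len(np.unique(n[start:i])) >= min_fraction * len(ids):
                volleys += 1
            start = i
    return volleys


def mean_responsive_rate(table: RateTable, threshold_frac: float = 0.2) -> float:
    """Mean firing rate over strongly responsive (cell, presentation)
    entries — those at or above ``threshold_frac`` of the table's peak
    rate.  Approximates the typical rate of responding output cells,
    excluding silent cells and the windows in which a selective cell's
    non-preferred stimulus was shown."""
    r = table.rates
    top = r.max()
    if top <= 0:
        return 0.0
    active = r >= threshold_frac * top
    return float(r[active].mean())
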