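"""End-to-end experiment driver: build, train, test, analyse."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .info import InfoResult, RateTable, multi_cell_info, rates_from_spikes
from .network import POPULATIONS, Network, SpikeRecord
from .plasticity import weight_histogram
from .presets import Preset
from .stimuli import Schedule

__all__ = ["ExperimentResult", "run_experiment"]

logger = logging.getLogger("stdpnet")


@dataclass
class ExperimentResult:
    """Everything one training-and-testing run produces."""

    preset: Preset
    network: Network
    weights_before: np.ndarray
    weights_after: np.ndarray
    train_record: SpikeRecord | None
    test_record: SpikeRecord
    rate_table: RateTable
    info: InfoResult

    @property
    def max_single_cell_bits(self) -> float:
        return float(self.info.single_cell.max())

    @property
    def max_multi_cell_bits(self) -> float:
        return float(self.info.multi_cell.max())

    def top_single_cell_mean(self, n: int = 10) -> float:
        """Mean information of the n most informative cells (bits)."""
        top = np.sort(self.info.single_cell)[::-1][:n]
        return float(top.mean())

    def summary(self) -> dict:
        return {
            "preset": self.preset.name,
            "seed": self.preset.seed,
            "max_single_cell_bits": self.max_single_cell_bits,
            "top10_single_cell_mean_bits": self.top_single_cell_mean(10),
            "max_multi_cell_bits": self.max_multi_cell_bits,
            "n_train_events": len(self.preset.train_schedule),
            "n_test_events": len(self.preset.test_schedule),
        }


def _train_with_epoch_logging(net: Network, p: Preset) -> None:
    """Run training epoch by epoch, logging mean population rates and the
    weight-histogram quartile mass (enable via the ``stdpnet`` logger)."""
    stimset = p.stimuli
    per_epoch = stimset.n_stimuli * stimset.n_transforms
    events = p.train_schedule.events
    logger.info("training %s: seed=%d, %d epochs of %d presentations",
                p.name, p.seed, len(events) // per_epoch, per_epoch)
    for e0 in range(0, len(events), per_epoch):
        chunk = Schedule(events=events[e0 : e0 + per_epoch], phase="train",
                         stimulus_set=stimset)
        rec = net.run(chunk, learning_on=True, record=True)
        dur_s = chunk.total_duration_ms / 1000.0
        rates = [
            (rec.pop == p_i).sum() / (net.sizes[p_i] * dur_s) for p_i in range(4)
        ]
        counts, _ = weight_histogram(net.delta_g, 4)
        quartiles = counts / counts.sum()
        logger.info(
            "epoch %d: mean rates %s Hz; weight quartile mass %s",
            e0 // per_epoch + 1,
            ", ".join(f"{POPULATIONS[i]}={rates[i]:.1f}" for i in range(4)),
            np.round(quartiles, 3).tolist(),
        )


def run_experiment(
    p: Preset,
    learning: bool = True,
    record_training: bool = False,
    n_iterations: int = 100,
    n_rate_bins: int | None = None,
) -> ExperimentResult:
    """Train a network on a preset, test it and compute both information
    measures.

    With ``learning=False`` the training phase is skipped entirely, giving
    the untrained (random-weight) reference.  The analysis uses its own
    random stream derived from the preset seed, so results are
    reproducible end to end.
    """
    net = Network(p.config)
    w0 = net.delta_g.copy()
    train_rec = None
    if learning:
        if logger.isEnabledFor(logging.INFO):
            _train_with_epoch_logging(net, p)
        else:
            train_rec = net.run(p.train_schedule, learning_on=True,
                                record=record_training)
            if not record_training:
                train_rec = None
    test_rec = net.run(p.test_schedule, learning_on=False, record=True)
    table = rates_from_spikes(test_rec, p.test_schedule, n_cells=p.config.n_e)
    info = multi_cell_info(
        table,
        n_iterations=n_iterations,
        rng=np.random.default_rng([p.seed, 2]),
        n_rate_bins=n_rate_bins,
    )
    return ExperimentResult(
        preset=p,
        network=net,
        weights_before=w0,
        weights_after=net.delta_g.copy(),
        train_record=train_rec,
        test_record=test_rec,
        rate_table=table,
        info=info,
    )
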