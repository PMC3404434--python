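"""Network assembly, the optimised engine, determinism and persistence.

The engine maintains one summed synaptic conductance per postsynaptic
neuron instead of a conductance per synapse; the central test here checks
that this aggregation reproduces the naive per-synapse simulation built
from the module-level primitives, spike for spike.
"""

import numpy as np
import pytest

from stdpnet import (
    INPUT_EXC,
    INPUT_INH,
    OUTPUT_EXC,
    OUTPUT_INH,
    LayerState,
    Network,
    NetworkConfig,
    PlasticityState,
    PresentationEvent,
    Schedule,
    SpikeRecord,
    SynapseGroup,
    apply_weight_updates,
    make_stimuli,
    preset,
    step_conductances,
    step_membrane,
    step_traces,
    synaptic_current,
)


def tiny_setup(seed=0, tau_ee=2.0, amplitude=1.0, n_events=4, reset_some=False):
    """A 10+3-neuron-per-layer network with scaled conductances."""
    cfg = NetworkConfig(
        n_e=10, n_i=3, conductance_scale=40.0,
        noise_exc=False, noise_inh=False, seed=seed,
    )
    if tau_ee != 2.0:
        from dataclasses import replace
        cfg = replace(cfg, ff=replace(cfg.ff, tau_g_ms=tau_ee))
    stims = make_stimuli(10, 2, 3, 3, 1)
    events = []
    for i in range(n_events):
        events.append(
            PresentationEvent(
                stimulus=i % 2, transform=i % 3, duration_ms=30.0,
                amplitude_nA=amplitude, reset_before=reset_some and i == 2,
            )
        )
    sched = Schedule(events=events, phase="train", stimulus_set=stims)
    return cfg, stims, sched


class ReferenceNetwork:
    """Naive per-synapse simulation assembled from the module primitives.

    Mirrors the engine's update order: conductance decay + delayed
    deliveries, synaptic currents, membrane update, STDP trace jumps then
    weight updates.  All conduction delays are one step (0 ms)."""

    def __init__(self, cfg, delta_g0):
        self.cfg = cfg
        n_e, n_i, s = cfg.n_e, cfg.n_i, cfg.conductance_scale
        e, i = cfg.exc, cfg.inh
        self.layers = {
            "ine": LayerState.at_rest(n_e, e),
            "ini": LayerState.at_rest(n_i, i),
            "oute": LayerState.at_rest(n_e, e),
            "outi": LayerState.at_rest(n_i, i),
        }

        def grp(n_post, n_pre, pc, dg, vhat):
            return SynapseGroup(
                source_class="x", target_class="y",
                g=np.zeros((n_post, n_pre)), delta_g=dg,
                lambda_nS=pc.lambda_nS * s, tau_g_ms=pc.tau_g_ms, vhat_mV=vhat,
            )

        self.ff = grp(n_e, n_e, cfg.ff, delta_g0, e.vhat_E_mV)
        self.ei_in = grp(n_i, n_e, cfg.e_to_i, cfg.e_to_i.delta_g, i.vhat_E_mV)
        self.ei_out = grp(n_i, n_e, cfg.e_to_i, cfg.e_to_i.delta_g, i.vhat_E_mV)
        self.ie_in = grp(n_e, n_i, cfg.i_to_e, cfg.i_to_e.delta_g, e.vhat_I_mV)
        self.ie_out = grp(n_e, n_i, cfg.i_to_e, cfg.i_to_e.delta_g, e.vhat_I_mV)
        self.ii_in = grp(n_i, n_i, cfg.i_to_i, cfg.i_to_i.delta_g, i.vhat_I_mV)
        self.ii_out = grp(n_i, n_i, cfg.i_to_i, cfg.i_to_i.delta_g, i.vhat_I_mV)
        self.plast = PlasticityState.zeros(n_e, n_e)
        self.hist = {k: [] for k in self.layers}  # spike indices per step
        self.barrier = 0
        self.t = 0
        self.spikes = []  # (step, pop_name, local index)

    def reset(self):
        for name, layer in self.layers.items():
            params = self.cfg.exc if name.endswith("e") else self.cfg.inh
            layer.V[:] = params.v0_mV
            layer.refractory_steps[:] = 0
        for g in (self.ff, self.ei_in, self.ei_out, self.ie_in, self.ie_out,
                  self.ii_in, self.ii_out):
            g.g[:] = 0.0
        self.plast.C[:] = 0.0
        self.plast.D[:] = 0.0
        self.barrier = self.t

    def _arrivals(self, pop):
        i = self.t - 1  # all delays are one step
        if i < self.barrier or i < 0 or i >= len(self.hist[pop]):
            return np.empty(0, dtype=np.int64)
        return self.hist[pop][i]

    def run_event(self, ev, stims, learning_on):
        cfg = self.cfg
        if ev.reset_before:
            self.reset()
        cue = stims.indices(ev.stimulus, ev.transform)
        for layer in self.layers.values():
            layer.I_ext_nA[:] = 0.0
        self.layers["ine"].I_ext_nA[cue] = ev.amplitude_nA
        for _ in range(int(round(ev.duration_ms / cfg.dt_ms))):
            arr_ine = self._arrivals("ine")
            arr_ini = self._arrivals("ini")
            arr_oute = self._arrivals("oute")
            arr_outi = self._arrivals("outi")
            for g, arr in (
                (self.ff, arr_ine), (self.ei_in, arr_ine), (self.ei_out, arr_oute),
                (self.ie_in, arr_ini), (self.ie_out, arr_outi),
                (self.ii_in, arr_ini), (self.ii_out, arr_outi),
            ):
                step_conductances(g, arr, cfg.dt_ms)
            currents = {
                "ine": synaptic_current(self.layers["ine"].V, [self.ie_in]),
                "ini": synaptic_current(self.layers["ini"].V, [self.ei_in, self.ii_in]),
                "oute": synaptic_current(self.layers["oute"].V, [self.ff, self.ie_out]),
                "outi": synaptic_current(self.layers["outi"].V, [self.ei_out, self.ii_out]),
            }
            for name, layer in self.layers.items():
                params = cfg.exc if name in ("ine", "oute") else cfg.inh
                step_membrane(layer, params, currents[name], cfg.dt_ms)
            fired = {
                name: np.flatnonzero(layer.spike_flags)
                for name, layer in self.layers.items()
            }
            if learning_on:
                step_traces(self.plast, arr_ine, fired["oute"], cfg.plasticity, cfg.dt_ms)
                apply_weight_updates(
                    self.ff.delta_g, self.plast, arr_ine, fired["oute"], cfg.plasticity
                )
            for name in self.layers:
                self.hist[name].append(fired[name])
                for idx in fired[name]:
                    self.spikes.append((self.t, name, int(idx)))
            self.t += 1


@pytest.mark.parametrize("learning_on", [False, True])
@pytest.mark.parametrize("tau_ee", [2.0, 150.0])
def test_aggregated_engine_matches_per_synapse_reference(learning_on, tau_ee):
    """The summed-conductance fast path equals the naive per-synapse
    simulation: identical spikes, matching potentials and weights."""
    cfg, stims, sched = tiny_setup(seed=3, tau_ee=tau_ee, reset_some=True)
    engine = Network(cfg)
    ref = ReferenceNetwork(cfg, engine.delta_g.copy())
    rec = engine.run(sched, learning_on=learning_on)
    for ev in sched:
        ref.run_event(ev, stims, learning_on)

    pop_name = {INPUT_EXC: "ine", INPUT_INH: "ini", OUTPUT_EXC: "oute", OUTPUT_INH: "outi"}
    got = sorted(
        (int(round(t / cfg.dt_ms)), pop_name[p], int(n))
        for t, p, n in zip(rec.t_ms, rec.pop, rec.neuron)
    )
    assert got == sorted(ref.spikes)
    assert len(got) > 20  # the comparison exercised real activity
    np.testing.assert_allclose(engine.V[: cfg.n_e], ref.layers["ine"].V, atol=1e-9)
    off = cfg.n_e + cfg.n_i
    np.testing.assert_allclose(
        engine.V[off : off + cfg.n_e], ref.layers["oute"].V, atol=1e-9
    )
    np.testing.assert_allclose(
        engine.G_exc[off : off + cfg.n_e], ref.ff.conductance_onto(), atol=1e-9
    )
    np.testing.assert_allclose(engine.delta_g, ref.ff.delta_g, atol=1e-12)


class TestBuild:
    def test_full_size_synapse_count(self):
        net = Network(NetworkConfig.ct())
        assert net.n_plastic_synapses == 160_000
        assert net.n_total == 1000

    def test_initial_weights_uniform_and_seeded(self):
        a = Network(NetworkConfig.ct(4, seed=5)).delta_g
        b = Network(NetworkConfig.ct(4, seed=5)).delta_g
        c = Network(NetworkConfig.ct(4, seed=6)).delta_g
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        assert 0.0 <= a.min() and a.max() <= 1.0
        assert abs(a.mean() - 0.5) < 0.02

    def test_ct_and_trace_projection_constants(self):
        ct = preset("ct_baseline").config
        assert ct.ff.lambda_nS == 4.0 and ct.ff.tau_g_ms == 2.0
        tr = preset("trace_baseline").config
        assert tr.ff.lambda_nS == 1.25 and tr.ff.tau_g_ms == 150.0
        assert tr.i_to_e.lambda_nS == 2.5  # standard inhibition

    def test_scaled_config_preserves_total_drive(self):
        cfg = NetworkConfig.ct(4)
        assert cfg.n_e == 100 and cfg.n_i == 25
        assert cfg.conductance_scale == 4.0

    def test_bad_scale_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig.ct(3)


class TestRunSemantics:
    def test_no_drive_and_no_noise_means_no_spikes(self):
        cfg, stims, sched = tiny_setup(amplitude=0.0)
        rec = Network(cfg).run(sched, learning_on=True)
        assert len(rec) == 0

    def test_identical_seeds_reproduce_bit_identical_runs(self):
        results = []
        for _ in range(2):
            p = preset("ct_baseline", seed=11, scale_factor=4, epochs=1)
            net = Network(p.config)
            rec = net.run(p.train_schedule, learning_on=True)
            results.append((rec, net.delta_g.copy()))
        (r1, w1), (r2, w2) = results
        np.testing.assert_array_equal(r1.t_ms, r2.t_ms)
        np.testing.assert_array_equal(r1.pop, r2.pop)
        np.testing.assert_array_equal(r1.neuron, r2.neuron)
        np.testing.assert_array_equal(w1, w2)
        assert len(r1) > 0

    def test_learning_off_leaves_weights_bit_identical(self):
        cfg, stims, sched = tiny_setup()
        net = Network(cfg)
        before = net.delta_g.copy()
        net.run(sched, learning_on=False)
        np.testing.assert_array_equal(net.delta_g, before)

    def test_learning_on_changes_weights(self):
        cfg, stims, sched = tiny_setup()
        net = Network(cfg)
        before = net.delta_g.copy()
        net.run(sched, learning_on=True)
        assert not np.array_equal(net.delta_g, before)
        assert net.delta_g.min() >= 0.0 and net.delta_g.max() <= 1.0

    def test_reset_returns_to_rest_but_keeps_weights(self):
        cfg, stims, sched = tiny_setup()
        net = Network(cfg)
        net.run(sched, learning_on=True)
        w = net.delta_g.copy()
        net.reset()
        np.testing.assert_array_equal(net.V, net._v0)
        assert net.G_exc.max() == 0.0 and net.G_inh.max() == 0.0
        assert net.trace_C.max() == 0.0 and net.trace_D.max() == 0.0
        np.testing.assert_array_equal(net.delta_g, w)

    def test_empty_schedule_rejected(self):
        cfg, stims, _ = tiny_setup()
        with pytest.raises(ValueError):
            Network(cfg).run(Schedule(events=[], phase="train", stimulus_set=stims))


class TestPersistence:
    def test_snapshot_roundtrip_resumes_identically(self, tmp_path):
        cfg, stims, sched = tiny_setup(seed=2)
        net = Network(cfg)
        net.run(sched, learning_on=True)
        net.save_snapshot(tmp_path / "state.npz")
        rec_a = net.run(sched, learning_on=True)
        net2 = Network(cfg)
        net2.load_snapshot(tmp_path / "state.npz")
        rec_b = net2.run(sched, learning_on=True)
        np.testing.assert_array_equal(rec_a.t_ms, rec_b.t_ms)
        np.testing.assert_array_equal(rec_a.neuron, rec_b.neuron)
        np.testing.assert_array_equal(net.delta_g, net2.delta_g)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = preset("trace_baseline", seed=4, scale_factor=2).config
        cfg.save_yaml(tmp_path / "cfg.yaml")
        loaded = NetworkConfig.load_yaml(tmp_path / "cfg.yaml")
        assert loaded == cfg

    def test_spike_record_text_roundtrip(self, tmp_path):
        cfg, stims, sched = tiny_setup()
        rec = Network(cfg).run(sched, learning_on=False)
        rec.save_text(tmp_path / "spikes.tsv")
        back = SpikeRecord.load_text(tmp_path / "spikes.tsv")
        np.testing.assert_allclose(back.t_ms, rec.t_ms)
        np.testing.assert_array_equal(back.pop, rec.pop)
        np.testing.assert_array_equal(back.neuron, rec.neuron)
        np.testing.assert_array_equal(back.event, rec.event)
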