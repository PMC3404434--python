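"""Two-layer network assembly and the simulation engine.

Architecture: an input and an output layer, each with ``n_e`` excitatory
pyramidal cells and ``n_i`` inhibitory interneurons.  Within a layer the
excitatory pool is fully reciprocally connected to the inhibitory pool
(E->I and I->E) and the interneurons inhibit each other (I->I); all these
lateral synapses are fixed.  The input-layer excitatory cells are fully
connected to the output-layer excitatory cells through plastic
feed-forward synapses governed by the multiplicative STDP rule.  Stimuli
drive the input-layer excitatory cells by direct current injection only.

The engine integrates all four populations with Forward-Euler at
``dt = 0.02 ms``.  Because every synapse of a projection shares the same
decay time constant and conduction delay, the summed synaptic conductance
onto each postsynaptic neuron can be maintained directly::

    G_i <- G_i * (1 - dt/tau_g) + lambda * sum_{j in arrivals} Delta_g_ij

which is exactly equivalent to integrating every synapse separately and
summing (linearity); the equivalence is covered by a regression test
against the naive per-synapse primitives.  Update order within a step:
(1) decay conductances and deliver the spikes arriving this step,
(2) compute synaptic currents, (3) advance membranes and detect spikes,
(4) plasticity trace jumps, then weight updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from collections import deque

import numpy as np
import pandas as pd
import yaml

from .neurons import (
    EXCITATORY,
    INHIBITORY,
    NumericalError,
    PopulationParams,
    refractory_steps_for,
)
from .plasticity import PlasticityParams
from .stimuli import Schedule

__all__ = [
    "ProjectionConfig",
    "NetworkConfig",
    "Network",
    "SpikeRecord",
    "POPULATIONS",
    "INPUT_EXC",
    "INPUT_INH",
    "OUTPUT_EXC",
    "OUTPUT_INH",
]

POPULATIONS = ("input_exc", "input_inh", "output_exc", "output_inh")
INPUT_EXC, INPUT_INH, OUTPUT_EXC, OUTPUT_INH = range(4)

DT_MS = 0.02  # integration step used in all simulations


@dataclass(frozen=True)
class ProjectionConfig:
    """One projection's synaptic constants.

    The per-synapse conductance increment on a spike is
    ``lambda_nS * delta_g`` (times the network's conductance scale); for
    the plastic feed-forward projection ``delta_g`` is the initial-weight
    placeholder and the per-synapse efficacies are drawn at build time.
    """

    lambda_nS: float
    tau_g_ms: float
    delta_g: float = 1.0
    delay_ms: float = 0.0
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.tau_g_ms <= 0:
            raise ValueError("tau_g must be positive")
        if self.delay_ms < 0:
            raise ValueError("delay must be non-negative")
        if not 0 <= self.delta_g <= 1:
            raise ValueError("delta_g must lie in [0, 1]")


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameterisation of the two-layer network.

    ``conductance_scale`` multiplies every synaptic conductance; reduced
    networks (``scale_factor`` k: n_e = 400/k, n_i = 100/k) use
    ``conductance_scale = k`` so each neuron receives the same total
    synaptic drive as at full size.
    """

    n_e: int = 400
    n_i: int = 100
    dt_ms: float = DT_MS
    exc: PopulationParams = EXCITATORY
    inh: PopulationParams = INHIBITORY
    ff: ProjectionConfig = ProjectionConfig(lambda_nS=4.0, tau_g_ms=2.0, plastic=True)
    e_to_i: ProjectionConfig = ProjectionConfig(lambda_nS=5.0, tau_g_ms=2.0)
    i_to_e: ProjectionConfig = ProjectionConfig(lambda_nS=2.5, tau_g_ms=5.0)
    i_to_i: ProjectionConfig = ProjectionConfig(lambda_nS=5.0, tau_g_ms=5.0)
    conductance_scale: float = 1.0
    noise_exc: bool = True
    noise_inh: bool = True
    plasticity: PlasticityParams = PlasticityParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_e < 1 or self.n_i < 1:
            raise ValueError("population sizes must be positive")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if not self.ff.plastic:
            raise ValueError("the feed-forward projection must be plastic")

    # -- regime presets -------------------------------------------------
    @classmethod
    def ct(cls, scale_factor: int = 1, **overrides) -> "NetworkConfig":
        """Continuous-transformation regime: fast feed-forward synapses
        (tau_EE = 2 ms) with plastic conductance cap 4 nS."""
        return cls._scaled(
            scale_factor,
            ff=ProjectionConfig(lambda_nS=4.0, tau_g_ms=2.0, plastic=True),
            **overrides,
        )

    @classmethod
    def trace(cls, scale_factor: int = 1, **overrides) -> "NetworkConfig":
        """Trace regime: slow feed-forward synapses (tau_EE = 150 ms) with
        plastic conductance cap reduced to 1.25 nS."""
        return cls._scaled(
            scale_factor,
            ff=ProjectionConfig(lambda_nS=1.25, tau_g_ms=150.0, plastic=True),
            **overrides,
        )

    @classmethod
    def _scaled(cls, scale_factor: int, **overrides) -> "NetworkConfig":
        if 400 % scale_factor or 100 % scale_factor:
            raise ValueError("scale factor must divide 400 and 100")
        kw = dict(
            n_e=400 // scale_factor,
            n_i=100 // scale_factor,
            conductance_scale=float(scale_factor),
        )
        kw.update(overrides)
        return cls(**kw)

    def with_inhibition(self, g_IE_nS: float) -> "NetworkConfig":
        """Copy with a different I->E conductance strength (nS)."""
        return replace(self, i_to_e=replace(self.i_to_e, lambda_nS=g_IE_nS))

    # -- text-config round trip ----------------------------------------
    def to_dict(self) -> dict:
        def pop_d(p: PopulationParams) -> dict:
            return {
                "c_m_pF": p.c_m_pF,
                "g0_nS": p.g0_nS,
                "tau_m_ms": p.tau_m_ms,
                "v0_mV": p.v0_mV,
                "theta_mV": p.theta_mV,
                "vH_mV": p.vH_mV,
                "vhat_E_mV": p.vhat_E_mV,
                "vhat_I_mV": p.vhat_I_mV,
                "tau_R_ms": p.tau_R_ms,
                "sigma_coeff": p.sigma_coeff,
            }

        return {
            "network": {
                "n_e": self.n_e,
                "n_i": self.n_i,
                "dt_ms": self.dt_ms,
                "conductance_scale": self.conductance_scale,
                "noise_exc": self.noise_exc,
                "noise_inh": self.noise_inh,
                "seed": self.seed,
            },
            "populations": {
                "excitatory": pop_d(self.exc),
                "inhibitory": pop_d(self.inh),
            },
            "projections": {
                name: asdict(getattr(self, name))
                for name in ("ff", "e_to_i", "i_to_e", "i_to_i")
            },
            "plasticity": asdict(self.plasticity),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        def pop_p(label: str, pd_: dict) -> PopulationParams:
            pd_ = dict(pd_)
            tau_m = pd_.pop("tau_m_ms", None)
            p = PopulationParams(class_label=label, **pd_)
            if tau_m is not None and abs(p.tau_m_ms - tau_m) > 0.5:
                raise ValueError(
                    f"{label}: tau_m_ms={tau_m} inconsistent with C_m/g_0={p.tau_m_ms:.3f}"
                )
            return p

        net = d["network"]
        return cls(
            n_e=net["n_e"],
            n_i=net["n_i"],
            dt_ms=net["dt_ms"],
            conductance_scale=net.get("conductance_scale", 1.0),
            noise_exc=net.get("noise_exc", True),
            noise_inh=net.get("noise_inh", True),
            seed=net.get("seed", 0),
            exc=pop_p("excitatory", d["populations"]["excitatory"]),
            inh=pop_p("inhibitory", d["populations"]["inhibitory"]),
            plasticity=PlasticityParams(**d["plasticity"]),
            **{name: ProjectionConfig(**pd_) for name, pd_ in d["projections"].items()},
        )

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SpikeRecord:
    """Time-stamped spike events with presentation annotations.

    ``pop`` holds population codes (see ``POPULATIONS``); ``neuron`` is the
    index within its population; ``event`` the presentation-event index of
    the schedule being run (-1 outside any event).
    """

    t_ms: np.ndarray
    pop: np.ndarray
    neuron: np.ndarray
    event: np.ndarray

    def __len__(self) -> int:
        return len(self.t_ms)

    def select(self, pop: int | None = None, event: int | None = None) -> "SpikeRecord":
        mask = np.ones(len(self.t_ms), dtype=bool)
        if pop is not None:
            mask &= self.pop == pop
        if event is not None:
            mask &= self.event == event
        return SpikeRecord(self.t_ms[mask], self.pop[mask], self.neuron[mask], self.event[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.t_ms,
                "population": [POPULATIONS[p] for p in self.pop],
                "neuron": self.neuron,
                "event_id": self.event,
            }
        )

    def save_text(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load_text(cls, path) -> "SpikeRecord":
        df = pd.read_csv(path, sep="\t")
        codes = np.array([POPULATIONS.index(p) for p in df["population"]], dtype=np.int8)
        return cls(
            t_ms=df["time_ms"].to_numpy(float),
            pop=codes,
            neuron=df["neuron"].to_numpy(np.int64),
            event=df["event_id"].to_numpy(np.int64),
        )

    @classmethod
    def empty(cls) -> "SpikeRecord":
        z = np.empty(0)
        zi = np.empty(0, dtype=np.int64)
        return cls(z, np.empty(0, dtype=np.int8), zi, zi)


class Network:
    """Simulation state and integrator for one two-layer network.

    Building draws the plastic feed-forward efficacies
    ``Delta_g ~ Uniform(0, 1)`` from the config seed; the same generator
    then supplies the membrane noise, so a config fully determines a run.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed) if rng is None else rng
        c = config
        n_e, n_i = c.n_e, c.n_i
        self.n_total = 2 * (n_e + n_i)
        self.offsets = {
            INPUT_EXC: 0,
            INPUT_INH: n_e,
            OUTPUT_EXC: n_e + n_i,
            OUTPUT_INH: 2 * n_e + n_i,
        }
        self.sizes = {INPUT_EXC: n_e, INPUT_INH: n_i, OUTPUT_EXC: n_e, OUTPUT_INH: n_i}
        self._bounds = np.array([n_e, n_e + n_i, 2 * n_e + n_i], dtype=np.int64)

        def per_neuron(exc_val: float, inh_val: float) -> np.ndarray:
            v = np.empty(self.n_total)
            v[0:n_e] = exc_val
            v[n_e : n_e + n_i] = inh_val
            v[n_e + n_i : 2 * n_e + n_i] = exc_val
            v[2 * n_e + n_i :] = inh_val
            return v

        dt = c.dt_ms
        self._v0 = per_neuron(c.exc.v0_mV, c.inh.v0_mV)
        self._theta = per_neuron(c.exc.theta_mV, c.inh.theta_mV)
        self._vH = per_neuron(c.exc.vH_mV, c.inh.vH_mV)
        self._vhatE = per_neuron(c.exc.vhat_E_mV, c.inh.vhat_E_mV)
        self._vhatI = per_neuron(c.exc.vhat_I_mV, c.inh.vhat_I_mV)
        a_exc, a_inh = dt / c.exc.tau_m_ms, dt / c.inh.tau_m_ms
        self._a = per_neuron(a_exc, a_inh)
        self._b = per_neuron(a_exc / c.exc.g0_nS, a_inh / c.inh.g0_nS)
        self._noise_amp = per_neuron(
            (c.exc.sigma_mV * np.sqrt(dt / c.exc.tau_m_ms)) if c.noise_exc else 0.0,
            (c.inh.sigma_mV * np.sqrt(dt / c.inh.tau_m_ms)) if c.noise_inh else 0.0,
        )
        self._any_noise = bool(np.any(self._noise_amp > 0))
        self._nref = per_neuron(
            refractory_steps_for(c.exc, dt), refractory_steps_for(c.inh, dt)
        ).astype(np.int64)

        # conductance decay factors: one excitatory and one inhibitory
        # summed conductance per neuron (all its afferents of a class share tau_g)
        self._dec_exc = per_neuron(1.0, 1.0 - dt / c.e_to_i.tau_g_ms)
        self._dec_exc[n_e + n_i : 2 * n_e + n_i] = 1.0 - dt / c.ff.tau_g_ms
        self._dec_inh = per_neuron(1.0 - dt / c.i_to_e.tau_g_ms, 1.0 - dt / c.i_to_i.tau_g_ms)

        s = c.conductance_scale
        self._w_ei = c.e_to_i.lambda_nS * c.e_to_i.delta_g * s
        self._w_ie = c.i_to_e.lambda_nS * c.i_to_e.delta_g * s
        self._w_ii = c.i_to_i.lambda_nS * c.i_to_i.delta_g * s
        self._lam_ff = c.ff.lambda_nS * s

        self._d_ff = max(1, int(round(c.ff.delay_ms / dt)))
        self._d_ei = max(1, int(round(c.e_to_i.delay_ms / dt)))
        self._d_ie = max(1, int(round(c.i_to_e.delay_ms / dt)))
        self._d_ii = max(1, int(round(c.i_to_i.delay_ms / dt)))
        self._hist_len = max(self._d_ff, self._d_ei, self._d_ie, self._d_ii)

        # plastic feed-forward efficacies, Uniform(0,1) per synapse
        self.delta_g = self.rng.uniform(0.0, 1.0, size=(n_e, n_e))

        self.V = self._v0.copy()
        self.refractory_steps = np.zeros(self.n_total, dtype=np.int64)
        self.G_exc = np.zeros(self.n_total)
        self.G_inh = np.zeros(self.n_total)
        self.trace_C = np.zeros(n_e)  # presynaptic trace per input cell
        self.trace_D = np.zeros(n_e)  # postsynaptic trace per output cell
        self.I_ext_nA = np.zeros(self.n_total)
        self.t_step = 0
        self._clear_history()

    # ------------------------------------------------------------------
    @property
    def n_plastic_synapses(self) -> int:
        return self.delta_g.size

    def _clear_history(self) -> None:
        empty = np.empty(0, dtype=np.int64)
        self._hist = {
            p: deque([empty] * self._hist_len, maxlen=self._hist_len) for p in range(4)
        }

    def reset(self) -> None:
        """Return neurons to rest: V = V_0, conductances and STDP traces
        cleared, refractoriness and in-flight spikes cancelled.  The
        learned efficacies ``delta_g`` are untouched."""
        self.V[:] = self._v0
        self.refractory_steps[:] = 0
        self.G_exc[:] = 0.0
        self.G_inh[:] = 0.0
        self.trace_C[:] = 0.0
        self.trace_D[:] = 0.0
        self._clear_history()

    def set_cue(self, input_indices: np.ndarray, amplitude_nA: float) -> None:
        """Inject ``amplitude_nA`` into the given input-layer excitatory
        neurons (and nothing anywhere else)."""
        self.I_ext_nA[:] = 0.0
        self.I_ext_nA[np.asarray(input_indices, dtype=np.int64)] = amplitude_nA

    # ------------------------------------------------------------------
    def run(
        self,
        schedule: Schedule,
        learning_on: bool = False,
        record: bool = True,
    ) -> SpikeRecord:
        """Run a presentation schedule; returns the spikes recorded.

        With ``learning_on`` the STDP traces and weight updates are active;
        otherwise ``delta_g`` is provably untouched.  Each event optionally
        resets the network before injecting its cue current.
        """
        if len(schedule) == 0:
            raise ValueError("schedule is empty")
        stimset = schedule.stimulus_set
        if stimset is None:
            raise ValueError("schedule has no stimulus set attached")

        dt = self.config.dt_ms
        rec_steps: list = []
        rec_idx: list = []
        rec_event: list = []

        for ev_id, ev in enumerate(schedule):
            if ev.reset_before:
                self.reset()
            self.set_cue(stimset.indices(ev.stimulus, ev.transform), ev.amplitude_nA)
            n_steps = int(round(ev.duration_ms / dt))
            self._integrate(
                n_steps, learning_on, record, ev_id, rec_steps, rec_idx, rec_event
            )

        self.I_ext_nA[:] = 0.0
        if not record or not rec_steps:
            return SpikeRecord.empty()
        counts = [len(ix) for ix in rec_idx]
        steps = np.repeat(np.asarray(rec_steps, dtype=np.int64), counts)
        events = np.repeat(np.asarray(rec_event, dtype=np.int64), counts)
        flat = np.concatenate(rec_idx)
        pop = np.searchsorted(self._bounds, flat, side="right").astype(np.int8)
        off = np.array([self.offsets[p] for p in range(4)], dtype=np.int64)
        return SpikeRecord(
            t_ms=steps * dt, pop=pop, neuron=flat - off[pop], event=events
        )

    def _integrate(
        self,
        n_steps: int,
        learning_on: bool,
        record: bool,
        ev_id: int,
        rec_steps: list,
        rec_idx: list,
        rec_event: list,
    ) -> None:
        """Inner Forward-Euler loop (hot path: local bindings, in-place ops)."""
        c = self.config
        V = self.V
        refr = self.refractory_steps
        G_exc, G_inh = self.G_exc, self.G_inh
        dg = self.delta_g
        trC, trD = self.trace_C, self.trace_D
        dec_exc, dec_inh = self._dec_exc, self._dec_inh
        a, b = self._a, self._b
        v0, theta, vH = self._v0, self._theta, self._vH
        vhatE, vhatI = self._vhatE, self._vhatI
        noise_amp, any_noise = self._noise_amp, self._any_noise
        nref = self._nref
        rng = self.rng
        n_e, n_i = c.n_e, c.n_i
        o_ini, o_oute, o_outi = (
            self.offsets[INPUT_INH],
            self.offsets[OUTPUT_EXC],
            self.offsets[OUTPUT_INH],
        )
        sl_ini = slice(o_ini, o_ini + n_i)
        sl_oute = slice(o_oute, o_oute + n_e)
        sl_outi = slice(o_outi, o_outi + n_i)
        w_ei, w_ie, w_ii, lam_ff = self._w_ei, self._w_ie, self._w_ii, self._lam_ff
        d_ff, d_ei, d_ie, d_ii = self._d_ff, self._d_ei, self._d_ie, self._d_ii
        hist = self._hist
        I_ext_pA = 1000.0 * self.I_ext_nA
        bounds = self._bounds
        pl = c.plasticity
        fC = 1.0 - c.dt_ms / pl.tau_C_ms
        fD = 1.0 - c.dt_ms / pl.tau_D_ms
        aC, aD, rho = pl.alpha_C, pl.alpha_D, pl.rho

        n = V.shape[0]
        buf1 = np.empty(n)
        buf2 = np.empty(n)
        refr_mask = np.empty(n, dtype=bool)
        fired = np.empty(n, dtype=bool)
        h_ine, h_ini, h_oute, h_outi = (
            hist[INPUT_EXC],
            hist[INPUT_INH],
            hist[OUTPUT_EXC],
            hist[OUTPUT_INH],
        )
        # membrane noise is drawn in blocks and pre-scaled by the
        # per-neuron amplitude; the stream is consumed deterministically
        # so a seed fully reproduces a run
        NOISE_CHUNK = 256
        noise_block = None
        noise_i = NOISE_CHUNK

        for _ in range(n_steps):
            # (1) conductance decay + delivery of arriving spikes
            G_exc *= dec_exc
            G_inh *= dec_inh
            ff_arrivals = h_ine[-d_ff]
            if ff_arrivals.size:
                G_exc[sl_oute] += lam_ff * dg[:, ff_arrivals].sum(axis=1)
            sp = h_ine[-d_ei]
            if sp.size:
                G_exc[sl_ini] += w_ei * sp.size
            sp = h_oute[-d_ei]
            if sp.size:
                G_exc[sl_outi] += w_ei * sp.size
            sp = h_ini[-d_ie]
            if sp.size:
                G_inh[0:n_e] += w_ie * sp.size
            sp = h_ini[-d_ii]
            if sp.size:
                G_inh[sl_ini] += w_ii * sp.size
            sp = h_outi[-d_ie]
            if sp.size:
                G_inh[sl_oute] += w_ie * sp.size
            sp = h_outi[-d_ii]
            if sp.size:
                G_inh[sl_outi] += w_ii * sp.size

            # (2)+(3) fused current and Forward-Euler membrane update:
            # dV = a*(v0 - V) + b*(G_exc*(vhatE-V) + G_inh*(vhatI-V) + I_ext)
            np.subtract(vhatE, V, out=buf1)
            buf1 *= G_exc
            np.subtract(vhatI, V, out=buf2)
            buf2 *= G_inh
            buf1 += buf2
            buf1 += I_ext_pA
            buf1 *= b
            np.subtract(v0, V, out=buf2)
            buf2 *= a
            buf1 += buf2
            if any_noise:
                if noise_i == NOISE_CHUNK:
                    noise_block = rng.standard_normal((NOISE_CHUNK, n))
                    noise_block *= noise_amp
                    noise_i = 0
                buf1 += noise_block[noise_i]
                noise_i += 1
            V += buf1
            np.greater(refr, 0, out=refr_mask)
            np.copyto(V, vH, where=refr_mask)
            refr -= refr_mask
            np.greater_equal(V, theta, out=fired)
            if fired.any():
                fired_idx = fired.nonzero()[0]
                V[fired_idx] = vH[fired_idx]
                refr[fired_idx] = nref[fired_idx]
                if record:
                    rec_steps.append(self.t_step)
                    rec_idx.append(fired_idx)
                    rec_event.append(ev_id)
                lo, mid, hi = np.searchsorted(fired_idx, bounds)
                sp_ine = fired_idx[:lo]
                sp_ini = fired_idx[lo:mid] - o_ini
                sp_oute = fired_idx[mid:hi] - o_oute
                sp_outi = fired_idx[hi:] - o_outi
            else:
                sp_ine = sp_ini = sp_oute = sp_outi = _EMPTY

            # (4) STDP: trace decay + jumps, then weight updates
            if learning_on:
                trC *= fC
                trD *= fD
                if ff_arrivals.size:
                    trC[ff_arrivals] += aC * (1.0 - trC[ff_arrivals])
                if sp_oute.size:
                    trD[sp_oute] += aD * (1.0 - trD[sp_oute])
                if sp_oute.size:  # LTP at postsynaptic spikes
                    dg[sp_oute, :] += rho * (1.0 - dg[sp_oute, :]) * trC[np.newaxis, :]
                if ff_arrivals.size:  # LTD at arriving presynaptic spikes
                    dg[:, ff_arrivals] -= rho * dg[:, ff_arrivals] * trD[:, np.newaxis]

            h_ine.append(sp_ine)
            h_ini.append(sp_ini)
            h_oute.append(sp_oute)
            h_outi.append(sp_outi)
            self.t_step += 1

        if not np.isfinite(V).all():
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise NumericalError(
                f"non-finite membrane potential at neuron {bad}, "
                f"t={self.t_step * c.dt_ms:.2f} ms"
            )

    # -- snapshot container --------------------------------------------
    def save_snapshot(self, path) -> None:
        """Binary state snapshot: potentials, conductances, efficacies,
        traces, RNG state and simulation clock."""
        np.savez_compressed(
            path,
            V=self.V,
            refractory_steps=self.refractory_steps,
            G_exc=self.G_exc,
            G_inh=self.G_inh,
            delta_g=self.delta_g,
            trace_C=self.trace_C,
            trace_D=self.trace_D,
            t_step=np.int64(self.t_step),
            rng_state=np.frombuffer(
                json.dumps(self.rng.bit_generator.state).encode(), dtype=np.uint8
            ),
        )

    def load_snapshot(self, path) -> None:
        with np.load(path) as z:
            self.V[:] = z["V"]
            self.refractory_steps[:] = z["refractory_steps"]
            self.G_exc[:] = z["G_exc"]
            self.G_inh[:] = z["G_inh"]
            self.delta_g[:] = z["delta_g"]
            self.trace_C[:] = z["trace_C"]
            self.trace_D[:] = z["trace_D"]
            self.t_step = int(z["t_step"])
            state = json.loads(z["rng_state"].tobytes().decode())
        self.rng.bit_generator.state = state
        self._clear_history()


_EMPTY = np.empty(0, dtype=np.int64)
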