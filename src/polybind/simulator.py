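"""Conductance-based LIF dynamics with delayed spike delivery.

Forward-Euler integration on a fixed step grid (default dt = 0.02 ms):

    tau_m dV/dt = (V_0 - V) + I / g_0,     I_i = sum_j g_ij (Vrev_j - V_i)

Synaptic conductances decay with the exact per-step exponential factor
exp(-dt/tau_g) (unconditionally stable; equals the Euler difference in the
dt -> 0 limit) and jump by lambda * dg_ij when a presynaptic spike arrives
after its axonal delay.  Spikes are stamped on the step grid; delays are
rounded to the nearest step at scheduling time.

Within one step the order is: conductance decay, spike arrivals (so an
arrival may trigger a spike in the same step), membrane integration,
threshold detection/reset, delivery scheduling.  During the absolute
refractory period the membrane is clamped at V_H while conductances keep
decaying and accumulating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .builder import Network
from .params import PlasticityParams
from .plasticity import (TraceState, decay_traces, on_postsynaptic_spike,
                         on_presynaptic_arrival)
from .records import SpikeRecord

logger = logging.getLogger(__name__)

__all__ = ["NetworkState", "DelayLine", "SpikeEvent", "Simulator", "run_trial"]


@dataclass(frozen=True)
class SpikeEvent:
    neuron: int
    time_ms: float


@dataclass
class NetworkState:
    """Mutable per-step state: membrane potentials, refractory clocks,
    per-synapse conductances, derived input currents and the clock."""

    v: np.ndarray            # mV
    refrac_ms: np.ndarray    # remaining refractory time
    g: np.ndarray            # nS, per synapse
    i_pa: np.ndarray         # pA, recomputed each step
    t_ms: float = 0.0
    step: int = 0


class DelayLine:
    """Pending delayed deliveries, bucketed by arrival step."""

    def __init__(self) -> None:
        self._buckets: dict[int, list[np.ndarray]] = {}

    def push(self, syn_ids: np.ndarray, arrival_steps: np.ndarray) -> None:
        if syn_ids.size == 0:
            return
        order = np.argsort(arrival_steps, kind="stable")
        syn_ids = syn_ids[order]
        arrival_steps = arrival_steps[order]
        bounds = np.flatnonzero(np.diff(arrival_steps)) + 1
        for chunk, step0 in zip(np.split(syn_ids, bounds),
                                arrival_steps[np.r_[0, bounds]]):
            self._buckets.setdefault(int(step0), []).append(chunk)

    def pop(self, step: int) -> np.ndarray:
        parts = self._buckets.pop(step, None)
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(parts)

    def pending(self) -> list[tuple[int, int]]:
        """All pending (arrival_step, synapse_id) pairs, unsorted."""
        out = []
        for step, parts in self._buckets.items():
            for chunk in parts:
                out.extend((step, int(s)) for s in chunk)
        return out

    def __len__(self) -> int:
        return sum(chunk.size for parts in self._buckets.values()
                   for chunk in parts)


class Simulator:
    """Bind a :class:`Network` to an integration grid and run trials.

    The plastic weights live in ``network.connections.weight`` and are
    mutated in place when a trial is run with plasticity enabled; all other
    state (membrane, conductances, traces, pending deliveries) is created
    fresh per trial.
    """

    def __init__(self, network: Network, dt_ms: float,
                 plasticity: PlasticityParams | None = None) -> None:
        if dt_ms <= 0:
            raise ValueError("dt must be positive")
        self.network = network
        self.dt_ms = float(dt_ms)
        self.plasticity = plasticity

        con = network.connections
        self.n_syn = len(con)
        self.weights = con.weight  # shared, mutated under plasticity
        self.syn_post = con.post
        self.syn_pre = con.pre
        self.syn_scale = con.per_synapse("g_scale_ns")
        self.syn_vrev = con.per_synapse("reversal_mv")
        tau_g = con.per_synapse("tau_g_ms")
        self.g_decay = np.exp(-self.dt_ms / tau_g)
        self.syn_plastic = con.plastic
        self.delay_steps = np.maximum(
            1, np.rint(con.delay_ms / self.dt_ms).astype(np.int64))

        cls = network.neuron_class
        def per_neuron(attr):
            table = np.array([getattr(c, attr) for c in network.classes])
            return table[cls]
        self.v0 = per_neuron("v_rest_mv")
        self.theta = per_neuron("v_thresh_mv")
        self.v_reset = per_neuron("v_reset_mv")
        self.tau_m = per_neuron("tau_m_ms")
        self.g0 = per_neuron("g0_ns")
        self.tau_refrac = per_neuron("tau_refrac_ms")
        self.dynamic = ~network.is_input

        # CSR adjacency: efferent synapses by presynaptic neuron
        order = np.argsort(self.syn_pre, kind="stable")
        self.eff_idx = order
        self.eff_ptr = np.searchsorted(self.syn_pre[order],
                                       np.arange(network.n_neurons + 1))
        # plastic afferent synapses by postsynaptic neuron (for LTP)
        pl = np.flatnonzero(self.syn_plastic)
        order = pl[np.argsort(self.syn_post[pl], kind="stable")]
        self.aff_idx = order
        self.aff_ptr = np.searchsorted(self.syn_post[order],
                                       np.arange(network.n_neurons + 1))

    # -- state management ---------------------------------------------------

    def initial_state(self) -> NetworkState:
        n = self.network.n_neurons
        return NetworkState(
            v=self.v0.copy(),
            refrac_ms=np.zeros(n),
            g=np.zeros(self.n_syn),
            i_pa=np.zeros(n),
        )

    def efferents(self, neuron_ids: np.ndarray) -> np.ndarray:
        """Synapse indices of all efferent synapses of the given neurons."""
        if len(neuron_ids) == 0:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [self.eff_idx[self.eff_ptr[n]:self.eff_ptr[n + 1]]
             for n in neuron_ids])

    def plastic_afferents(self, neuron_ids: np.ndarray) -> np.ndarray:
        if len(neuron_ids) == 0:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [self.aff_idx[self.aff_ptr[n]:self.aff_ptr[n + 1]]
             for n in neuron_ids])

    # -- the four per-step operations ----------------------------------------

    def update_conductances(self, state: NetworkState, arrivals: np.ndarray,
                            traces: TraceState | None = None) -> None:
        """Decay all conductances by exp(-dt/tau_g), then add lambda * dg
        for each arriving spike; plastic arrivals also trigger depression
        and drive the presynaptic trace when ``traces`` is given."""
        state.g *= self.g_decay
        if arrivals.size:
            if arrivals.max() >= self.n_syn or arrivals.min() < 0:
                raise IndexError("arrival references an unknown synapse")
            np.add.at(state.g, arrivals,
                      self.syn_scale[arrivals] * self.weights[arrivals])
            if traces is not None:
                pa = arrivals[self.syn_plastic[arrivals]]
                on_presynaptic_arrival(pa, self.syn_post, traces,
                                       self.weights, self.plasticity)

    def integrate_step(self, state: NetworkState) -> None:
        """One forward-Euler membrane step; refractory neurons hold at V_H
        while their countdown decrements.  Advances the clock by dt."""
        contrib = state.g * (self.syn_vrev - state.v[self.syn_post])
        state.i_pa = np.bincount(self.syn_post, weights=contrib,
                                 minlength=self.network.n_neurons)
        refractory = state.refrac_ms > 0
        active = self.dynamic & ~refractory
        dv = (self.dt_ms / self.tau_m) * (
            (self.v0 - state.v) + state.i_pa / self.g0)
        state.v[active] += dv[active]
        held = self.dynamic & refractory
        state.v[held] = self.v_reset[held]
        state.refrac_ms[held] -= self.dt_ms
        state.step += 1
        state.t_ms = state.step * self.dt_ms
        if not np.all(np.isfinite(state.v[self.dynamic])):
            raise FloatingPointError(
                "non-finite membrane potential: forward-Euler step unstable "
                f"(dt = {self.dt_ms} ms too large for the given conductances)")

    def detect_spikes_and_reset(self, state: NetworkState,
                                traces: TraceState | None = None) -> np.ndarray:
        """Emit spikes for non-refractory neurons at or above threshold,
        reset them to V_H and start the refractory countdown.  Potentiation
        and the postsynaptic trace drive happen here when ``traces`` given.
        Returns the spiking neuron indices."""
        fired = np.flatnonzero(self.dynamic & (state.refrac_ms <= 0)
                               & (state.v >= self.theta))
        if fired.size:
            state.v[fired] = self.v_reset[fired]
            state.refrac_ms[fired] = self.tau_refrac[fired]
            if traces is not None:
                on_postsynaptic_spike(fired, self.plastic_afferents(fired),
                                      traces, self.weights, self.plasticity)
        return fired

    def schedule_deliveries(self, neuron_ids: np.ndarray, emission_step: int,
                            line: DelayLine) -> None:
        """Enqueue one pending delivery per efferent synapse of each spiking
        neuron, at emission step + the synapse's delay (in steps)."""
        syn = self.efferents(neuron_ids)
        if syn.size:
            line.push(syn, emission_step + self.delay_steps[syn])

    # -- trial loop -----------------------------------------------------------

    def run_trial(self, input_spikes: SpikeRecord | None, duration_ms: float,
                  plasticity_on: bool = False,
                  record_v: np.ndarray | None = None) -> SpikeRecord:
        """Present one trial and return the spikes of all non-input neurons.

        ``input_spikes`` holds the spike times of input-layer units (times in
        [0, duration]); their spikes are delivered through their efferent
        synapses with the stored axonal delays.  When ``plasticity_on``,
        weights and traces update event-wise; when off, weights are untouched.
        """
        if plasticity_on and self.plasticity is None:
            raise ValueError("plasticity_on requires PlasticityParams")
        dt = self.dt_ms
        n_steps = int(math.floor(duration_ms / dt + 1e-9))
        if abs(n_steps * dt - duration_ms) > 1e-9:
            logger.warning("duration %.4f ms not a multiple of dt=%.4f ms; "
                           "rounded down to %d steps", duration_ms, dt, n_steps)

        state = self.initial_state()
        line = DelayLine()
        traces = (TraceState.zeros(self.n_syn, self.network.n_neurons)
                  if plasticity_on else None)

        # bucket input emissions by step
        if input_spikes is not None and len(input_spikes):
            if input_spikes.time_ms.min() < 0 or \
               input_spikes.time_ms.max() > duration_ms:
                raise ValueError("input spike times must lie in [0, duration]")
            in_steps = np.clip(np.rint(input_spikes.time_ms / dt).astype(np.int64),
                               0, n_steps - 1)
            order = np.argsort(in_steps, kind="stable")
            in_steps = in_steps[order]
            in_units = input_spikes.neuron[order]
            in_ptr = np.searchsorted(in_steps, np.arange(n_steps + 1))
        else:
            in_units = np.empty(0, dtype=np.int64)
            in_ptr = np.zeros(n_steps + 1, dtype=np.int64)

        out_neurons: list[np.ndarray] = []
        out_times: list[np.ndarray] = []
        v_trace = [] if record_v is not None else None

        for k in range(n_steps):
            if traces is not None:
                decay_traces(traces, dt, self.plasticity)
            arrivals = line.pop(k)
            self.update_conductances(state, arrivals, traces)
            self.integrate_step(state)
            fired = self.detect_spikes_and_reset(state, traces)
            if fired.size:
                out_neurons.append(fired)
                out_times.append(np.full(fired.size, state.t_ms))
            emitters = fired
            inputs_now = in_units[in_ptr[k]:in_ptr[k + 1]]
            if inputs_now.size:
                emitters = np.concatenate([fired, inputs_now])
            self.schedule_deliveries(emitters, k, line)
            if v_trace is not None:
                v_trace.append(state.v[record_v].copy())

        neuron = (np.concatenate(out_neurons) if out_neurons
                  else np.empty(0, dtype=np.int64))
        time_ms = (np.concatenate(out_times) if out_times
                   else np.empty(0, dtype=np.float64))
        rec = SpikeRecord.single_trial(neuron, time_ms,
                                       meta={"dt_ms": dt,
                                             "duration_ms": duration_ms})
        if v_trace is not None:
            rec.meta["v_trace"] = np.array(v_trace)
        return rec


def run_trial(network: Network, input_spikes: SpikeRecord | None,
              duration_ms: float, dt_ms: float, plasticity_on: bool = False,
              plasticity: PlasticityParams | None = None) -> SpikeRecord:
    """Convenience wrapper: build a :class:`Simulator` and run one trial."""
    sim = Simulator(network, dt_ms, plasticity)
    return sim.run_trial(input_spikes, duration_ms, plasticity_on=plasticity_on)
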