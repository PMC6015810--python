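"""Trace-based STDP for plastic excitatory->excitatory synapses.

Two exponentially decaying traces drive the rule:

* ``C_ij`` (per plastic synapse) models the concentration of neurotransmitter
  released into the cleft; it is driven up by presynaptic spikes *at their
  arrival time* (emission + axonal delay) via C <- C + alpha_C (1 - C).
* ``D_i`` (per neuron) models the proportion of NMDA receptors unblocked by
  recent depolarization; it is driven up at postsynaptic spikes via
  D <- D + alpha_D (1 - D).

Weights dg in [0, 1] evolve event-wise and multiplicatively:

* at a presynaptic arrival, depression first (using the current post trace):
  dg <- dg - lr * D_i * dg, then the C trace is driven;
* at a postsynaptic spike, potentiation first (using current pre traces):
  dg <- dg + lr * C_ij * (1 - dg), then the D trace is driven.

The saturating trace drive and the multiplicative weight factors keep all
quantities in [0, 1] by construction for 0 <= alpha <= 1.  ``lr`` is the
learning rate rho, or 1/tau_dg under the continuous-time reading (see
:class:`polybind.params.PlasticityParams`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PlasticityParams

__all__ = [
    "TraceState",
    "decay_traces",
    "on_presynaptic_arrival",
    "on_postsynaptic_spike",
    "learning_rate",
]


@dataclass
class TraceState:
    """Presynaptic traces ``c`` (per plastic synapse), postsynaptic ``d``
    (per neuron).  Both lie in [0, 1] and decay toward 0."""

    c: np.ndarray
    d: np.ndarray

    @classmethod
    def zeros(cls, n_synapses: int, n_neurons: int) -> "TraceState":
        return cls(np.zeros(n_synapses), np.zeros(n_neurons))


def learning_rate(params: PlasticityParams) -> float:
    if params.continuous_tau_dg_ms is not None:
        return 1.0 / params.continuous_tau_dg_ms
    return params.rho


def decay_traces(traces: TraceState, dt_ms: float,
                 params: PlasticityParams) -> TraceState:
    """Exponential decay of both traces over one step (in place)."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    traces.c *= np.exp(-dt_ms / params.tau_c_ms)
    traces.d *= np.exp(-dt_ms / params.tau_d_ms)
    return traces


def on_presynaptic_arrival(syn_ids: np.ndarray, post_of_syn: np.ndarray,
                           traces: TraceState, weights: np.ndarray,
                           params: PlasticityParams) -> None:
    """Process presynaptic spike arrivals on plastic synapses (in place).

    Depression is applied first, against the *current* postsynaptic trace,
    then the presynaptic trace is driven up.  Must be invoked at the spike's
    arrival time (emission + delay), not its emission time.
    """
    syn_ids = np.asarray(syn_ids)
    if syn_ids.size == 0:
        return
    lr = learning_rate(params)
    d_post = traces.d[post_of_syn[syn_ids]]
    weights[syn_ids] -= lr * d_post * weights[syn_ids]
    traces.c[syn_ids] += params.alpha_c * (1.0 - traces.c[syn_ids])


def on_postsynaptic_spike(neuron_ids: np.ndarray, afferent_syn_ids: np.ndarray,
                          traces: TraceState, weights: np.ndarray,
                          params: PlasticityParams) -> None:
    """Process postsynaptic spikes (in place).

    ``afferent_syn_ids`` lists the plastic afferent synapses of the spiking
    neurons.  Potentiation is applied first against the current presynaptic
    traces, then the postsynaptic traces are driven up.
    """
    neuron_ids = np.asarray(neuron_ids)
    afferent_syn_ids = np.asarray(afferent_syn_ids)
    lr = learning_rate(params)
    if afferent_syn_ids.size:
        w = weights[afferent_syn_ids]
        weights[afferent_syn_ids] = w + lr * traces.c[afferent_syn_ids] * (1.0 - w)
    if neuron_ids.size:
        traces.d[neuron_ids] += params.alpha_d * (1.0 - traces.d[neuron_ids])
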