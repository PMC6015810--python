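"""Network performance statistics.

Four analyses quantify what the trained network represents:

* single-cell stimulus-specific information carried by binned firing rates,
  I(s, R) = sum_r P(r|s) log2[P(r|s) / P(r)], with ceiling log2(n_stimuli);
* spike-pair polychronous-group (PNG) information: for every ordered neuron
  pair (i, j) and 1 ms interval bin d in [0, 10) ms, the probability across
  transforms that i spikes in bin d after a spike of j, fed through the same
  information formula as a binary response;
* first-spike precision: mean and sample standard deviation of first-spike
  times across repeated presentations, restricted to neurons responding in
  every trial;
* binding-circuit detection: ordered triples (low, high, binder) of strong
  synapses whose delays satisfy delta(3,1) ~= delta(2,1) + delta(3,2), plus
  a dynamical probe of the binder's fire-iff-causally-driven contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .builder import ConnectionGroup, LayerSpec, Network
from .params import EXCITATORY, SynapseClassParams
from .records import SpikeRecord

__all__ = [
    "ResponseTable",
    "InfoResult",
    "PairPNGTable",
    "BindingCircuitRecord",
    "ProbeConfig",
    "bin_responses",
    "max_information",
    "stimulus_specific_information",
    "binary_information",
    "build_pair_png_table",
    "pair_png_information",
    "first_spike_statistics",
    "find_binding_circuits",
    "verify_binding_behavior",
]


# ---------------------------------------------------------------------------
# single-cell rate information

@dataclass
class ResponseTable:
    """Firing rate (Hz) per (cell, stimulus, transform), plus the discretized
    response labels after binning."""

    rates: np.ndarray                       # (n_cells, n_stim, n_transforms)
    cell_ids: np.ndarray | None = None
    stimuli: tuple[str, ...] | None = None
    binned: np.ndarray | None = None        # same shape, int labels
    n_bins: int | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (n_cells, n_stimuli, n_transforms)")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.rates.shape[0])


def bin_responses(table: ResponseTable, n_bins: int = 10) -> ResponseTable:
    """Discretize each cell's rates into equal-width bins over [0, max rate].

    Bins are (low, high] with zero rate pinned to bin 0, so a rate exactly on
    an interior boundary falls in the lower bin and the cell's maximum lands
    in the top bin.  A silent cell maps entirely to bin 0.  Idempotent for
    already-binned integer labels re-binned with the same n_bins.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    r = table.rates
    peak = r.max(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        lab = np.ceil(r / peak * n_bins) - 1
    lab = np.where((peak > 0) & (r > 0), lab, 0.0)
    lab = np.clip(lab, 0, n_bins - 1).astype(np.int64)
    return replace(table, binned=lab, n_bins=n_bins)


def max_information(n_stimuli: int) -> float:
    """Ceiling on the information a single response can carry (bits)."""
    return float(np.log2(n_stimuli))


def _information_from_conditionals(p_r_given_s: np.ndarray) -> np.ndarray:
    """I(s, R) for each leading index; ``p_r_given_s`` has shape
    (..., n_stim, n_levels) and sums to 1 over the last axis.  The marginal
    P(r) weights stimuli uniformly."""
    p_r = p_r_given_s.mean(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p_r_given_s * np.log2(p_r_given_s / p_r)
    terms = np.where(p_r_given_s > 0, terms, 0.0)
    return terms.sum(axis=-1)


@dataclass
class InfoResult:
    """Per cell: information per stimulus (bits), its maximum over stimuli,
    and the descending rank order used for the ranked-information plots."""

    info: np.ndarray          # (n_cells, n_stim)
    cell_ids: np.ndarray
    stimuli: tuple[str, ...] | None = None

    @property
    def max_info(self) -> np.ndarray:
        return self.info.max(axis=1)

    @property
    def order(self) -> np.ndarray:
        return np.argsort(-self.max_info, kind="stable")

    def count_at_ceiling(self, n_stimuli: int, tol: float = 1e-9) -> int:
        return int(np.sum(self.max_info >= max_information(n_stimuli) - tol))

    def to_frame(self) -> pd.DataFrame:
        cols = {f"bits_{s}": self.info[:, k]
                for k, s in enumerate(self.stimuli or
                                      range(self.info.shape[1]))}
        df = pd.DataFrame({"cell_id": self.cell_ids, **cols,
                           "bits_max": self.max_info})
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def stimulus_specific_information(table: ResponseTable) -> InfoResult:
    """Stimulus-specific information per cell and stimulus from the binned
    response table (transforms are the samples behind P(r|s))."""
    if table.binned is None:
        raise ValueError("bin_responses must be applied first")
    if table.rates.size == 0:
        raise ValueError("empty response table")
    n_cells, n_stim, n_t = table.binned.shape
    if n_stim < 2:
        raise ValueError("need at least two stimuli")
    n_levels = int(table.binned.max()) + 1
    onehot = (table.binned[..., None] ==
              np.arange(n_levels)).astype(np.float64)
    p_r_given_s = onehot.mean(axis=2)  # (n_cells, n_stim, n_levels)
    info = _information_from_conditionals(p_r_given_s)
    return InfoResult(info=info, cell_ids=table.cell_ids,
                      stimuli=table.stimuli)


def binary_information(presence: np.ndarray) -> np.ndarray:
    """I(s, R) for binary responses; ``presence`` is boolean with shape
    (..., n_stim, n_transforms).  Returns (..., n_stim) bits."""
    p1 = presence.mean(axis=-1)
    p_r_given_s = np.stack([1.0 - p1, p1], axis=-1)
    return _information_from_conditionals(p_r_given_s)


# ---------------------------------------------------------------------------
# spike-pair PNG information

@dataclass
class PairPNGTable:
    """Spike-pair occurrence across transforms.

    ``presence[i, j, d, s, t]`` is True when neuron ``neurons[i]`` emitted a
    spike within interval bin d (1 ms bins over [0, window) ms) after some
    spike of ``neurons[j]`` during transform t of stimulus s.  The
    per-stimulus occurrence probability is the mean over transforms.
    """

    presence: np.ndarray
    neurons: np.ndarray
    stimuli: tuple[str, ...]
    window_ms: float = 10.0
    n_bins: int = 10

    def probabilities(self) -> np.ndarray:
        """(i, j, d, s) occurrence probability across transforms."""
        return self.presence.mean(axis=-1)


def build_pair_png_table(records_by_stimulus: dict[str, list[SpikeRecord]],
                         neurons, window_ms: float = 10.0,
                         n_bins: int = 10) -> PairPNGTable:
    """Tabulate spike-pair occurrences for every ordered neuron pair.

    ``records_by_stimulus`` maps stimulus label -> one onset-aligned
    single-trial record per transform.  Pair occurrence is binary per
    transform; an interval of exactly ``window_ms`` or more never counts.
    """
    neurons = np.asarray(neurons, dtype=np.int64)
    stimuli = tuple(records_by_stimulus)
    n_transforms = len(records_by_stimulus[stimuli[0]])
    n_sel = neurons.size
    sel_of = {int(n): k for k, n in enumerate(neurons)}
    bin_width = window_ms / n_bins

    presence = np.zeros((n_sel, n_sel, n_bins, len(stimuli), n_transforms),
                        dtype=bool)
    for s_idx, s in enumerate(stimuli):
        recs = records_by_stimulus[s]
        if len(recs) != n_transforms:
            raise ValueError("every stimulus needs the same transform count")
        for t_idx, rec in enumerate(recs):
            keep = np.isin(rec.neuron, neurons)
            ts = rec.time_ms[keep]
            ns = rec.neuron[keep]
            order = np.argsort(ts, kind="stable")
            ts, ns = ts[order], ns[order]
            if ts.size == 0:
                continue
            sel_idx = np.array([sel_of[int(n)] for n in ns], dtype=np.int64)
            lo = np.searchsorted(ts, ts, side="left")
            hi = np.searchsorted(ts, ts + window_ms, side="left")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            j_rep = np.repeat(sel_idx, counts)
            t_rep = np.repeat(ts, counts)
            starts = np.repeat(lo, counts)
            pos = (np.arange(total)
                   - np.repeat(np.cumsum(counts) - counts, counts) + starts)
            i_idx = sel_idx[pos]
            d = np.floor((ts[pos] - t_rep) / bin_width).astype(np.int64)
            ok = (i_idx != j_rep) & (d >= 0) & (d < n_bins)
            flat = (i_idx[ok] * n_sel + j_rep[ok]) * n_bins + d[ok]
            view = presence[..., s_idx, t_idx].reshape(-1)
            view[np.unique(flat)] = True
    return PairPNGTable(presence=presence, neurons=neurons, stimuli=stimuli,
                        window_ms=window_ms, n_bins=n_bins)


def pair_png_information(table: PairPNGTable) -> np.ndarray:
    """Stimulus information per (i, j, d) spike pair, maximum over stimuli
    (bits); computed from the binary occurrence table."""
    info = binary_information(table.presence)   # (i, j, d, s)
    return info.max(axis=-1)


# ---------------------------------------------------------------------------
# first-spike precision

def first_spike_statistics(record: SpikeRecord,
                           neurons=None) -> pd.DataFrame:
    """First-spike mean and sample (n-1) standard deviation per neuron.

    Only neurons that responded (>= 1 spike) in *every* trial of the record
    are included; returns a DataFrame indexed by neuron with columns
    ``n_trials``, ``mean_ms`` and ``std_ms``.
    """
    trials = record.trials()
    if trials.size < 2:
        raise ValueError("need at least two trials")
    df = record.to_frame()
    if neurons is not None:
        df = df[df["neuron_id"].isin(np.asarray(neurons))]
    if df.empty:
        return pd.DataFrame(columns=["n_trials", "mean_ms", "std_ms"])
    first = (df.groupby(["neuron_id", "trial"])["time_ms"].min()
             .unstack("trial").reindex(columns=trials))
    full = first.dropna(axis=0, how="any")
    out = pd.DataFrame({
        "n_trials": trials.size,
        "mean_ms": full.mean(axis=1),
        "std_ms": full.std(axis=1, ddof=1),
    })
    out.index.name = "neuron_id"
    return out


# ---------------------------------------------------------------------------
# binding circuits

@dataclass(frozen=True)
class BindingCircuitRecord:
    """A delay-consistent strong triple: low-level neuron 1, high-level
    neuron 2 and binder 3 with delays d21 (1->2), d31 (1->3), d32 (2->3)."""

    low: int
    high: int
    binder: int
    d21_ms: float
    d31_ms: float
    d32_ms: float
    layers: tuple[int, int, int] = (0, 0, 0)

    @property
    def residual_ms(self) -> float:
        return abs(self.d31_ms - (self.d21_ms + self.d32_ms))


def find_binding_circuits(network: Network,
                          weight_threshold: float | None = None,
                          delay_tolerance_ms: float = 1.0,
                          ) -> list[BindingCircuitRecord]:
    """All ordered triples (1, 2, 3) of plastic synapses 1->2, 1->3, 2->3
    whose weights reach the threshold and whose delays satisfy
    |d31 - (d21 + d32)| <= tolerance.

    The default threshold is half the maximum plastic weight.  With multiple
    contacts per pair, every delay combination that satisfies the relation
    is reported.
    """
    con = network.connections
    plastic = con.plastic
    if weight_threshold is None:
        weight_threshold = 0.5 * (con.weight[plastic].max()
                                  if plastic.any() else 1.0)
    strong = np.flatnonzero(plastic & (con.weight >= weight_threshold))
    pre, post, delay = con.pre[strong], con.post[strong], con.delay_ms[strong]

    out_edges: dict[int, list[tuple[int, float]]] = {}
    direct: dict[tuple[int, int], list[float]] = {}
    for p, q, d in zip(pre, post, delay):
        out_edges.setdefault(int(p), []).append((int(q), float(d)))
        direct.setdefault((int(p), int(q)), []).append(float(d))

    found: list[BindingCircuitRecord] = []
    for n1, edges1 in out_edges.items():
        for n2, d21 in edges1:
            if n2 == n1:
                continue
            for n3, d32 in out_edges.get(n2, ()):
                if n3 in (n1, n2):
                    continue
                for d31 in direct.get((n1, n3), ()):
                    if abs(d31 - (d21 + d32)) <= delay_tolerance_ms:
                        found.append(BindingCircuitRecord(
                            low=n1, high=n2, binder=n3,
                            d21_ms=d21, d31_ms=d31, d32_ms=d32,
                            layers=(int(network.layer_of[n1]),
                                    int(network.layer_of[n2]),
                                    int(network.layer_of[n3]))))
    return found


def binding_circuits_frame(circuits: list[BindingCircuitRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "low": c.low, "high": c.high, "binder": c.binder,
        "d21_ms": c.d21_ms, "d31_ms": c.d31_ms, "d32_ms": c.d32_ms,
        "residual_ms": c.residual_ms,
        "layer_low": c.layers[0], "layer_high": c.layers[1],
        "layer_binder": c.layers[2],
    } for c in circuits])


@dataclass(frozen=True)
class ProbeConfig:
    """Configuration of the dynamical binding probe.

    The probe embeds the triple in an isolated circuit with fast synaptic
    time constants so the binder acts as a coincidence detector: one
    afferent volley peaks ~12 mV below threshold, two volleys within the
    ~6 ms summation window fire it.  External drive and the 1 -> 2 path use
    a 0.5 ms conductance so each drive volley elicits exactly one spike.
    Non-causal offsets must lie beyond the summation window (>= ~8 ms).
    """

    tau_g_ms: float = 2.0               # binder afferents
    drive_tau_g_ms: float = 0.5         # external drive and 1->2 path
    dt_ms: float = 0.02
    drive_scale_ns: float = 400.0
    coincidence_scale_ns: float = 60.0  # each binder afferent
    noncausal_offsets_ms: tuple[float, ...] = (-12.0, -9.0, 9.0, 12.0)
    onset_ms: float = 5.0
    #: allowance around t1 + d31 for the binder spike; covers the binder's
    #: own integration latency (a near-threshold crossing takes a few ms)
    fire_tolerance_ms: float = 4.0


def _build_probe_network(circuit: BindingCircuitRecord,
                         probe: ProbeConfig) -> tuple[Network, int]:
    """Isolated runnable circuit: inputs X1, X2 drive neurons 1 and 2; the
    triple's delays are copied exactly.  Returns (network, index of the
    1->2 synapse) so the causal path can be toggled."""
    classes = {
        "probe_drive": SynapseClassParams(
            tau_g_ms=probe.drive_tau_g_ms, reversal_mv=0.0,
            g_scale_ns=probe.drive_scale_ns, plastic=False),
        "probe_coinc": SynapseClassParams(
            tau_g_ms=probe.tau_g_ms, reversal_mv=0.0,
            g_scale_ns=probe.coincidence_scale_ns, plastic=False),
    }
    # neurons: 0 = X1, 1 = X2 (inputs); 2, 3, 4 = low, high, binder
    pre = np.array([0, 1, 2, 2, 3])
    post = np.array([2, 3, 3, 4, 4])
    weight = np.ones(5)
    delay = np.array([0.1, 0.1, circuit.d21_ms, circuit.d31_ms,
                      circuit.d32_ms])
    cls = np.array([0, 0, 0, 1, 1], dtype=np.int16)
    group = ConnectionGroup(pre, post, weight, delay, cls,
                            ("probe_drive", "probe_coinc"), classes)
    layer_of = np.array([0, 0, 1, 2, 2])
    net = Network(
        layers={"input": LayerSpec(1, 2, "input"),
                "circuit": LayerSpec(1, 3, "excitatory")},
        populations={"input": np.array([0, 1]),
                     "circuit": np.array([2, 3, 4])},
        layer_of=layer_of,
        is_input=layer_of == 0,
        neuron_class=np.zeros(5, dtype=np.int16),
        classes=(EXCITATORY,),
        connections=group,
        meta={"model": "binding_probe"},
    )
    return net, 2  # synapse index of the 1->2 path


def verify_binding_behavior(circuit: BindingCircuitRecord,
                            probe: ProbeConfig = ProbeConfig()) -> bool:
    """Dynamical test of the binder's fire-iff contract.

    Returns True iff (a) under causal drive (input volley fires neuron 1,
    whose spike drives neuron 2) the binder fires within the tolerance of
    its predicted time t1 + d31, and (b) the binder stays silent when
    neurons 1 and 2 are driven independently at every non-causal offset,
    and when neuron 2 is driven alone.
    """
    from .simulator import Simulator  # local import to avoid a cycle

    net, path_idx = _build_probe_network(circuit, probe)
    sim = Simulator(net, probe.dt_ms)
    t0 = probe.onset_ms
    horizon = t0 + circuit.d21_ms + circuit.d31_ms + circuit.d32_ms + 30.0

    def present(x1_times, x2_times, causal_path: bool) -> SpikeRecord:
        net.connections.weight[path_idx] = 1.0 if causal_path else 0.0
        units = [0] * len(x1_times) + [1] * len(x2_times)
        times = np.array(list(x1_times) + list(x2_times))
        shift = max(0.0, -times.min(initial=0.0))  # offsets may be negative
        rec = SpikeRecord.single_trial(np.array(units, dtype=np.int64),
                                       times + shift)
        return sim.run_trial(rec, duration_ms=horizon + shift)

    # (a) causal drive
    rec = present([t0], [], causal_path=True)
    t1 = rec.time_ms[rec.neuron == 2]
    t3 = rec.time_ms[rec.neuron == 4]
    if t1.size == 0 or t3.size == 0:
        return False
    predicted = t1[0] + circuit.d31_ms
    if not np.any(np.abs(t3 - predicted) <= probe.fire_tolerance_ms):
        return False

    # (b) independent, non-causal drive
    for off in probe.noncausal_offsets_ms:
        rec = present([t0], [t0 + circuit.d21_ms + off], causal_path=False)
        if np.any(rec.neuron == 4):
            return False
    rec = present([], [t0], causal_path=False)  # neuron 1 silent
    return not np.any(rec.neuron == 4)
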