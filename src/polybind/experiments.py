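"""Reproducible experiment drivers.

Each driver builds a network from a config, runs the pre-test / training /
post-test schedule with per-role child seeds, and returns a
:class:`RunResult` holding the rasters, the derived statistics and a config
snapshot.  State (membrane, conductances, traces, pending deliveries) is
reset between presentations; only the plastic weights persist.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (InfoResult, PairPNGTable, ResponseTable, bin_responses,
                       build_pair_png_table, max_information,
                       pair_png_information, stimulus_specific_information)
from .builder import FourLayerSpec, Network, build_four_layer, build_two_layer
from .config import (ROLE_TEST, ROLE_TRAIN, ExperimentConfig, child_seed,
                     four_layer_defaults, two_layer_defaults)
from .params import PlasticityParams
from .records import SpikeRecord
from .simulator import Simulator
from .stimuli import (encode_image, generate_poisson_trains,
                      make_flat_stimulus, make_shape_image)
from .analysis import first_spike_statistics

logger = logging.getLogger(__name__)

__all__ = [
    "RunResult",
    "run_two_layer_polychronization",
    "run_synchrony_control",
    "run_four_layer_training",
    "run_stdp_timeconstant_sweep",
    "run_multicontact_comparison",
]

CEILING_TOL_BITS = 1e-6
#: reporting threshold for "highly informative" cells/pairs (bits); the
#: exact ceiling additionally requires responding in every transform of the
#: preferred stimulus and never otherwise
HIGH_INFO_BITS = 1.0


@dataclass
class RunResult:
    """Rasters, statistics and provenance of one experiment run."""

    config: ExperimentConfig
    records: dict[str, SpikeRecord] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    network: Network | None = None

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.write(outdir / "config.txt")
        for name, rec in self.records.items():
            rec.meta.setdefault("seed", self.config.get("seed"))
            rec.meta.setdefault("dt_ms", self.config.get("integration.dt_ms"))
            rec.write_tsv(outdir / f"raster_{name}.tsv")
        for name, obj in self.stats.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"stats_{name}.tsv", sep="\t",
                           float_format="%.6f")
            elif isinstance(obj, InfoResult):
                obj.write_tsv(outdir / f"stats_{name}.tsv")
        manifest = {"summary": _jsonable(self.summary), "flags": self.flags,
                    "records": sorted(self.records),
                    "stats": sorted(self.stats)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _plasticity_from(cfg: ExperimentConfig) -> PlasticityParams:
    return PlasticityParams(
        alpha_c=float(cfg["plasticity.alpha_c"]),
        alpha_d=float(cfg["plasticity.alpha_d"]),
        tau_c_ms=float(cfg["plasticity.tau_c_ms"]),
        tau_d_ms=float(cfg["plasticity.tau_d_ms"]),
        rho=float(cfg["plasticity.rho"]),
    )


# ---------------------------------------------------------------------------
# two-layer polychronization experiments

def _two_layer_network(cfg: ExperimentConfig) -> Network:
    uniform = cfg["architecture.uniform_l2_delay_ms"]
    uniform = float(uniform) if uniform not in ("", None) else None
    return build_two_layer(
        seed=int(cfg["seed"]),
        n_per_layer=int(cfg["architecture.n_per_layer"]),
        p_input_l1=float(cfg["architecture.p_input_l1"]),
        p_l1_l2=float(cfg["architecture.p_l1_l2"]),
        input_delay_range_ms=(float(cfg["architecture.input_delay_low_ms"]),
                              float(cfg["architecture.input_delay_high_ms"])),
        l2_delay_range_ms=(float(cfg["architecture.l2_delay_low_ms"]),
                           float(cfg["architecture.l2_delay_high_ms"])),
        uniform_l2_delay_ms=uniform,
    )


def run_two_layer_polychronization(cfg: ExperimentConfig | dict) -> RunResult:
    """Pre-test, train and post-test the two-layer model on the flat 50 Hz
    all-units-active stimulus; measure first-spike precision per layer.

    The test phases run with plasticity off and matched Poisson seeds, so a
    run with zero training presentations reproduces the pre-test rasters
    exactly in the post-test.
    """
    if not isinstance(cfg, ExperimentConfig):
        cfg = ExperimentConfig.from_defaults(two_layer_defaults(), cfg)
    seed = int(cfg["seed"])
    dt = float(cfg["integration.dt_ms"])
    duration = float(cfg["stimulus.duration_ms"])
    net = _two_layer_network(cfg)
    sim = Simulator(net, dt, _plasticity_from(cfg))
    stim = make_flat_stimulus(int(cfg["architecture.n_per_layer"]),
                              float(cfg["stimulus.rate_hz"]))

    def test_phase(n_trials: int) -> SpikeRecord:
        recs = []
        for i in range(n_trials):
            spikes = generate_poisson_trains(
                stim, duration, np.random.default_rng(child_seed(seed, ROLE_TEST, i)))
            rec = sim.run_trial(spikes, duration, plasticity_on=False)
            rec.trial[:] = i
            recs.append(rec)
        return SpikeRecord.concatenate(recs)

    result = RunResult(config=cfg, network=net)
    result.records["pretest"] = test_phase(int(cfg["schedule.n_pretest"]))

    stdp = bool(cfg["plasticity.stdp_enabled"])
    for i in range(int(cfg["schedule.n_training"])):
        spikes = generate_poisson_trains(
            stim, duration, np.random.default_rng(child_seed(seed, ROLE_TRAIN, i)))
        sim.run_trial(spikes, duration, plasticity_on=stdp)

    result.records["posttest"] = test_phase(int(cfg["schedule.n_posttest"]))

    summary: dict = {}
    for phase in ("pretest", "posttest"):
        rec = result.records[phase]
        for layer in ("exc_1", "exc_2"):
            pop = net.population_of(layer)
            stats = first_spike_statistics(rec, neurons=pop)
            result.stats[f"first_spike_{phase}_{layer}"] = stats
            if stats.empty:
                result.flags.append(f"no all-trial responders in {phase} {layer}")
                continue
            summary[f"{phase}_{layer}_n_responders"] = int(len(stats))
            summary[f"{phase}_{layer}_median_std_ms"] = float(
                stats["std_ms"].median())
            if len(stats) >= 2:
                summary[f"{phase}_{layer}_mean_dispersion_ms"] = float(
                    stats["mean_ms"].std(ddof=1))
    result.summary = summary
    return result


def run_synchrony_control(cfg: ExperimentConfig | dict) -> RunResult:
    """The same protocol with all layer-1 -> layer-2 delays fixed at 1 ms;
    directly comparable with the broad-delay run under matched seeds."""
    if not isinstance(cfg, ExperimentConfig):
        cfg = ExperimentConfig.from_defaults(two_layer_defaults(), cfg)
    cfg = ExperimentConfig.from_defaults(
        dict(cfg), {"architecture.uniform_l2_delay_ms": 1.0})
    return run_two_layer_polychronization(cfg)


# ---------------------------------------------------------------------------
# four-layer visual training experiments

def _four_layer_spec(cfg: ExperimentConfig) -> FourLayerSpec:
    return FourLayerSpec(
        scale=float(cfg["architecture.scale"]),
        include_fb=bool(cfg["architecture.include_fb"]),
        include_lat=bool(cfg["architecture.include_lat"]),
        m_contacts=int(cfg["architecture.m_contacts"]),
    )


def _multi_contact_pairs(net: Network, m: int) -> np.ndarray:
    """Synapse index pairs (n_pairs, m) for pre/post pairs wired with
    exactly ``m`` plastic contacts (pairs further duplicated by
    with-replacement afferent sampling are skipped)."""
    con = net.connections
    plastic = np.flatnonzero(con.plastic)
    key = con.pre[plastic].astype(np.int64) * net.n_neurons + con.post[plastic]
    order = np.argsort(key, kind="stable")
    key, plastic = key[order], plastic[order]
    _, start, counts = np.unique(key, return_index=True, return_counts=True)
    rows = [plastic[s:s + c] for s, c in zip(start, counts) if c == m]
    return (np.array(rows) if rows
            else np.empty((0, m), dtype=np.int64))


def _rate_table(records: dict[str, list[SpikeRecord]], neurons: np.ndarray,
                duration_ms: float) -> ResponseTable:
    stimuli = tuple(records)
    n_t = len(records[stimuli[0]])
    rates = np.zeros((neurons.size, len(stimuli), n_t))
    index = {int(n): k for k, n in enumerate(neurons)}
    for s_idx, s in enumerate(stimuli):
        for t_idx, rec in enumerate(records[s]):
            keep = np.isin(rec.neuron, neurons)
            ids, counts = np.unique(rec.neuron[keep], return_counts=True)
            for nid, c in zip(ids, counts):
                rates[index[int(nid)], s_idx, t_idx] = c * 1000.0 / duration_ms
    return ResponseTable(rates=rates, cell_ids=neurons, stimuli=stimuli)


def run_four_layer_training(cfg: ExperimentConfig | dict) -> RunResult:
    """Train the four-layer model on the circle/heart/star set and measure
    output-layer stimulus information in rates and in spike pairs.

    Training presents the stimuli repeatedly in turn with plasticity on;
    testing presents each stimulus across independent Poisson transforms
    with plasticity off.  The rate code and the spike-pair PNG code of the
    layer-4 excitatory population are analysed for the pre-test (if enabled)
    and the post-test.
    """
    if not isinstance(cfg, ExperimentConfig):
        cfg = ExperimentConfig.from_defaults(four_layer_defaults(), cfg)
    seed = int(cfg["seed"])
    dt = float(cfg["integration.dt_ms"])
    duration = float(cfg["stimulus.duration_ms"])
    labels = tuple(str(cfg["stimulus.labels"]).split(","))
    n_test = int(cfg["schedule.n_test_transforms"])
    spec = _four_layer_spec(cfg)
    net = build_four_layer(seed, spec)
    sim = Simulator(net, dt, _plasticity_from(cfg))
    out_pop = net.population_of("exc_4")

    rate_maps = {
        label: encode_image(make_shape_image(label, size=spec.retina_n),
                            max_rate_hz=float(cfg["stimulus.max_rate_hz"]),
                            label=label)
        for label in labels
    }

    result = RunResult(config=cfg, network=net)
    contact_pairs = (_multi_contact_pairs(net, spec.m_contacts)
                     if spec.m_contacts > 1 else None)
    if contact_pairs is not None and contact_pairs.size:
        result.summary["initial_contact_weights"] = \
            net.connections.weight[contact_pairs].copy()

    def test_phase(tag: str) -> None:
        recs: dict[str, list[SpikeRecord]] = {}
        for s_idx, label in enumerate(labels):
            recs[label] = []
            for t in range(n_test):
                ss = child_seed(seed, ROLE_TEST, s_idx * 1000 + t)
                spikes = generate_poisson_trains(rate_maps[label], duration,
                                                 np.random.default_rng(ss))
                recs[label].append(sim.run_trial(spikes, duration,
                                                 plasticity_on=False))
        for label in labels:
            result.records[f"{tag}_{label}"] = SpikeRecord.concatenate(
                [r for r in (_with_trial(rec, t)
                             for t, rec in enumerate(recs[label]))])
        table = bin_responses(_rate_table(recs, out_pop, duration),
                              n_bins=int(cfg["analysis.n_rate_bins"]))
        info = stimulus_specific_information(table)
        result.stats[f"rate_info_{tag}"] = info
        pair_table = build_pair_png_table(recs, out_pop)
        pair_info = pair_png_information(pair_table)
        ceiling = max_information(len(labels)) - CEILING_TOL_BITS
        result.summary[f"{tag}_rate_ceiling_cells"] = int(
            np.sum(info.max_info >= ceiling))
        result.summary[f"{tag}_pair_ceiling_pairs"] = int(
            np.sum(pair_info >= ceiling))
        result.summary[f"{tag}_rate_highinfo_cells"] = int(
            np.sum(info.max_info >= HIGH_INFO_BITS))
        result.summary[f"{tag}_pair_highinfo_pairs"] = int(
            np.sum(pair_info >= HIGH_INFO_BITS))
        result.summary[f"{tag}_output_spikes"] = int(sum(
            len(r) and np.isin(r.neuron, out_pop).sum()
            for rs in recs.values() for r in rs))

    if bool(cfg["schedule.pretest"]):
        test_phase("pretest")

    stdp = bool(cfg["plasticity.stdp_enabled"])
    counter = 0
    for _ in range(int(cfg["schedule.n_training_sweeps"])):
        for label in labels:
            ss = child_seed(seed, ROLE_TRAIN, counter)
            counter += 1
            spikes = generate_poisson_trains(rate_maps[label], duration,
                                             np.random.default_rng(ss))
            sim.run_trial(spikes, duration, plasticity_on=stdp)

    test_phase("posttest")
    if contact_pairs is not None and contact_pairs.size:
        result.summary["final_contact_weights"] = \
            net.connections.weight[contact_pairs].copy()
    return result


def _with_trial(rec: SpikeRecord, trial: int) -> SpikeRecord:
    rec.trial[:] = trial
    return rec


def run_stdp_timeconstant_sweep(cfg: ExperimentConfig | dict,
                                taus_ms: tuple[float, ...] = (5.0, 25.0, 125.0),
                                ) -> dict[float, RunResult]:
    """Repeat the four-layer training with tau_C = tau_D swept over the
    published grid {5, 25, 125} ms; everything else byte-identical."""
    if not isinstance(cfg, ExperimentConfig):
        cfg = ExperimentConfig.from_defaults(four_layer_defaults(), cfg)
    results: dict[float, RunResult] = {}
    for tau in taus_ms:
        sub = ExperimentConfig.from_defaults(
            dict(cfg), {"plasticity.tau_c_ms": tau, "plasticity.tau_d_ms": tau})
        results[tau] = run_four_layer_training(sub)
    return results


def run_multicontact_comparison(cfg: ExperimentConfig | dict,
                                contacts: tuple[int, ...] = (1, 2),
                                ) -> dict[int, RunResult]:
    """Compare one vs two synaptic contacts per excitatory pair.

    For M = 2 the result's summary carries initial and final weights of each
    contact pair plus the fraction of strongly driven pairs whose weight gap
    widened during training (plasticity selecting between the two delays).
    """
    if not isinstance(cfg, ExperimentConfig):
        cfg = ExperimentConfig.from_defaults(four_layer_defaults(), cfg)
    results: dict[int, RunResult] = {}
    for m in contacts:
        sub = ExperimentConfig.from_defaults(
            dict(cfg), {"architecture.m_contacts": m})
        res = run_four_layer_training(sub)
        if m > 1 and "final_contact_weights" in res.summary:
            w0 = res.summary["initial_contact_weights"]
            w1 = res.summary["final_contact_weights"]
            # "strongly driven": at least one contact consistently
            # potentiated; weights near the 0.5 equilibrium carry no
            # evidence of consistent causal drive
            driven = w1.max(axis=1) >= 0.9
            gap0 = np.abs(np.diff(w0, axis=1)).ravel()
            gap1 = np.abs(np.diff(w1, axis=1)).ravel()
            if driven.any():
                res.summary["divergent_fraction"] = float(
                    np.mean(gap1[driven] > gap0[driven]))
                res.summary["n_driven_pairs"] = int(driven.sum())
        results[m] = res
    return results
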