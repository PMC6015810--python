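"""Network construction: layers, topographic fan-in wiring, randomized delays.

Two architectures are provided:

* a four-layer model of the ventral visual pathway (V2, V4, TEO, TE): each
  layer holds a grid of excitatory and a grid of inhibitory neurons, wired
  with topographic feedforward, feedback and lateral connections, plastic
  on all excitatory->excitatory classes, with axonal delays drawn uniformly
  from [0.1, 10] ms;
* a two-layer feedforward model (1000-unit Poisson input layer -> layer 1 ->
  layer 2) used to study the emergence of polychronization, with delays
  U[1, 10] ms into layer 1 and U[1, 30] ms into layer 2.

Grid positions map proportionally between layers of different sizes; fan-in
radii are measured in pre-layer grid cells with a Euclidean metric and no
wraparound (a retina has borders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .params import (EXCITATORY, INHIBITORY, SYNAPSE_CLASSES,
                     NeuronClassParams, SynapseClassParams)

logger = logging.getLogger(__name__)

__all__ = [
    "LayerSpec",
    "ConnectionGroup",
    "Network",
    "sample_delays",
    "expand_multi_contact",
    "build_two_layer",
    "build_four_layer",
    "FourLayerSpec",
]

#: default axonal delay range (ms)
DELAY_RANGE_MS = (0.1, 10.0)
#: delay range for extra synaptic contacts between one pre/post pair (ms)
MULTI_CONTACT_DELAY_RANGE_MS = (0.0, 10.0)


@dataclass(frozen=True)
class LayerSpec:
    """One neuron population laid out on a grid (height x width)."""

    height: int
    width: int
    cell_class: str  # "excitatory" | "inhibitory" | "input"

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("population grid dimensions must be positive")

    @property
    def size(self) -> int:
        return self.height * self.width


@dataclass
class ConnectionGroup:
    """Parallel synapse arrays: wiring, weights and delays.

    ``cls`` indexes into ``class_names``; the synapse-class parameter table
    (time constants, reversal potentials, scaling bounds, plastic flags) is
    resolved against :data:`polybind.params.SYNAPSE_CLASSES` unless a custom
    table is attached.
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay_ms: np.ndarray
    cls: np.ndarray
    class_names: tuple[str, ...]
    class_params: dict[str, SynapseClassParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.delay_ms = np.asarray(self.delay_ms, dtype=np.float64)
        self.cls = np.asarray(self.cls, dtype=np.int16)
        n = self.pre.size
        if not (self.post.size == self.weight.size == self.delay_ms.size
                == self.cls.size == n):
            raise ValueError("synapse arrays must be congruent")
        if n and (self.weight.min() < 0 or self.weight.max() > 1):
            raise ValueError("weights must lie in [0, 1]")
        if n and self.delay_ms.min() < 0:
            raise ValueError("delays must be non-negative")

    def __len__(self) -> int:
        return self.pre.size

    def params_for(self, name: str) -> SynapseClassParams:
        if name in self.class_params:
            return self.class_params[name]
        return SYNAPSE_CLASSES[name]

    def per_synapse(self, attr: str) -> np.ndarray:
        """Per-synapse array of a class parameter (e.g. ``tau_g_ms``)."""
        table = np.array([getattr(self.params_for(n), attr)
                          for n in self.class_names], dtype=np.float64)
        return table[self.cls]

    @property
    def plastic(self) -> np.ndarray:
        table = np.array([self.params_for(n).plastic for n in self.class_names])
        return table[self.cls]

    def of_class(self, name: str) -> np.ndarray:
        """Synapse indices belonging to one connection class."""
        code = self.class_names.index(name)
        return np.flatnonzero(self.cls == code)

    @classmethod
    def concatenate(cls, groups: list["ConnectionGroup"]) -> "ConnectionGroup":
        names: list[str] = []
        params: dict[str, SynapseClassParams] = {}
        for g in groups:
            for n in g.class_names:
                if n not in names:
                    names.append(n)
                if n in g.class_params:
                    params[n] = g.class_params[n]
        remap = []
        for g in groups:
            remap.append(np.array([names.index(n) for n in g.class_names],
                                  dtype=np.int16))
        return cls(
            np.concatenate([g.pre for g in groups]),
            np.concatenate([g.post for g in groups]),
            np.concatenate([g.weight for g in groups]),
            np.concatenate([g.delay_ms for g in groups]),
            np.concatenate([m[g.cls] for g, m in zip(groups, remap)]),
            tuple(names),
            params,
        )


@dataclass
class Network:
    """A complete wired model: populations plus one merged connection group."""

    layers: dict[str, LayerSpec]
    populations: dict[str, np.ndarray]  # population name -> neuron indices
    layer_of: np.ndarray                # per neuron: layer number (input = 0)
    is_input: np.ndarray                # per neuron: spike source, not LIF
    neuron_class: np.ndarray            # per neuron: index into classes
    classes: tuple[NeuronClassParams, ...]
    connections: ConnectionGroup
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.layer_of.size

    def population_of(self, name: str) -> np.ndarray:
        return self.populations[name]


def sample_delays(n: int, low_ms: float, high_ms: float,
                  rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. axonal delays, uniform on [low, high] ms."""
    if low_ms < 0 or high_ms < 0:
        raise ValueError("delay bounds must be non-negative")
    if low_ms > high_ms:
        raise ValueError("delay range must satisfy low <= high")
    if low_ms == high_ms:
        return np.full(n, low_ms, dtype=np.float64)
    return rng.uniform(low_ms, high_ms, size=n)


def expand_multi_contact(group: ConnectionGroup, m: int,
                         delay_range_ms: tuple[float, float],
                         rng: np.random.Generator) -> ConnectionGroup:
    """Represent each pre/post pair by ``m`` contacts.

    For ``m == 1`` the group is returned unchanged.  For ``m >= 2`` every
    listed pair appears ``m`` times with independently sampled delays (from
    ``delay_range_ms``) and independent initial weights, so that plasticity
    can select among the different transmission delays.
    """
    if m < 1:
        raise ValueError("contacts per pair must be >= 1")
    if m == 1:
        return group
    n = len(group) * m
    pre = np.tile(group.pre, m)
    post = np.tile(group.post, m)
    cls = np.tile(group.cls, m)
    delays = sample_delays(n, *delay_range_ms, rng=rng)
    weight = rng.uniform(0.0, 1.0, size=n)
    # non-plastic contacts keep their fixed weights
    fixed = ~group.plastic
    if fixed.any():
        weight[np.tile(fixed, m)] = np.tile(group.weight[fixed], m)
        delays[np.tile(fixed, m)] = np.tile(group.delay_ms[fixed], m)
    return ConnectionGroup(pre, post, weight, delays, cls,
                           group.class_names, dict(group.class_params))


def _bernoulli_group(pre_ids: np.ndarray, post_ids: np.ndarray, p: float,
                     delay_range_ms: tuple[float, float], cls_name: str,
                     rng: np.random.Generator,
                     class_params: dict | None = None) -> ConnectionGroup:
    """All-to-all Bernoulli(p) wiring between two populations."""
    mask = rng.random((post_ids.size, pre_ids.size)) < p
    post_idx, pre_idx = np.nonzero(mask)
    n = pre_idx.size
    return ConnectionGroup(
        pre_ids[pre_idx], post_ids[post_idx],
        rng.uniform(0.0, 1.0, size=n),
        sample_delays(n, *delay_range_ms, rng=rng),
        np.zeros(n, dtype=np.int16), (cls_name,),
        class_params or {},
    )


def build_two_layer(seed: int, n_per_layer: int = 1000,
                    p_input_l1: float = 0.2, p_l1_l2: float = 0.02,
                    input_delay_range_ms: tuple[float, float] = (1.0, 10.0),
                    l2_delay_range_ms: tuple[float, float] = (1.0, 30.0),
                    uniform_l2_delay_ms: float | None = None) -> Network:
    """Two-layer feedforward polychronization model.

    1000 Poisson input units project to layer 1 (connection probability 0.2,
    delays U[1, 10] ms), which projects to layer 2 (probability 0.02, delays
    U[1, 30] ms).  All connections are plastic feedforward excitatory; there
    are no inhibitory populations.  ``uniform_l2_delay_ms`` replaces the
    layer-1 -> layer-2 delay distribution with a single value (the synchrony
    control uses 1 ms).
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0)))
    n = n_per_layer
    input_ids = np.arange(0, n)
    l1_ids = np.arange(n, 2 * n)
    l2_ids = np.arange(2 * n, 3 * n)

    if uniform_l2_delay_ms is not None:
        l2_delay_range_ms = (uniform_l2_delay_ms, uniform_l2_delay_ms)
    g_in = _bernoulli_group(input_ids, l1_ids, p_input_l1,
                            input_delay_range_ms, "EfE", rng)
    g_12 = _bernoulli_group(l1_ids, l2_ids, p_l1_l2,
                            l2_delay_range_ms, "EfE", rng)

    layer_of = np.repeat([0, 1, 2], n)
    is_input = layer_of == 0
    return Network(
        layers={
            "input": LayerSpec(1, n, "input"),
            "exc_1": LayerSpec(1, n, "excitatory"),
            "exc_2": LayerSpec(1, n, "excitatory"),
        },
        populations={"input": input_ids, "exc_1": l1_ids, "exc_2": l2_ids},
        layer_of=layer_of,
        is_input=is_input,
        neuron_class=np.zeros(3 * n, dtype=np.int16),
        classes=(EXCITATORY,),
        connections=ConnectionGroup.concatenate([g_in, g_12]),
        meta={"model": "two_layer", "seed": int(seed),
              "uniform_l2_delay_ms": uniform_l2_delay_ms},
    )


@dataclass(frozen=True)
class FourLayerSpec:
    """Build specification for the four-layer ventral-stream model.

    ``scale`` shrinks every grid's linear dimension and scales fan-in counts
    proportionally, so scale = 0.25 gives 16 x 16 excitatory grids with
    feedforward counts {8, 25, 25, 25}.  Full scale (1.0) reproduces the
    published 64 x 64 / 32 x 32 grids and counts {30, 100, 100, 100}.
    """

    scale: float = 1.0
    exc_grid: int = 64
    inh_grid: int = 32
    retina: int = 128
    n_channels: int = 8  # Gabor sublayers: 4 orientations x 2 phases
    ff_counts: tuple[int, ...] = (30, 100, 100, 100)
    ff_radii: tuple[float, ...] = (1.0, 8.0, 12.0, 16.0)
    fb_count: int = 10
    fb_radius: float = 8.0
    lat_count: int = 10
    lat_radius: float = 4.0
    eli_count: int = 30
    eli_radius: float = 1.0
    ile_count: int = 30
    ile_radius: float = 8.0
    include_fb: bool = True
    include_lat: bool = True
    m_contacts: int = 1
    delay_range_ms: tuple[float, float] = DELAY_RANGE_MS
    #: preserve each neuron's mean total synaptic drive when fan-in counts
    #: shrink with the grids: conductance scaling factors are divided by
    #: sqrt(scale), matching the sqrt(scale) fan-in reduction (a standard
    #: in-degree compensation for down-scaled networks)
    compensate_scale: bool = True

    # Fan-in counts and radii shrink with sqrt(scale) rather than scale:
    # fully proportional count scaling would cut each neuron's afferent
    # sample 4x at quarter scale, and the drive compensation would then
    # quadruple unitary conductances; the square-root split keeps both the
    # fan-in sampling noise and the unitary synaptic strength closer to the
    # full-size model.
    def scaled_count(self, c: int) -> int:
        return max(1, int(round(c * self.scale ** 0.5)))

    def scaled_radius(self, r: float) -> float:
        return max(1.0, r * self.scale ** 0.5)

    @property
    def exc_n(self) -> int:
        return max(2, int(round(self.exc_grid * self.scale)))

    @property
    def inh_n(self) -> int:
        return max(1, int(round(self.inh_grid * self.scale)))

    @property
    def retina_n(self) -> int:
        return max(4, int(round(self.retina * self.scale)))


def _grid_positions(n: int) -> np.ndarray:
    """(row, col) coordinates for an n x n grid in index order."""
    rows, cols = np.divmod(np.arange(n * n), n)
    return np.stack([rows, cols], axis=1).astype(np.float64)


def _topographic_group(pre_ids: np.ndarray, pre_grid_n: int,
                       post_grid_n: int, post_ids: np.ndarray,
                       count: int, radius: float, cls_name: str,
                       rng: np.random.Generator, plastic_weights: bool,
                       channels: int = 1,
                       forbid_self: bool = False) -> ConnectionGroup:
    """Sample ``count`` afferents per post neuron within a Euclidean radius.

    ``pre_ids`` must be laid out channel-major over ``channels`` copies of a
    ``pre_grid_n`` x ``pre_grid_n`` grid.  Positions scale proportionally
    between grids; sampling is without replacement when the radius disc holds
    enough candidates, otherwise with replacement (logged).
    """
    pre_pos = _grid_positions(pre_grid_n)
    post_pos = _grid_positions(post_grid_n)
    # map post grid coordinates onto the pre grid
    factor = pre_grid_n / post_grid_n
    mapped = (post_pos + 0.5) * factor - 0.5
    n_cells = pre_grid_n * pre_grid_n

    pres, posts = [], []
    replacement_used = False
    for k, pid in enumerate(post_ids):
        d2 = np.sum((pre_pos - mapped[k]) ** 2, axis=1)
        cells = np.flatnonzero(d2 <= radius * radius + 1e-9)
        if channels > 1:
            cand = (cells[None, :] + n_cells * np.arange(channels)[:, None]).ravel()
        else:
            cand = cells
        cand = pre_ids[cand]
        if forbid_self:
            cand = cand[cand != pid]
        if cand.size == 0:
            raise ValueError(f"no candidate afferents within radius {radius}")
        if cand.size >= count:
            chosen = rng.choice(cand, size=count, replace=False)
        else:
            replacement_used = True
            chosen = rng.choice(cand, size=count, replace=True)
        pres.append(chosen)
        posts.append(np.full(count, pid, dtype=np.int64))
    if replacement_used:
        logger.warning(
            "connection class %s: radius %.2f disc smaller than fan-in %d; "
            "sampled with replacement", cls_name, radius, count)
    pre = np.concatenate(pres)
    post = np.concatenate(posts)
    n = pre.size
    weight = (rng.uniform(0.0, 1.0, size=n) if plastic_weights
              else np.ones(n, dtype=np.float64))
    return ConnectionGroup(pre, post, weight,
                           sample_delays(n, *DELAY_RANGE_MS, rng=rng),
                           np.zeros(n, dtype=np.int16), (cls_name,))


def build_four_layer(seed: int, spec: FourLayerSpec = FourLayerSpec()) -> Network:
    """Four-layer topographic ventral-stream model.

    Layers 1-4 each hold an excitatory and an inhibitory grid.  Feedforward
    excitatory->excitatory connections are always present; feedback and
    lateral excitatory connections are optional.  Excitatory<->inhibitory
    lateral loops implement competition within each layer.  All E->E classes
    are plastic; delays are sampled uniformly from ``spec.delay_range_ms``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0)))
    ne, ni, nr = spec.exc_n, spec.inh_n, spec.retina_n
    n_input = spec.n_channels * nr * nr

    populations: dict[str, np.ndarray] = {}
    layers: dict[str, LayerSpec] = {}
    layer_of_parts, class_parts = [], []
    offset = 0

    populations["input"] = np.arange(offset, offset + n_input)
    layers["input"] = LayerSpec(nr * spec.n_channels, nr, "input")
    layer_of_parts.append(np.zeros(n_input, dtype=np.int64))
    class_parts.append(np.zeros(n_input, dtype=np.int16))
    offset += n_input

    for ell in range(1, 5):
        populations[f"exc_{ell}"] = np.arange(offset, offset + ne * ne)
        layers[f"exc_{ell}"] = LayerSpec(ne, ne, "excitatory")
        layer_of_parts.append(np.full(ne * ne, ell, dtype=np.int64))
        class_parts.append(np.zeros(ne * ne, dtype=np.int16))
        offset += ne * ne
        populations[f"inh_{ell}"] = np.arange(offset, offset + ni * ni)
        layers[f"inh_{ell}"] = LayerSpec(ni, ni, "inhibitory")
        layer_of_parts.append(np.full(ni * ni, ell, dtype=np.int64))
        class_parts.append(np.ones(ni * ni, dtype=np.int16))
        offset += ni * ni

    groups: list[ConnectionGroup] = []
    # feedforward E->E (GfE into layer 1, EfE above)
    for ell in range(1, 5):
        count = spec.scaled_count(spec.ff_counts[ell - 1])
        radius = spec.scaled_radius(spec.ff_radii[ell - 1])
        if ell == 1:
            groups.append(_topographic_group(
                populations["input"], nr, ne, populations["exc_1"],
                count, radius, "GfE", rng, plastic_weights=True,
                channels=spec.n_channels))
        else:
            groups.append(_topographic_group(
                populations[f"exc_{ell - 1}"], ne, ne,
                populations[f"exc_{ell}"], count, radius, "EfE", rng,
                plastic_weights=True))
    # feedback E->E
    if spec.include_fb and spec.fb_count > 0:
        for ell in range(1, 4):
            groups.append(_topographic_group(
                populations[f"exc_{ell + 1}"], ne, ne,
                populations[f"exc_{ell}"],
                spec.scaled_count(spec.fb_count),
                spec.scaled_radius(spec.fb_radius), "EbE", rng,
                plastic_weights=True))
    # lateral E->E
    if spec.include_lat and spec.lat_count > 0:
        for ell in range(1, 5):
            groups.append(_topographic_group(
                populations[f"exc_{ell}"], ne, ne, populations[f"exc_{ell}"],
                spec.scaled_count(spec.lat_count),
                spec.scaled_radius(spec.lat_radius), "ElE", rng,
                plastic_weights=True, forbid_self=True))
    # excitatory -> inhibitory and inhibitory -> excitatory loops
    for ell in range(1, 5):
        groups.append(_topographic_group(
            populations[f"exc_{ell}"], ne, ni, populations[f"inh_{ell}"],
            spec.scaled_count(spec.eli_count),
            spec.scaled_radius(spec.eli_radius), "ElI", rng,
            plastic_weights=False))
        groups.append(_topographic_group(
            populations[f"inh_{ell}"], ni, ne, populations[f"exc_{ell}"],
            spec.scaled_count(spec.ile_count),
            spec.scaled_radius(spec.ile_radius), "IlE", rng,
            plastic_weights=False))

    connections = ConnectionGroup.concatenate(groups)
    if spec.compensate_scale and spec.scale != 1.0:
        from dataclasses import replace as _replace
        connections.class_params = {
            name: _replace(SYNAPSE_CLASSES[name],
                           g_scale_ns=SYNAPSE_CLASSES[name].g_scale_ns
                           / spec.scale ** 0.5)
            for name in connections.class_names
        }
    if spec.m_contacts > 1:
        # duplicate only the plastic E->E contacts
        plastic = connections.plastic
        keep = ConnectionGroup(
            connections.pre[~plastic], connections.post[~plastic],
            connections.weight[~plastic], connections.delay_ms[~plastic],
            connections.cls[~plastic], connections.class_names,
            connections.class_params)
        dup = ConnectionGroup(
            connections.pre[plastic], connections.post[plastic],
            connections.weight[plastic], connections.delay_ms[plastic],
            connections.cls[plastic], connections.class_names,
            connections.class_params)
        dup = expand_multi_contact(dup, spec.m_contacts,
                                   MULTI_CONTACT_DELAY_RANGE_MS, rng)
        connections = ConnectionGroup.concatenate([keep, dup])

    layer_of = np.concatenate(layer_of_parts)
    return Network(
        layers=layers,
        populations=populations,
        layer_of=layer_of,
        is_input=layer_of == 0,
        neuron_class=np.concatenate(class_parts),
        classes=(EXCITATORY, INHIBITORY),
        connections=connections,
        meta={"model": "four_layer", "seed": int(seed), "spec": spec},
    )
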