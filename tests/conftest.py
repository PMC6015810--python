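import logging

import numpy as np
import pytest

from polybind.builder import ConnectionGroup, Network
from polybind.params import EXCITATORY, NeuronClassParams, SynapseClassParams

logging.getLogger("polybind").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_single_cell(g_scale_ns=10.0, tau_g_ms=1e12, delay_ms=0.1,
                     v_thresh_mv=-53.0, weight=1.0, plastic=False):
    """One input unit driving one LIF cell through a single synapse.

    A huge tau_g turns a single arrival into a held (constant) conductance,
    which makes the closed-form steady state and inter-spike-interval
    oracles exact.
    """
    cell = NeuronClassParams(500.0, 25.0, -74.0, v_thresh_mv, -57.0, 2.0,
                             "excitatory")
    classes = {"drive": SynapseClassParams(tau_g_ms, 0.0, g_scale_ns, plastic)}
    group = ConnectionGroup(np.array([0]), np.array([1]), np.array([weight]),
                            np.array([delay_ms]), np.zeros(1, np.int16),
                            ("drive",), classes)
    layer_of = np.array([0, 1])
    return Network(layers={}, populations={"cell": np.array([1])},
                   layer_of=layer_of, is_input=layer_of == 0,
                   neuron_class=np.zeros(2, np.int16), classes=(cell,),
                   connections=group, meta={})


@pytest.fixture
def single_cell_factory():
    return make_single_cell
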