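import numpy as np
import pandas as pd
import pytest

from hairplate.circuits import SynapseGraph
from hairplate.io import NeuronRecord


def toy_annotations(premotor_nt="acetylcholine"):
    return [
        NeuronRecord("hp1", "sensory", hair_plate="HP"),
        NeuronRecord("p", "premotor", hemilineage="20A", neurotransmitter=premotor_nt),
        NeuronRecord("m1", "motor", motor_module=1),
        NeuronRecord("bgp", "other"),
        NeuronRecord("bgm", "other"),
    ]


def toy_edges():
    # HP -> module: 20 of 200 total module input (w1 = 0.1)
    # HP -> p: 25 of p's 50 inputs; p -> module: 40 of 200 (w2 = +-0.1)
    return pd.DataFrame(
        [
            ("hp1", "m1", 20),
            ("hp1", "p", 25),
            ("bgp", "p", 25),
            ("p", "m1", 40),
            ("bgm", "m1", 140),
        ],
        columns=["pre_id", "post_id", "n_synapses"],
    )


@pytest.fixture
def toy_graph():
    """Hand-computable circuit: w1 = 0.1, excitatory w2 = +0.1."""
    return SynapseGraph(toy_edges(), toy_annotations())


@pytest.fixture
def toy_graph_inhibitory():
    return SynapseGraph(toy_edges(), toy_annotations("GABA"))
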