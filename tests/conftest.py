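import numpy as np
import pandas as pd
import pytest

from neuroperc import make_fixture_graphs, make_synthetic_connectome
from neuroperc.connectome import build_connectome
from neuroperc.synthetic import ConnectomeSpec


@pytest.fixture(scope="session")
def fixtures():
    return make_fixture_graphs()


def connectome_from_edges(edge_rows, n_neurons=None, regions=None):
    """Build a small connectome from (pre, post, synapse_count) triples."""
    ids = sorted({e[0] for e in edge_rows} | {e[1] for e in edge_rows})
    if n_neurons is not None:
        ids = sorted(set(ids) | set(range(n_neurons)))
    rng = np.random.default_rng(0)
    nodes = pd.DataFrame(
        {
            "neuron_id": ids,
            "region": regions if regions is not None else [0] * len(ids),
            "x_nm": rng.uniform(0, 1e5, len(ids)),
            "y_nm": rng.uniform(0, 1e5, len(ids)),
            "z_nm": rng.uniform(0, 1e5, len(ids)),
        }
    )
    edges = pd.DataFrame(edge_rows, columns=["pre_id", "post_id", "synapse_count"])
    return build_connectome(nodes, edges)


@pytest.fixture(scope="session")
def chain_connectome():
    """A -> B (2 synapses), B -> C (1 synapse)."""
    return connectome_from_edges([(0, 1, 2), (1, 2, 1)])


@pytest.fixture(scope="session")
def small_synthetic():
    """120-neuron heavy-tailed connectome for dynamics tests."""
    return make_synthetic_connectome(ConnectomeSpec(n_neurons=120, seed=42))


@pytest.fixture(scope="session")
def medium_synthetic():
    """500-neuron connectome matching the default study conditions."""
    return make_synthetic_connectome(ConnectomeSpec(n_neurons=500, seed=7))
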