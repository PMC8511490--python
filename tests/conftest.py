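import numpy as np
import pytest

from unibrainnet import PlantedModel, contiguous_blocks, make_toy_graph


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def small_model():
    """Two-community planted model small enough for fast solver runs."""
    return PlantedModel(
        n_regions=20,
        n_timepoints=60,
        rank=4,
        blocks=contiguous_blocks(20, 2),
        noise_sd=0.05,
        fiber_scale=50.0,
        seed=11,
    )


# Directed five-node graph where the in-neighbors of node A are {B, C, E},
# the in-neighbors of B are {A, D}, out-degrees are A:3, B:2, C:2, D:1, E:2;
# strongly connected, so the simplified PageRank has a unique fixed point.
FIVE_NODE_EDGES = [
    (0, 1), (0, 2), (0, 4),  # A -> B, C, E
    (1, 0), (1, 3),          # B -> A, D
    (2, 0), (2, 3),          # C -> A, D
    (3, 1),                  # D -> B
    (4, 0), (4, 3),          # E -> A, D
]


@pytest.fixture
def five_node_graph():
    return make_toy_graph(5, FIVE_NODE_EDGES)
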