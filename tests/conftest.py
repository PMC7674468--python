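from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from dicn import build_graph, five_node_example, train_probe_example

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy():
    """The five-node worked-example graph (edges 1-2, 2-3, 2-5, 3-4)."""
    return five_node_example().graph()


@pytest.fixture
def split_example():
    """(training graph, probe label pair, negative label pairs) of the
    evaluation worked example."""
    fx, probe, negatives = train_probe_example()
    return fx.graph(), probe, negatives


@st.composite
def edge_lists(draw, max_nodes=8):
    """Random simple-graph edge lists over integer-string labels."""
    n = draw(st.integers(min_value=2, max_value=max_nodes))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = draw(
        st.lists(st.sampled_from(pairs), unique=True, max_size=len(pairs))
    )
    return n, [(str(i), str(j)) for i, j in chosen]


@pytest.fixture
def make_graph():
    def _make(n, edges):
        return build_graph(edges, nodes=[str(k) for k in range(n)])

    return _make
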