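"""Built-in worked-example fixtures and seeded synthetic-graph generators.

The worked examples are tiny networks small enough to score by hand; their
annotated expected values anchor the golden-value tests and the acceptance
checks, so every module is testable without downloading any benchmark
network.  The random generators emulate the two structural regimes the
benchmark networks span: homogeneous-degree (Erdős–Rényi) and heavy-tailed
(preferential attachment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import networkx as nx

from .graph import Graph, build_graph

LabelPair = tuple[Hashable, Hashable]


@dataclass(frozen=True)
class FixtureSpec:
    """A named edge list plus hand-computed expected values."""

    name: str
    nodes: tuple[Hashable, ...]
    edges: tuple[LabelPair, ...]
    annotations: dict[str, object] = field(default_factory=dict)

    def graph(self) -> Graph:
        return build_graph(self.edges, nodes=self.nodes)


def five_node_example() -> FixtureSpec:
    """The five-node worked example: edges {1-2, 2-3, 2-5, 3-4}.

    Node 2 is the hub; 4 and 5 are leaves with no common neighbour but a
    latent second-order relationship through 2 and 3.
    """
    return FixtureSpec(
        name="five_node_example",
        nodes=("1", "2", "3", "4", "5"),
        edges=(("1", "2"), ("2", "3"), ("2", "5"), ("3", "4")),
        annotations={
            "n_nodes": 5,
            "n_edges": 4,
            "non_existing": {
                ("1", "3"), ("1", "4"), ("1", "5"),
                ("2", "4"), ("3", "5"), ("4", "5"),
            },
            "degree_sequence_sorted": [1, 1, 1, 2, 3],
            "cn_24": 1,
            "cn_45": 0,
        },
    )


def train_probe_example() -> tuple[FixtureSpec, LabelPair, set[LabelPair]]:
    """The evaluation worked example: the five-node graph plus probe edge
    (3,5), i.e. the full network {1-2, 2-3, 2-5, 3-4, 3-5} split 80/20.

    Returns (training fixture, probe edge, non-existing negatives).  The
    hand-computed DICN scores and exhaustive AUC (n1=3, n2=1, AUC=0.7) are
    in the training fixture's annotations.
    """
    training = FixtureSpec(
        name="train_probe_example_training",
        nodes=("1", "2", "3", "4", "5"),
        edges=(("1", "2"), ("2", "3"), ("2", "5"), ("3", "4")),
        annotations={
            "dicn_scores_2dp": {
                ("3", "5"): 2.5,
                ("1", "3"): 2.5,
                ("1", "4"): 0.59,
                ("1", "5"): 2.0,
                ("2", "4"): 2.82,
                ("4", "5"): 0.59,
            },
            "auc": {"n": 5, "n1": 3, "n2": 1, "value": 0.7},
            "vector_node3": [1, 1, 2, 1, 1],
            "vector_node5": [1, 1, 1, 0, 1],
        },
    )
    probe: LabelPair = ("3", "5")
    negatives = {("1", "3"), ("1", "4"), ("1", "5"), ("2", "4"), ("4", "5")}
    return training, probe, negatives


def eleven_node_vectors() -> tuple[list[int], list[int], int]:
    """The published pair of 11-entry neighbourhood vectors whose masked
    correlation is the method's headline hand example.

    Only the two vectors (for nodes 2 and 5 of an 11-node network) are
    published — the generating topology is not reconstructible — so this
    fixture ships vectors, not a graph.  Returns (N_2, N_5, |V|); their
    union support covers all 11 indices, the masked correlation is ≈ −0.74
    and the resulting DICN score for the pair (with zero common neighbours)
    is ≈ 0.26.
    """
    n2 = [2, 5, 3, 2, 0, 0, 0, 1, 2, 1, 2]
    n5 = [0, 0, 1, 0, 4, 2, 3, 1, 1, 2, 0]
    return n2, n5, 11


def _from_networkx(gnx: nx.Graph) -> Graph:
    nodes = sorted(gnx.nodes(), key=repr)
    edges = sorted((str(u), str(v)) for u, v in gnx.edges())
    return build_graph(edges, nodes=[str(u) for u in nodes])


def random_uniform_graph(n: int, edge_probability: float, seed: int) -> Graph:
    """Erdős–Rényi G(n, p) graph with string labels "0".."n-1"."""
    if n < 1:
        raise ValueError("need at least one node")
    if not 0.0 <= edge_probability <= 1.0:
        raise ValueError("edge_probability must be in [0, 1]")
    return _from_networkx(nx.gnp_random_graph(n, edge_probability, seed=seed))


def random_skewed_graph(n: int, edges_per_node: int, seed: int) -> Graph:
    """Degree-heterogeneous graph grown by preferential attachment.

    Each new node attaches ``edges_per_node`` edges to existing nodes with
    probability proportional to current degree; the result is connected and
    heavy-tailed.  Requires n > edges_per_node >= 1.
    """
    if not 1 <= edges_per_node < n:
        raise ValueError("require n > edges_per_node >= 1")
    return _from_networkx(nx.barabasi_albert_graph(n, edges_per_node, seed=seed))


def planted_two_community_graph(
    n: int, p_in: float, p_out: float, seed: int
) -> Graph:
    """Two equal communities with dense intra- and sparse inter-community
    edges; a regime where common-neighbour signals separate candidate
    pairs, used for evaluation sanity tests."""
    sizes = [n // 2, n - n // 2]
    gnx = nx.stochastic_block_model(
        sizes, [[p_in, p_out], [p_out, p_in]], seed=seed
    )
    return _from_networkx(gnx)
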