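"""Undirected simple-graph container and the structural primitives shared by
every similarity index.

The graph model is deliberately minimal: a label <-> contiguous-index mapping
plus per-node adjacency sets.  All scoring code works on integer indices so
that the length-|V| neighbourhood vectors can be dense arrays; original labels
are only touched at the I/O boundary.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

logger = logging.getLogger("dicn")

#: Sentinel for the hop distance between disconnected nodes.
INFINITY: float = math.inf

Label = Hashable
Pair = tuple[int, int]


class GraphInputError(ValueError):
    """Malformed edge input (wrong arity, rejected self-loop, ...)."""


class UnknownNodeError(KeyError):
    """A node index or label outside the graph."""


@dataclass
class Graph:
    """Undirected simple graph over contiguously indexed nodes.

    Attributes
    ----------
    labels:
        Original node labels, position = internal index.
    index_of:
        Inverse mapping, label -> internal index.
    adjacency:
        ``adjacency[i]`` is the set of neighbour indices of node ``i``.
        Symmetric, no self-loops.
    edge_count:
        Number of undirected edges.
    """

    labels: list[Label]
    index_of: dict[Label, int]
    adjacency: list[set[int]]
    edge_count: int
    _mean_clustering: float | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def check_node(self, i: int) -> int:
        if not (0 <= i < self.n_nodes):
            raise UnknownNodeError(f"node index {i} outside 0..{self.n_nodes - 1}")
        return i

    def edges(self) -> list[Pair]:
        """Sorted list of unordered edge index pairs (i < j)."""
        return sorted(
            (i, j) for i in range(self.n_nodes) for j in self.adjacency[i] if i < j
        )


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network statistics: size, mean clustering ⟨C⟩, mean degree ⟨d⟩
    and degree assortativity r."""

    n_nodes: int
    n_edges: int
    mean_clustering: float
    mean_degree: float
    assortativity: float


def build_graph(
    edges: Iterable[Sequence[Label]],
    nodes: Iterable[Label] | None = None,
    on_bad_edge: str = "drop",
) -> Graph:
    """Build a :class:`Graph` from unordered label pairs.

    Duplicate pairs (either orientation) collapse to a single edge.
    Self-loops and duplicates are dropped with a logged warning by default;
    ``on_bad_edge="error"`` raises instead.  ``nodes`` may add isolated
    nodes beyond the edge endpoints.
    """
    if on_bad_edge not in ("drop", "error"):
        raise ValueError("on_bad_edge must be 'drop' or 'error'")

    labels: list[Label] = []
    index_of: dict[Label, int] = {}

    def intern(label: Label) -> int:
        idx = index_of.get(label)
        if idx is None:
            idx = len(labels)
            index_of[label] = idx
            labels.append(label)
        return idx

    for label in nodes or ():
        intern(label)

    pending: list[Pair] = []
    n_self = n_dup = 0
    seen: set[Pair] = set()
    for pair in edges:
        pair = tuple(pair)
        if len(pair) != 2:
            raise GraphInputError(f"edge must have exactly 2 endpoints, got {pair!r}")
        u, v = intern(pair[0]), intern(pair[1])
        if u == v:
            if on_bad_edge == "error":
                raise GraphInputError(f"self-loop on node {pair[0]!r}")
            n_self += 1
            continue
        key = (min(u, v), max(u, v))
        if key in seen:
            if on_bad_edge == "error":
                raise GraphInputError(f"duplicate edge {pair!r}")
            n_dup += 1
            continue
        seen.add(key)
        pending.append(key)

    if n_self or n_dup:
        logger.warning(
            "dropped %d self-loop(s) and %d duplicate edge(s)", n_self, n_dup
        )

    adjacency: list[set[int]] = [set() for _ in labels]
    for u, v in pending:
        adjacency[u].add(v)
        adjacency[v].add(u)
    return Graph(labels, index_of, adjacency, len(pending))


def degree(g: Graph, i: int) -> int:
    """d_i = |Γ_i|."""
    return len(g.adjacency[g.check_node(i)])


def neighbours(g: Graph, i: int) -> set[int]:
    """Γ_i, the first-order neighbourhood (never contains i)."""
    return set(g.adjacency[g.check_node(i)])


def second_order_neighbours(g: Graph, i: int) -> set[int]:
    """Γ_i^(2): nodes at hop distance exactly 2 from i.

    A node z qualifies when some 2-path i-j-z exists and z is neither a
    direct neighbour of i nor i itself (self-exclusion takes precedence).
    """
    g.check_node(i)
    direct = g.adjacency[i]
    out: set[int] = set()
    for j in direct:
        out |= g.adjacency[j]
    out -= direct
    out.discard(i)
    return out


def common_neighbour_count(g: Graph, i: int, j: int) -> int:
    """CN_ij = |Γ_i ∩ Γ_j|.  Requires i ≠ j."""
    g.check_node(i)
    g.check_node(j)
    if i == j:
        raise ValueError("common neighbours undefined for a node with itself")
    return len(g.adjacency[i] & g.adjacency[j])


def local_clustering(g: Graph, i: int) -> float:
    """Local clustering coefficient C_i = 2·T_i / (d_i·(d_i−1)).

    T_i counts edges among the neighbours of i.  Nodes of degree < 2 get 0.
    """
    g.check_node(i)
    nbrs = g.adjacency[i]
    d = len(nbrs)
    if d < 2:
        return 0.0
    t = sum(len(g.adjacency[u] & nbrs) for u in nbrs) // 2
    return 2.0 * t / (d * (d - 1))


def shortest_path_length(g: Graph, i: int, j: int) -> float:
    """BFS hop distance d_ij; 0 when i == j, ``INFINITY`` when disconnected."""
    g.check_node(i)
    g.check_node(j)
    if i == j:
        return 0
    dist = {i: 0}
    queue = deque([i])
    while queue:
        u = queue.popleft()
        for v in g.adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                if v == j:
                    return dist[v]
                queue.append(v)
    return INFINITY


def all_pairs(g: Graph) -> list[Pair]:
    """Every unordered pair of distinct nodes (the universal set U)."""
    n = g.n_nodes
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def non_existing_edges(g: Graph) -> set[Pair]:
    """E^N = U − E: all unordered node pairs not joined by an edge.

    Isolated nodes count towards the pair universe.
    """
    return {(i, j) for i, j in all_pairs(g) if j not in g.adjacency[i]}


def mean_clustering(g: Graph) -> float:
    """Network average clustering coefficient ⟨C⟩ (cached on the graph)."""
    if g._mean_clustering is None:
        n = g.n_nodes
        g._mean_clustering = (
            sum(local_clustering(g, i) for i in range(n)) / n if n else 0.0
        )
    return g._mean_clustering


def degree_assortativity(g: Graph) -> float:
    """Degree assortativity r: Pearson correlation of endpoint degrees over
    the edge list, both orientations.  0 by convention when degenerate."""
    if g.edge_count == 0:
        return 0.0
    x, y = [], []
    for i, j in g.edges():
        di, dj = len(g.adjacency[i]), len(g.adjacency[j])
        x += [di, dj]
        y += [dj, di]
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.std() == 0.0 or ya.std() == 0.0:
        return 0.0
    return float(np.corrcoef(xa, ya)[0, 1])


def network_summary(g: Graph) -> NetworkSummary:
    """Size, ⟨C⟩, ⟨d⟩ = 2|E|/|V| and assortativity r for a graph."""
    n = g.n_nodes
    if n < 1:
        raise ValueError("summary requires at least one node")
    return NetworkSummary(
        n_nodes=n,
        n_edges=g.edge_count,
        mean_clustering=mean_clustering(g),
        mean_degree=2.0 * g.edge_count / n,
        assortativity=degree_assortativity(g),
    )
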