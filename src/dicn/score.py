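"""The Direct-Indirect Common Neighbours (DICN) score.

DICN augments the common-neighbour count with a *latent* similarity signal:
for every node i a length-|V| neighbourhood vector N_i records its degree
(self entry), common-neighbour overlap with each second-order neighbour, and
overlap + 1 with each direct neighbour.  Two nodes whose vectors correlate
strongly over the union of their supports are structurally similar even with
no shared neighbour.  The combined score is

    DICN_ij = (1 + CN_ij) · (1 + Corr_ij),

with Corr_ij the Pearson correlation of N_i and N_j restricted to the union
neighbourhood set UN_ij and centred by the masked means.  Degenerate cases
(empty union, zero variance of a restricted vector) define Corr_ij = 0, so
the score collapses to 1 + CN_ij.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .graph import Graph, Pair, common_neighbour_count, second_order_neighbours
from .indices import METHOD_REGISTRY, DEFAULT_PARAMS, MethodParams


@dataclass(frozen=True)
class NeighbourhoodVector:
    """Integer neighbourhood vector N_i of one node.

    values[owner] is the owner's degree; entries for direct neighbours are
    CN + 1, for second-order neighbours CN, and 0 elsewhere.
    """

    owner: int
    values: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.values > 0


@dataclass(frozen=True)
class UnionNeighbourhood:
    """UN_ij: indices where either of the two vectors is positive."""

    pair: Pair
    members: frozenset[int]


@dataclass(frozen=True)
class DicnScore:
    """One scored node pair: CN count, masked correlation and DICN value."""

    pair: Pair
    cn: int
    corr: float
    score: float


def neighbourhood_vector(g: Graph, i: int) -> NeighbourhoodVector:
    """Build N_i entry-wise.

    Case order matters only for the owner entry: the self entry is always the
    degree, taking precedence over the second-order membership the literal
    set definition would admit.
    """
    g.check_node(i)
    n = g.n_nodes
    values = np.zeros(n, dtype=np.int64)
    direct = g.adjacency[i]
    for z in direct:
        values[z] = len(g.adjacency[i] & g.adjacency[z]) + 1
    for z in second_order_neighbours(g, i):
        values[z] = len(g.adjacency[i] & g.adjacency[z])
    values[i] = len(direct)
    return NeighbourhoodVector(owner=i, values=values)


def union_neighbourhood(
    ni: NeighbourhoodVector, nj: NeighbourhoodVector
) -> UnionNeighbourhood:
    """UN_ij = {z : N_i[z] > 0 or N_j[z] > 0}."""
    if ni.values.shape != nj.values.shape:
        raise ValueError("neighbourhood vectors must have equal length")
    members = frozenset(np.flatnonzero(ni.support | nj.support).tolist())
    return UnionNeighbourhood(pair=(ni.owner, nj.owner), members=members)


def masked_correlation(
    ni: NeighbourhoodVector,
    nj: NeighbourhoodVector,
    un: UnionNeighbourhood | None = None,
) -> float:
    """Pearson correlation of two neighbourhood vectors over the union set.

    Each vector is centred by its mean over UN_ij only.  Returns 0 when the
    union is empty or either restricted vector has zero variance; this
    degenerate convention makes DICN collapse to 1 + CN.
    """
    if un is None:
        un = union_neighbourhood(ni, nj)
    if not un.members:
        return 0.0
    idx = np.fromiter(sorted(un.members), dtype=np.int64)
    a = ni.values[idx].astype(np.float64)
    b = nj.values[idx].astype(np.float64)
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        return 0.0
    corr = float(da @ db) / np.sqrt(va * vb)
    # guard against float drift outside [-1, 1]
    return float(min(1.0, max(-1.0, corr)))


def dicn_score(g: Graph, i: int, j: int) -> DicnScore:
    """Score one node pair: DICN_ij = (1 + CN_ij)(1 + Corr_ij)."""
    cn = common_neighbour_count(g, i, j)
    ni = neighbourhood_vector(g, i)
    nj = neighbourhood_vector(g, j)
    corr = masked_correlation(ni, nj)
    return DicnScore(
        pair=(min(i, j), max(i, j)),
        cn=cn,
        corr=corr,
        score=(1 + cn) * (1.0 + corr),
    )


def dicn_all(
    g: Graph, candidate_pairs: Iterable[Pair] | None = None
) -> list[DicnScore]:
    """Score many candidate pairs, computing all neighbourhood vectors once.

    Defaults to every non-existing edge of the graph.  Output is in sorted
    pair order for determinism.
    """
    from .graph import non_existing_edges

    if candidate_pairs is None:
        pairs = sorted(non_existing_edges(g))
    else:
        pairs = sorted((min(i, j), max(i, j)) for i, j in candidate_pairs)

    vectors: dict[int, NeighbourhoodVector] = {}

    def vec(i: int) -> NeighbourhoodVector:
        if i not in vectors:
            vectors[i] = neighbourhood_vector(g, i)
        return vectors[i]

    out: list[DicnScore] = []
    for i, j in pairs:
        cn = common_neighbour_count(g, i, j)
        corr = masked_correlation(vec(i), vec(j))
        out.append(DicnScore(pair=(i, j), cn=cn, corr=corr, score=(1 + cn) * (1 + corr)))
    return out


def _dicn_method(
    g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS
) -> float:
    return dicn_score(g, i, j).score


METHOD_REGISTRY["dicn"] = _dicn_method


def vectors_from_values(values: Sequence[Sequence[int]]) -> list[NeighbourhoodVector]:
    """Wrap raw integer sequences as neighbourhood vectors (owner = position).

    Useful for working directly with published vectors when the generating
    topology is not available.
    """
    return [
        NeighbourhoodVector(owner=k, values=np.asarray(v, dtype=np.int64))
        for k, v in enumerate(values)
    ]
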