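"""Independent brute-force reference implementations used as test oracles.

Everything here works directly on plain adjacency dicts (or networkx graphs)
built from raw edge lists — deliberately sharing no code with the package —
so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math
from fractions import Fraction

import networkx as nx
import numpy as np
from scipy import stats


def adj_from_edges(edges, nodes):
    a = {u: set() for u in nodes}
    for u, v in edges:
        if u != v:
            a[u].add(v)
            a[v].add(u)
    return a


def to_nx(g):
    """Convert a package Graph to networkx on internal indices."""
    gx = nx.Graph()
    gx.add_nodes_from(range(g.n_nodes))
    gx.add_edges_from(g.edges())
    return gx


# ---- index oracles over adjacency dicts (node keys are arbitrary) ----

def cn(a, i, j):
    return len(a[i] & a[j])


def pa(a, i, j):
    return len(a[i]) * len(a[j])


def jc(a, i, j):
    u = a[i] | a[j]
    return Fraction(len(a[i] & a[j]), len(u)) if u else Fraction(0)


def hpi(a, i, j):
    m = min(len(a[i]), len(a[j]))
    return Fraction(len(a[i] & a[j]), m) if m else Fraction(0)


def clustering(a, i):
    nbrs = sorted(a[i])
    d = len(nbrs)
    if d < 2:
        return 0.0
    links = sum(
        1 for x in range(d) for y in range(x + 1, d) if nbrs[y] in a[nbrs[x]]
    )
    return 2.0 * links / (d * (d - 1))


def cn2(a, z, i, j):
    return (a[z] & a[i] & a[j]) | {i, j}


def cndp(a, i, j, exponent):
    return sum(
        len(cn2(a, z, i, j)) * len(a[z]) ** (-exponent) for z in a[i] & a[j]
    )


def ncc(a, i, j):
    total = 0.0
    for n in a[i] & a[j]:
        num = sum(1.0 / len(a[z]) + clustering(a, z) for z in cn2(a, n, i, j))
        den = sum(1.0 / len(a[w]) + clustering(a, w) for w in a[n])
        if den:
            total += num / den
    return total


def ccpa(a, i, j, alpha):
    gx = nx.Graph()
    gx.add_nodes_from(a)
    gx.add_edges_from((u, v) for u in a for v in a[u] if repr(u) < repr(v))
    try:
        d = nx.shortest_path_length(gx, i, j)
        closeness = len(a) / d
    except nx.NetworkXNoPath:
        closeness = 0.0
    return alpha * cn(a, i, j) + (1 - alpha) * closeness


def shopi(a, i, j, alpha, max_len):
    total = sum(1.0 / len(a[n]) for n in a[i] & a[j])
    if max_len > 2:
        gx = nx.Graph()
        gx.add_nodes_from(a)
        gx.add_edges_from((u, v) for u in a for v in a[u] if repr(u) < repr(v))
        for path in nx.all_simple_paths(gx, i, j, cutoff=max_len):
            length = len(path) - 1
            if length < 3:
                continue
            w = alpha ** (length - 2)
            for z in path[1:-1]:
                w /= len(a[z])
            total += w
    return total


# ---- DICN building blocks ----

def neighbourhood_vector(a, order, i):
    """Straight-line per-case evaluation of the vector definition."""
    out = []
    direct = a[i]
    second = set()
    for nb in direct:
        second |= a[nb]
    second -= direct
    second.discard(i)
    for z in order:
        if z == i:
            out.append(len(direct))
        elif z in second:
            out.append(len(a[i] & a[z]))
        elif z in direct:
            out.append(len(a[i] & a[z]) + 1)
        else:
            out.append(0)
    return out


def masked_pearson(ni, nj):
    ni = np.asarray(ni, float)
    nj = np.asarray(nj, float)
    mask = (ni > 0) | (nj > 0)
    a, b = ni[mask], nj[mask]
    if a.size == 0 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(stats.pearsonr(a, b).statistic)


def dicn(a, order, i, j):
    c = cn(a, i, j)
    corr = masked_pearson(
        neighbourhood_vector(a, order, i), neighbourhood_vector(a, order, j)
    )
    return (1 + c) * (1 + corr)


# ---- evaluation oracles ----

def auc_double_loop(probe_scores, negative_scores):
    n1 = n2 = 0
    for sp in probe_scores:
        for sq in negative_scores:
            if sp > sq:
                n1 += 1
            elif sp == sq:
                n2 += 1
    n = len(probe_scores) * len(negative_scores)
    return n, n1, n2, (n1 + 0.5 * n2) / n


def shortest_path_exhaustive(a, i, j):
    """Hop distance by exhaustive simple-path enumeration (tiny graphs)."""
    if i == j:
        return 0
    best = math.inf

    def walk(u, depth, visited):
        nonlocal best
        if depth >= best:
            return
        for v in a[u]:
            if v == j:
                best = min(best, depth + 1)
            elif v not in visited:
                walk(v, depth + 1, visited | {v})

    walk(i, 0, {i})
    return best


def atlas_small_graphs(max_nodes=6):
    """All non-isomorphic simple graphs with at most ``max_nodes`` nodes."""
    return [g for g in nx.graph_atlas_g() if g.number_of_nodes() <= max_nodes]
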