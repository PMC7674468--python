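"""Classical local similarity indices used as comparators: CN, PA, JC, HPI,
CNDP, NCC, CCPA and SHOPI.

Each index is a pure pairwise function of a training graph.  Scores are
symmetric, finite and non-negative; ratio-type indices (JC, HPI) are bounded
by 1.  Zero-denominator cases (empty neighbourhood union, isolated endpoint,
disconnected pair in CCPA, zero-mass NCC term) are defined as contributing 0,
so every index is a total function.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import (
    INFINITY,
    Graph,
    common_neighbour_count,
    local_clustering,
    mean_clustering,
    shortest_path_length,
)


@dataclass(frozen=True)
class MethodParams:
    """Tunable parameters of the parameterised indices.

    ccpa_alpha:
        α of the CCPA blend between common-neighbour count and closeness,
        in [0, 1].
    cndp_beta:
        β in the CNDP degree penalty d_z^(−β⟨C⟩); the exponent is β times
        the network mean clustering coefficient.
    cndp_exponent:
        Explicit override of the full CNDP exponent; when set, β and ⟨C⟩
        are ignored.
    shopi_alpha:
        Per-extra-hop damping factor for SHOPI path contributions.
    shopi_max_len:
        Maximal path length considered by SHOPI (≥ 2).
    """

    ccpa_alpha: float = 0.8
    cndp_beta: float = 1.0
    cndp_exponent: float | None = None
    shopi_alpha: float = 0.1
    shopi_max_len: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.ccpa_alpha <= 1.0:
            raise ValueError("ccpa_alpha must be in [0, 1]")
        if self.shopi_max_len < 2:
            raise ValueError("shopi_max_len must be >= 2")
        if not 0.0 <= self.shopi_alpha <= 1.0:
            raise ValueError("shopi_alpha must be in [0, 1]")


DEFAULT_PARAMS = MethodParams()


def _check_pair(g: Graph, i: int, j: int) -> None:
    g.check_node(i)
    g.check_node(j)
    if i == j:
        raise ValueError("similarity scores are defined for distinct nodes only")


def cn_score(g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS) -> float:
    """Common Neighbours: |Γ_i ∩ Γ_j|."""
    return float(common_neighbour_count(g, i, j))


def pa_score(g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS) -> float:
    """Preferential Attachment: d_i · d_j."""
    _check_pair(g, i, j)
    return float(len(g.adjacency[i]) * len(g.adjacency[j]))


def jc_score(g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS) -> float:
    """Jaccard: |Γ_i ∩ Γ_j| / |Γ_i ∪ Γ_j|; 0 when the union is empty."""
    _check_pair(g, i, j)
    union = g.adjacency[i] | g.adjacency[j]
    if not union:
        return 0.0
    return len(g.adjacency[i] & g.adjacency[j]) / len(union)


def hpi_score(g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS) -> float:
    """Hub Promoted: |Γ_i ∩ Γ_j| / min(d_i, d_j); 0 when an endpoint is isolated."""
    _check_pair(g, i, j)
    dmin = min(len(g.adjacency[i]), len(g.adjacency[j]))
    if dmin == 0:
        return 0.0
    return len(g.adjacency[i] & g.adjacency[j]) / dmin


def _cn2(g: Graph, n: int, i: int, j: int) -> set[int]:
    # CN_n^(2) = (Γ_n ∩ Γ_i ∩ Γ_j) ∪ {i, j} for a common neighbour n
    return (g.adjacency[n] & g.adjacency[i] & g.adjacency[j]) | {i, j}


def cndp_exponent(g: Graph, params: MethodParams) -> float:
    """The effective CNDP degree-penalty exponent for a graph."""
    if params.cndp_exponent is not None:
        return params.cndp_exponent
    return params.cndp_beta * mean_clustering(g)


def cndp_score(
    g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS
) -> float:
    """Common Neighbours Degree Penalization.

    Sum over common neighbours z of |CN_z^(2)| · d_z^(−exponent), where
    CN_z^(2) extends the triangle overlap by the endpoints themselves and the
    exponent defaults to β·⟨C⟩ (network mean clustering).
    """
    _check_pair(g, i, j)
    common = g.adjacency[i] & g.adjacency[j]
    if not common:
        return 0.0
    exp = cndp_exponent(g, params)
    return float(
        sum(len(_cn2(g, z, i, j)) * len(g.adjacency[z]) ** (-exp) for z in common)
    )


def ncc_score(g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS) -> float:
    """Node-Coupling Clustering.

    Each common neighbour n contributes the ratio of Σ(1/d_z + C_z) over its
    extended overlap CN_n^(2) to the same sum over its full neighbourhood Γ_n.
    A term with zero denominator contributes 0.
    """
    _check_pair(g, i, j)
    total = 0.0
    for n in g.adjacency[i] & g.adjacency[j]:
        denom = sum(
            1.0 / len(g.adjacency[w]) + local_clustering(g, w) for w in g.adjacency[n]
        )
        if denom == 0.0:
            continue
        numer = sum(
            (1.0 / len(g.adjacency[z]) if g.adjacency[z] else 0.0)
            + local_clustering(g, z)
            for z in _cn2(g, n, i, j)
        )
        total += numer / denom
    return total


def ccpa_score(
    g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS
) -> float:
    """Parameterized common-neighbour / closeness blend.

    α·CN_ij + (1−α)·|V|/d_ij; the closeness term vanishes for disconnected
    pairs (the d_ij → ∞ limit).
    """
    _check_pair(g, i, j)
    alpha = params.ccpa_alpha
    cn = len(g.adjacency[i] & g.adjacency[j])
    d = shortest_path_length(g, i, j)
    closeness = 0.0 if d == INFINITY else g.n_nodes / d
    return alpha * cn + (1.0 - alpha) * closeness


def _simple_paths_by_length(g: Graph, i: int, j: int, max_len: int) -> dict[int, list[list[int]]]:
    # depth-limited DFS over simple paths i -> j of edge-length 3..max_len
    out: dict[int, list[list[int]]] = {l: [] for l in range(3, max_len + 1)}
    path = [i]
    on_path = {i}

    def extend(u: int) -> None:
        depth = len(path)  # edges used so far = depth - 1 after appending next
        for v in g.adjacency[u]:
            if v == j:
                if depth >= 3:  # path length = depth edges
                    out[depth].append(path + [j])
                continue
            if v in on_path or depth >= max_len:
                continue
            path.append(v)
            on_path.add(v)
            extend(v)
            path.pop()
            on_path.remove(v)

    if max_len >= 3:
        extend(i)
    return out


def shopi_score(
    g: Graph, i: int, j: int, params: MethodParams = DEFAULT_PARAMS
) -> float:
    """Significance of Higher-Order Paths.

    Damped sum of per-length path significances,
    S_ij = Σ_{l=2..L} α^(l−2) · P_l(i, j): the length-2 term P_2 is the sum
    of 1/d_n over common neighbours n, and P_l for l > 2 sums, over all
    simple l-paths from i to j, the product of 1/d over the intermediate
    nodes.  Symmetric in (i, j) by construction.
    """
    _check_pair(g, i, j)
    p2 = sum(1.0 / len(g.adjacency[n]) for n in g.adjacency[i] & g.adjacency[j])
    total = p2
    if params.shopi_max_len > 2 and params.shopi_alpha > 0.0:
        by_len = _simple_paths_by_length(g, i, j, params.shopi_max_len)
        for length, paths in by_len.items():
            weight = params.shopi_alpha ** (length - 2)
            for p in paths:
                prod = 1.0
                for z in p[1:-1]:
                    prod /= len(g.adjacency[z])
                total += weight * prod
    return total


#: Canonical method registry shared with the CLI.  "dicn" is registered by
#: the score module on import (see dicn.score).
METHOD_REGISTRY: dict[str, object] = {
    "cn": cn_score,
    "pa": pa_score,
    "jc": jc_score,
    "hpi": hpi_score,
    "cndp": cndp_score,
    "ncc": ncc_score,
    "ccpa": ccpa_score,
    "shopi": shopi_score,
}


def get_method(name: str):
    """Look up a scoring function by its canonical lower-case name."""
    try:
        return METHOD_REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; known: {sorted(METHOD_REGISTRY)}"
        ) from None
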