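"""Train/probe edge splitting, exhaustive AUC, experiment runners and the
zero-common-neighbour motivation statistics.

Evaluation protocol: the edge set E is partitioned into a training set E^T
(β percent, rounded half-up, probe forced non-empty) and a probe set E^P.
Scores are always computed on the training graph only — probe edges are never
visible to a scorer.  AUC compares every probe edge against every
non-existing edge: strict wins count 1, exact ties count ½,
AUC = (n1 + n2/2)/n with n = |E^P|·|E^N|.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np

from .graph import Graph, Pair, all_pairs, build_graph, common_neighbour_count
from .indices import DEFAULT_PARAMS, MethodParams, get_method

LabelPair = tuple[Hashable, Hashable]

#: Scores are rounded to this many significant digits before tie comparison,
#: so exact rational ties register while accumulated float noise does not.
TIE_SIGNIFICANT_DIGITS = 12


@dataclass(frozen=True)
class EdgeSplit:
    """A partition E = E^T ∪ E^P plus the non-existing pairs E^N."""

    training_edges: frozenset[LabelPair]
    probe_edges: frozenset[LabelPair]
    non_existing: frozenset[LabelPair]
    beta: float
    seed: int


@dataclass(frozen=True)
class AUCResult:
    """Exhaustive-comparison AUC: n comparisons, n1 strict wins, n2 ties."""

    n: int
    n1: int
    n2: int

    @property
    def auc(self) -> float:
        return (self.n1 + 0.5 * self.n2) / self.n


@dataclass
class ExperimentReport:
    """Per-repetition AUC results for one method at one split ratio."""

    method: str
    beta: float
    repetitions: int
    seed: int
    results: list[AUCResult | None] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        vals = [r.auc for r in self.results if r is not None]
        if not vals:
            return float("nan")
        return float(np.mean(vals))


def _norm_pair(u: Hashable, v: Hashable) -> LabelPair:
    return (u, v) if repr(u) <= repr(v) else (v, u)


def _round_sig(x: float) -> float:
    return float(f"{x:.{TIE_SIGNIFICANT_DIGITS}g}")


def split_edges(
    edges: Iterable[LabelPair],
    beta: float,
    seed: int,
    nodes: Iterable[Hashable] | None = None,
) -> EdgeSplit:
    """Randomly partition edges into training (β percent) and probe sets.

    |E^T| = round(β·|E|/100) half-up, clamped so that both parts are
    non-empty.  Deterministic given (edges as a set, beta, seed); the input
    edge order does not matter.
    """
    if not 0.0 < beta < 100.0:
        raise ValueError("beta must be strictly between 0 and 100")
    norm = sorted({_norm_pair(u, v) for u, v in edges}, key=repr)
    m = len(norm)
    if m < 2:
        raise ValueError("need at least 2 edges to split")

    n_train = int(np.floor(beta * m / 100.0 + 0.5))
    n_train = min(max(n_train, 1), m - 1)  # probe must keep >= 1 edge

    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    train = frozenset(norm[k] for k in perm[:n_train])
    probe = frozenset(norm[k] for k in perm[n_train:])

    node_set = {u for e in norm for u in e}
    if nodes is not None:
        node_set |= set(nodes)
    ordered = sorted(node_set, key=repr)
    universe = {
        _norm_pair(ordered[a], ordered[b])
        for a in range(len(ordered))
        for b in range(a + 1, len(ordered))
    }
    return EdgeSplit(
        training_edges=train,
        probe_edges=probe,
        non_existing=frozenset(universe - set(norm)),
        beta=beta,
        seed=seed,
    )


def training_graph(split: EdgeSplit) -> Graph:
    """Graph over the full node universe with the training edges only."""
    nodes = sorted(
        {u for e in (split.training_edges | split.probe_edges) for u in e}, key=repr
    )
    return build_graph(sorted(split.training_edges, key=repr), nodes=nodes)


def auc_exhaustive(
    scores: Mapping[LabelPair, float],
    probe: Iterable[LabelPair],
    negatives: Iterable[LabelPair],
) -> AUCResult:
    """AUC over every (probe, negative) comparison pair.

    Raises ``KeyError`` if any pair lacks a score.
    """
    lut = {_norm_pair(*k): v for k, v in scores.items()}
    p_scores = [_round_sig(lut[_norm_pair(*p)]) for p in probe]
    q_scores = [_round_sig(lut[_norm_pair(*q)]) for q in negatives]
    n1 = n2 = 0
    for sp in p_scores:
        for sq in q_scores:
            if sp > sq:
                n1 += 1
            elif sp == sq:
                n2 += 1
    return AUCResult(n=len(p_scores) * len(q_scores), n1=n1, n2=n2)


def score_pairs(
    g: Graph,
    pairs: Iterable[LabelPair],
    method: str,
    params: MethodParams = DEFAULT_PARAMS,
) -> dict[LabelPair, float]:
    """Score label pairs with a registry method on the (training) graph."""
    fn = get_method(method)
    out: dict[LabelPair, float] = {}
    if method.lower() == "dicn":
        from .score import dicn_all

        idx_pairs = [(g.index_of[u], g.index_of[v]) for u, v in pairs]
        for rec in dicn_all(g, idx_pairs):
            i, j = rec.pair
            out[_norm_pair(g.labels[i], g.labels[j])] = rec.score
        return out
    for u, v in pairs:
        out[_norm_pair(u, v)] = fn(g, g.index_of[u], g.index_of[v], params)
    return out


def filter_no_common_neighbour(
    split: EdgeSplit, g_train: Graph
) -> tuple[set[LabelPair], set[LabelPair]]:
    """Keep probe/negative pairs whose endpoints share no common neighbour
    and both have training-graph degree > 1."""

    def keep(pair: LabelPair) -> bool:
        i, j = (g_train.index_of[pair[0]], g_train.index_of[pair[1]])
        if len(g_train.adjacency[i]) <= 1 or len(g_train.adjacency[j]) <= 1:
            return False
        return common_neighbour_count(g_train, i, j) == 0

    return (
        {p for p in split.probe_edges if keep(p)},
        {q for q in split.non_existing if keep(q)},
    )


def filter_equal_common_neighbours(
    split: EdgeSplit, g_train: Graph
) -> set[tuple[LabelPair, LabelPair]]:
    """All cross pairs (p, q) ∈ E^P × E^N whose endpoints have equal
    common-neighbour counts on the training graph."""

    def cn_of(pair: LabelPair) -> int:
        return common_neighbour_count(
            g_train, g_train.index_of[pair[0]], g_train.index_of[pair[1]]
        )

    probe_cn = {p: cn_of(p) for p in split.probe_edges}
    neg_cn = {q: cn_of(q) for q in split.non_existing}
    return {
        (p, q)
        for p, cp in probe_cn.items()
        for q, cq in neg_cn.items()
        if cp == cq
    }


def auc_over_comparisons(
    scores: Mapping[LabelPair, float],
    comparisons: Iterable[tuple[LabelPair, LabelPair]],
) -> AUCResult | None:
    """AUC restricted to an explicit set of (probe, negative) comparisons.

    Returns ``None`` when there is nothing to compare.
    """
    comparisons = list(comparisons)
    if not comparisons:
        return None
    lut = {_norm_pair(*k): v for k, v in scores.items()}
    n1 = n2 = 0
    for p, q in comparisons:
        sp = _round_sig(lut[_norm_pair(*p)])
        sq = _round_sig(lut[_norm_pair(*q)])
        if sp > sq:
            n1 += 1
        elif sp == sq:
            n2 += 1
    return AUCResult(n=len(comparisons), n1=n1, n2=n2)


def repetition_seed(base_seed: int, repetition: int) -> int:
    """Counter-based per-repetition seed, independent and reproducible."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(repetition,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    edges: Iterable[LabelPair],
    method: str,
    params: MethodParams = DEFAULT_PARAMS,
    beta: float = 80.0,
    repetitions: int = 15,
    seed: int = 0,
    experiment: int = 1,
    nodes: Iterable[Hashable] | None = None,
) -> ExperimentReport:
    """Repeated split + score + AUC for one method.

    ``experiment`` selects the comparison protocol: 1/2 — full exhaustive
    AUC over E^P × E^N; 3 — restricted to pairs with zero common neighbours
    and both endpoint degrees > 1 (training graph); 4 — restricted to
    matched common-neighbour-count comparison pairs.  A repetition whose
    restricted comparison set is empty reports ``None``.
    """
    if experiment not in (1, 2, 3, 4):
        raise ValueError("experiment must be 1, 2, 3 or 4")
    get_method(method)  # fail fast on unknown method
    edge_list = sorted({_norm_pair(u, v) for u, v in edges}, key=repr)
    report = ExperimentReport(
        method=method.lower(), beta=beta, repetitions=repetitions, seed=seed
    )
    for r in range(repetitions):
        split = split_edges(edge_list, beta, repetition_seed(seed, r), nodes=nodes)
        g_train = training_graph(split)
        if experiment in (1, 2):
            pairs = split.probe_edges | split.non_existing
            scores = score_pairs(g_train, pairs, method, params)
            report.results.append(
                auc_exhaustive(scores, split.probe_edges, split.non_existing)
            )
        elif experiment == 3:
            probe, neg = filter_no_common_neighbour(split, g_train)
            if not probe or not neg:
                report.results.append(None)
                continue
            scores = score_pairs(g_train, probe | neg, method, params)
            report.results.append(auc_exhaustive(scores, probe, neg))
        else:
            comps = filter_equal_common_neighbours(split, g_train)
            if not comps:
                report.results.append(None)
                continue
            pairs = {p for p, _ in comps} | {q for _, q in comps}
            scores = score_pairs(g_train, pairs, method, params)
            report.results.append(auc_over_comparisons(scores, comps))
    return report


def motivation_stats(
    g: Graph,
) -> tuple[float, Counter[int], Counter[int]]:
    """Zero-common-neighbour fraction of E, and CN-count histograms for E
    and E^N.

    Returns ``(zero_cn_fraction, hist_existing, hist_non_existing)``; the
    histogram masses sum to |E| and |E^N| respectively.
    """
    hist_e: Counter[int] = Counter()
    hist_n: Counter[int] = Counter()
    for i, j in all_pairs(g):
        cn = len(g.adjacency[i] & g.adjacency[j])
        if j in g.adjacency[i]:
            hist_e[cn] += 1
        else:
            hist_n[cn] += 1
    zero_frac = hist_e[0] / g.edge_count if g.edge_count else 0.0
    return zero_frac, hist_e, hist_n
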