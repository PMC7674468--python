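# Methods

## Model and assumptions

The package treats link prediction as a ranking problem on an undirected
simple graph G(V, E): every non-adjacent node pair receives a similarity
score, and a good scorer ranks held-out true edges above never-existing
pairs. No edge weights, directions, node attributes or temporal
information are used; graphs with those features must be projected down
before scoring. All indices are *local or semi-local*: a pair's score
depends only on its first- and second-order neighbourhood (CCPA's
closeness term and SHOPI's paths reach further but remain cheap).

The DICN score combines two signals. The direct signal is the
common-neighbour count CN_ij. The indirect signal embeds each node as an
integer neighbourhood vector N_i (self entry = degree; direct-neighbour
entries = shared-neighbour count + 1; second-order entries =
shared-neighbour count; zero elsewhere) and measures the Pearson
correlation of N_i and N_j restricted to the union of their supports.
Restricting to the union set matters: indices where both vectors are zero
carry no information about the pair and would otherwise inflate the
correlation. The final score (1 + CN)(1 + Corr) is non-negative, equals
zero only for perfectly anti-correlated neighbourhoods, and reduces to
1 + CN when the correlation is degenerate.

### Case precedence in the neighbourhood vector

The self entry always equals the degree, even though a node with no
self-loop could satisfy the literal second-order set definition through a
2-cycle i–j–i. Self-exclusion also applies to the second-order set itself
(Γ_i^(2) never contains i). Both choices are forced by the arithmetic of
the worked examples the test suite pins down.

### Degenerate correlation

Pearson correlation is undefined when a restricted vector is constant or
the union set is empty. These cases are defined as Corr := 0, collapsing
the score to 1 + CN. The alternative (corr = 1 for identical constant
vectors) would score a pair of degree-1 nodes hanging off the same hub as
highly as a tightly embedded pair; the worked-example value 2.0 for such a
pair confirms the zero convention. The raw correlation is kept unclamped
otherwise (only guarded against float drift outside [−1, 1]).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `ccpa_alpha` | 0.8 | CCPA weight on the CN term vs the |V|/d_ij closeness term; α=1 recovers CN exactly. Source experiments do not publish their value; 0.8 mirrors the customary training-heavy setting. |
| `cndp_beta` | 1.0 | β in the CNDP degree penalty d_z^(−β⟨C⟩). Only the network-level mean clustering ⟨C⟩ is well-defined as the C factor, so the exponent is β·⟨C⟩; `cndp_exponent` overrides it directly. |
| `shopi_alpha` | 0.1 | per-extra-hop damping of SHOPI path contributions. |
| `shopi_max_len` | 3 | maximal SHOPI path length; 2 keeps only the common-neighbour term. |
| `beta` (split) | 80 | percent of edges in the training set. |
| `repetitions` | 15 | independent splits averaged per evaluation. |

### SHOPI formulation

The published recurrence for paths longer than 2 is not operational (its
edge- and path-significance factors are never defined), so this package
implements a documented, symmetric formulation preserving the stated
ingredients: S_ij = Σ_{l=2..L} α^(l−2) P_l, with P_2 = Σ 1/d_n over common
neighbours n and P_l the sum over simple l-paths i→…→j of the product of
1/d over intermediate nodes. SHOPI comparisons should therefore be read as
indicative, not as a faithful reimplementation of the original index.

## Evaluation protocol

E is partitioned uniformly at random into E^T (β percent, rounded half-up,
with the probe set forced non-empty) and E^P. **Scores are computed on the
training graph only** — the training graph keeps the full node universe
(so nodes isolated by the split still count in |V| and in E^N) but none of
the probe edges. AUC compares every probe edge with every non-existing
edge: AUC = (n₁ + n₂/2)/n, n = |E^P|·|E^N|, strict wins n₁, ties n₂.

Ties are detected after rounding scores to 12 significant digits: the
worked example's ties are exact rationals and must register, while float
noise accumulated along different summation orders must not.

Two restricted protocols probe specific regimes. The zero-CN protocol
keeps only probe/negative pairs whose endpoints share no training-graph
neighbour and both have training degree > 1 (degrees and CN counts are
measured on the training graph — the only information legitimately
available at prediction time). The matched-CN protocol compares exactly
those probe×negative pairs with equal training-graph CN counts; n is the
number of kept comparison pairs, and a repetition with no matches reports
a missing value rather than a fabricated AUC. An alternative reading —
keep edges whose CN count appears in both sets, then run the full
cross-AUC — is possible; the matched-pair reading is this package's
documented choice.

Per-repetition seeds derive from the base seed through
`numpy.random.SeedSequence(entropy=seed, spawn_key=(r,))`, so repetitions
are mutually independent yet reproducible, and splits are invariant to the
input edge ordering (edges are set-normalised and sorted before
permutation).

## Synthetic data

The generators emulate the two degree regimes spanned by the usual
link-prediction benchmarks: `random_uniform_graph` (Erdős–Rényi G(n, p),
homogeneous degrees, vanishing clustering) and `random_skewed_graph`
(preferential attachment, heavy-tailed degrees, connected by
construction), plus a planted two-community stochastic block model for
evaluation sanity checks, where within-community pairs share many
neighbours by design. None of these reproduce the degree–clustering joint
structure, assortativity profiles, or community hierarchies of real PPI or
social networks, so passing tests demonstrate correctness of the
computation, not field performance; full-scale benchmark AUCs require the
user to supply the corresponding edge lists to `dicn evaluate`.

Test problem sizes — exhaustive enumeration over all non-isomorphic graphs
with ≤ 6 nodes, 200 random graphs of up to 30 nodes with sampled candidate
pairs, planted graphs of 20–30 nodes with 2–5 repetitions — were chosen so
the whole suite completes in seconds while still exercising every code
path against an independent brute-force oracle.

## Numerical choices and degenerate inputs

- Neighbourhood vectors are exact int64; the masked correlation is the
  only floating-point step. Published two-decimal values are checked at
  ±0.005.
- Zero-denominator conventions: JC and HPI return 0 for isolated
  endpoints; an NCC term with zero denominator contributes 0; CCPA's
  closeness term is 0 for disconnected pairs (the d_ij → ∞ limit);
  clustering of degree-<2 nodes is 0; assortativity of degree-regular
  graphs is 0.
- Self-loops and duplicate input edges are dropped with a logged warning
  (`on_bad_edge="error"` hard-fails instead); isolated nodes supplied via
  a node list are retained and count toward |V| and E^N.
- Pairwise scores require distinct nodes; i = j raises.

## Known limitations

- O(|E^P|·|E^N|) exhaustive AUC and O(|V|²) candidate enumeration make
  full evaluation quadratic in |V|; networks beyond ~10⁴ nodes need
  candidate subsampling, which the library supports via explicit candidate
  sets but the CLI does not expose.
- SHOPI is a documented reinterpretation (above).
- The CNDP exponent's C factor is taken as network mean clustering; other
  readings (per-node clustering) would change that index's values.
- Directed, weighted, temporal and multilayer graphs are out of scope.
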