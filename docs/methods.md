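# Methods

## Primary enrichment statistic

**Ranked mode.** The input is the full list *L* of *l* genes in the
experiment ranked by increasing per-gene p-value, and a gene set
*S ⊆ L* of size *s*. For the member with rank *i* within *S*, let *l_i*
be the number of genes in *L* with a p-value less than or equal to that
member's. The primary p-value is the minimum over *i* of the
hypergeometric over-representation tail of the 2×2 table

|               | in top *l_i* | below |
|---------------|--------------|-------|
| in *S*        | *i*          | *s−i* |
| not in *S*    | *l_i−i*      | *l−l_i−(s−i)* |

i.e. `min_i P(X ≥ i)` with `X ~ Hypergeom(l, s, l_i)`. The minimum is
taken only at thresholds realised by members of *S*. No multiple-testing
correction is applied to this minimum: the statistic is deliberately
anti-conservative at this stage (see *Limitations*), and downstream
stages assume a loose screen.

*Ties.* Genes sharing a p-value receive the count of the full tied
block: a member tied with non-members gets credit for every gene
ranking "above or equal". A member tied with another member keeps its
own within-set rank *i* but the shared *l_i*.

**Unranked mode.** For a cluster *C* of *c* genes selected from a
background of *l*, the p-value of *S* is the one-tailed Fisher exact
test on `[[n, s−n], [c−n, l−(c+s−n)]]` with `n = |C ∩ S|`.

All tails are computed with `scipy.stats.hypergeom.sf`, which sums the
point masses of the tail directly and therefore stays accurate for
very small p-values (no `1 − cdf` cancellation); results are clamped
into (0, 1] so a p-value never underflows to exactly zero. Exactness is
asserted in the test suite against an exact-rational enumerator on
thousands of small instances.

## False-positive elimination

1. **Screen.** Sets with primary p above `set_p_cutoff` (default 0.05;
   a loose value on purpose) are discarded.
2. **Candidate pairs.** For every remaining pair (M, N) the
   intersection significance `P(|M ∩ N| ≥ i)` is computed
   (hypergeometric: population *l*, *m* successes, *n* draws — the
   printed cutoff 0.01 is applied without correction). Only pairs below
   the cutoff are re-evaluated, keeping the stage near-linear for
   sparse collections. The tail is evaluated with a canonical argument
   order so the result is bit-identical under operand swap.
3. **Pair verdicts.** Each candidate pair (A, B) is re-tested on the
   set differences A\B and B\A with the same primary statistic and the
   same cutoff. Four outcomes: A invalidated (p′_A above the cutoff,
   p′_B below), B invalidated (symmetric), *mutual* (both above: the
   significance lies in the intersection; neither set is discarded,
   both are flagged), *none* (both below). An empty set difference is
   assigned p′ = 1 — membership outside the overlap carries no
   evidence. When A ⊊ B only the superset is re-evaluated (on B\A);
   the subset keeps its primary p as its p′ for that pair.
4. **Resolution.** Verdicts are collected first, then a directed
   invalidation graph (edges point at the invalidated set) is resolved
   by a layered fixpoint: sources are retained; a node with a retained
   invalidator is discarded; a node all of whose invalidators are
   discarded is retained; iterate until stable. A chain A→B→C thus
   loses only B. Nodes on directed cycles of length ≥ 3 with no
   external retained invalidator are retained — no member of such a
   cycle is a clean witness against the others. This rule is an
   extension point: only the single-edge, chain and mutual cases are
   canonically defined. "None"-verdict pairs contribute no
   invalidation edges; their p′ ordering is reused for overlap-edge
   direction. Resolution is independent of node and edge insertion
   order by construction.

## Gene-set network and prioritisation

Retained sets become nodes; every significantly intersecting retained
pair contributes exactly one edge: **subset** (directed subset →
superset), **intersection** (undirected, from mutual pairs) or
**overlap** (all other cases, directed from the less significant set
toward the one with the lower p′). Edges carry the Jaccard similarity
|A∩B|/|A∪B|.

**SetRank values** are PageRank scores on the overlap-edge subgraph
over *all* network nodes, damping 0.85, computed by power iteration
with a uniform teleport vector, dangling mass redistributed uniformly,
convergence at L1 change < 1e-12 (cap 10,000 iterations). Scores sum
to 1. PageRank is implemented in-package; the test suite checks it
against both a direct linear solve of the stationary system and
`networkx.pagerank`.

**Empirical null.** 100 random directed graphs with the same node and
edge counts (uniform G(n, m): m distinct ordered pairs sampled without
replacement, no self-loops) are scored; all pooled PageRank values are
fitted with a single normal (mean, sd), and each node's SetRank
p-value is the upper tail of its observed score, Holm-adjusted across
nodes. A zero-variance pool (e.g. an edgeless network) yields p = 1
for every node — nodes that do not participate in overlap edges are
deliberately uninformative rather than significant.

**Correction cascade.** Each node's corrected p-value is the maximum
of its p′ against every network neighbour (all edge types: any edge
marks genuine gene sharing), or its primary p when isolated. Weakly
connected components — which share no genes by construction — get the
minimum corrected p of their members; component p-values are
Holm-adjusted (the step-down FWER procedure, via
`statsmodels.stats.multitest`) and components above the
`fdr_cutoff` (default 0.05) are dropped. Final ordering is a stable
three-key ascending sort: SetRank p, Holm-adjusted SetRank p,
corrected p.

## Detection calling

On a non-log intensity matrix (rows = probesets/genes, columns =
samples), two data-driven cutoffs are derived: (1) the median of all
row rMADs, where rMAD = raw median absolute deviation / arithmetic
mean on the non-log scale (no 1.4826 consistency factor — the ratio is
a relative dispersion, not a robust sd estimate); (2) the 5th
percentile — linear interpolation between order statistics — of the
log2-mean intensity of the rows with rMAD *above* the median. Rows
strictly below both cutoffs are undetected; everything else is
detected. Log base 2 follows microarray convention; zero intensities
are floored at the smallest positive entry before the log. Because
rMAD is scale-free and a global intensity rescaling shifts all
log-means and the mean cutoff by the same constant, detection flags
are invariant under global rescaling. When rows map to genes
many-to-one, a gene is in the background if *any* of its rows is
detected.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `set_p_cutoff` | 0.05 | primary screen and p′ re-test cutoff (loose by design, 0.01–0.05 sensible) |
| `intersection_cutoff` | 0.01 | pair screen on intersection significance, uncorrected |
| `fdr_cutoff` | 0.05 | threshold on component-level Holm-adjusted p |
| `min_set_size` | 3 | smallest retained set after background intersection |
| `max_set_size` | 500 | ceiling that excludes vague, umbrella-level sets |
| `n_random_networks` | 100 | empirical-null sample size |
| damping | 0.85 | PageRank damping factor |

Sets are intersected with the background *before* size filtering so
that the size entering every test equals the effective size within the
universe L. Gene identifiers are opaque case-sensitive strings;
identifier mapping belongs to upstream annotation tooling. Duplicate
gene IDs in a ranked list are rejected by default
(`collapse_duplicates` keeps the best p-value instead).

## Synthetic data

The generator emulates the premise that truly affected sets are
enriched with significant genes while everything else is uniform
noise: non-signal genes draw p-values from Uniform(0, 1), enriched
members from Uniform(0, 0.01) — a continuous version of the
significant/non-significant dichotomy. The default scenario plants one
set of 30 genes with 60% enriched members in a background of 2,000,
plus eight signal-free decoys of the same size overlapping the planted
set by 40–80%. Expression matrices combine 200 expressed rows
(log-normal, log2 location ~ N(8, 1.5), per-row log2 sd U(0.3, 0.9))
with 50 silent rows near the detection floor (log2 location ~ N(3,
0.3), sd 0.05) across 10 samples. Identical seeds give byte-identical
fixtures.

What this does *not* emulate: correlated gene-gene noise, the
heavy-tailed p-value distributions of real differential-expression
runs, hierarchical (ontology-like) set structure, or realistic
database-scale collections of thousands of sets. Passing the planted
recovery tests therefore demonstrates the elimination and
prioritisation mechanics, not field performance on a given annotation
database.

The figure-style oracle fixtures (`make_figure_case`) are fully
determined constructions of the four canonical overlap topologies. The
chain case uses a background of 200 genes: the tail set's significance
must come from genes shared with the middle set, which the middle set
in turn shares with the head, so head and tail necessarily intersect
in significant genes; only at a small background size does that
intersection stay above the candidate-pair cutoff, which is what the
canonical chain scenario requires (the head must not confront the tail
directly).

## Limitations

- The minimum over rank thresholds is not corrected for the multiple
  thresholds it scans, so the primary statistic's null pass rate at a
  nominal 0.05 is well above 0.05 (it grows with set size). The
  pipeline relies on the elimination and component-correction stages —
  and, in realistic collections, on Holm running over *many*
  components — to restore specificity. With very small collections
  (few candidate components) the component-level Holm divisor is
  small and residual false positives can survive label permutation;
  `scripts/acceptance.py` reports the measured clean-permutation rate
  for the default (9-set) synthetic scenario.
- The empirical null assumes PageRank values from uniform random
  G(n, m) digraphs are adequately summarised by a single normal; for
  very small or very dense networks the pooled distribution is
  noticeably non-normal and the SetRank p-values should be read as
  ranks, not calibrated probabilities.
- Invalidation cycles of length ≥ 3 have no canonical resolution; the
  conservative retain-all rule is a documented choice.
- Detection calling presumes at least a modest fraction of rows are
  genuinely variable; on an all-constant matrix the cutoffs degenerate
  (a warning is raised and every row is called detected).
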