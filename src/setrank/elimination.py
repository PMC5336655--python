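"""Overlap-driven false-positive elimination.

A gene set can reach significance solely because it overlaps a genuinely
enriched set.  To detect this, every pair of initially significant sets
whose intersection is larger than expected by chance is re-evaluated on
the set differences A\\B and B\\A: if a set's significance vanishes once
the shared genes are removed while the partner's does not, the set is
recorded as *invalidated* by the partner.  The recorded relations form a
directed invalidation graph; a fixpoint pass over that graph decides
which sets are discarded as false positives.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .collections import GeneSet, GeneSetCollection
from .stats import intersection_significance, primary_pvalue

#: Verdict labels for a pair evaluation.
A_INVALIDATED = "a_invalidated"
B_INVALIDATED = "b_invalidated"
MUTUAL = "mutual"
NONE = "none"
SUBSET_AB = "subset_ab"  # A ⊊ B: only B re-evaluated
SUBSET_BA = "subset_ba"  # B ⊊ A: only A re-evaluated


@dataclass
class PairEvaluation:
    """Outcome of re-evaluating a significantly intersecting set pair.

    ``p_prime_a``/``p_prime_b`` are the primary statistics recomputed on
    the set differences (a set that is not re-evaluated — the subset
    side of a subset pair — keeps its primary p-value).  ``invalidated``
    lists the set IDs whose significance was explained away.
    """

    set_a: str
    set_b: str
    intersection_size: int
    p_intersection: float
    p_prime_a: float
    p_prime_b: float
    verdict: str
    invalidated: tuple = ()


def initial_significant_sets(collection: GeneSetCollection, input_data,
                             set_p_cutoff: float = 0.05) -> dict:
    """Primary p-value screen: sets with p <= cutoff, as {set_id: p}.

    A loose cutoff (0.01–0.05) is recommended here to avoid false
    negatives; downstream stages handle the false positives this lets
    through.
    """
    if not (0 < set_p_cutoff < 1):
        raise ValueError("set_p_cutoff must lie in (0, 1)")
    out = {}
    for s in collection:
        p = primary_pvalue(input_data, s)
        if p <= set_p_cutoff:
            out[s.set_id] = p
    return out


def candidate_pairs(sig_ids, collection: GeneSetCollection, l: int,
                    intersection_cutoff: float = 0.01) -> list:
    """Unordered set pairs whose overlap is significantly large.

    Returns the pairs (sorted IDs) with intersection-significance p
    strictly below the cutoff; only these are re-evaluated, which keeps
    the pairwise stage from scaling with the square of the collection.
    """
    if not (0 < intersection_cutoff < 1):
        raise ValueError("intersection_cutoff must lie in (0, 1)")
    by_id = collection.by_id
    pairs = []
    for id_a, id_b in itertools.combinations(sorted(sig_ids), 2):
        a, b = by_id[id_a], by_id[id_b]
        if not (a.genes & b.genes):
            continue
        p = intersection_significance(a, b, l)
        if p < intersection_cutoff:
            pairs.append((id_a, id_b))
    return pairs


def _difference_pvalue(diff_genes: frozenset, input_data) -> float:
    """Primary p of a set difference; empty difference carries no evidence."""
    if not diff_genes:
        return 1.0
    return primary_pvalue(input_data, diff_genes)


def evaluate_pair(set_a: GeneSet, set_b: GeneSet, input_data,
                  set_p_cutoff: float = 0.05,
                  p_intersection: float | None = None) -> PairEvaluation:
    """Re-test a significantly intersecting pair on its set differences.

    Computes p' for A on A\\B and for B on B\\A with the same primary
    statistic as the initial screen.  A set whose p' rises above the
    cutoff while the partner's stays below is invalidated; if both rise
    the pair is *mutual* (significance lives in the intersection and
    neither set is discarded).  When one set is a proper subset of the
    other, only the superset is re-evaluated.
    """
    inter = set_a.genes & set_b.genes
    if p_intersection is None:
        p_intersection = float("nan")

    if set_a.genes < set_b.genes:  # A ⊊ B: only B re-evaluated
        p_b = _difference_pvalue(set_b.genes - set_a.genes, input_data)
        p_a = primary_pvalue(input_data, set_a)
        invalid = (set_b.set_id,) if p_b > set_p_cutoff else ()
        return PairEvaluation(set_a.set_id, set_b.set_id, len(inter),
                              p_intersection, p_a, p_b, SUBSET_AB, invalid)
    if set_b.genes < set_a.genes:  # B ⊊ A: only A re-evaluated
        p_a = _difference_pvalue(set_a.genes - set_b.genes, input_data)
        p_b = primary_pvalue(input_data, set_b)
        invalid = (set_a.set_id,) if p_a > set_p_cutoff else ()
        return PairEvaluation(set_a.set_id, set_b.set_id, len(inter),
                              p_intersection, p_a, p_b, SUBSET_BA, invalid)

    p_a = _difference_pvalue(set_a.genes - set_b.genes, input_data)
    p_b = _difference_pvalue(set_b.genes - set_a.genes, input_data)
    above_a = p_a > set_p_cutoff
    above_b = p_b > set_p_cutoff
    if above_a and above_b:
        verdict, invalid = MUTUAL, ()
    elif above_a:
        verdict, invalid = A_INVALIDATED, (set_a.set_id,)
    elif above_b:
        verdict, invalid = B_INVALIDATED, (set_b.set_id,)
    else:
        verdict, invalid = NONE, ()
    return PairEvaluation(set_a.set_id, set_b.set_id, len(inter),
                          p_intersection, p_a, p_b, verdict, invalid)


def evaluate_all_pairs(pairs, collection: GeneSetCollection, input_data,
                       set_p_cutoff: float = 0.05, l: int | None = None) -> list:
    """Evaluate every candidate pair (two-phase: verdicts first)."""
    by_id = collection.by_id
    if l is None:
        l = len(input_data.gene_universe())
    evals = []
    for id_a, id_b in pairs:
        a, b = by_id[id_a], by_id[id_b]
        p_int = intersection_significance(a, b, l)
        evals.append(evaluate_pair(a, b, input_data, set_p_cutoff,
                                   p_intersection=p_int))
    return evals


def build_invalidation_graph(sig_ids, pair_evals) -> nx.DiGraph:
    """Directed graph with edges pointing at invalidated sets.

    An edge X -> Y records that Y's significance was explained away by
    its overlap with X.  Mutual pairs contribute no edges; the node
    attribute ``mutual_with`` collects the partners of such pairs.
    """
    g = nx.DiGraph()
    g.add_nodes_from(sig_ids)
    for ev in pair_evals:
        for victim in ev.invalidated:
            invalidator = ev.set_b if victim == ev.set_a else ev.set_a
            g.add_edge(invalidator, victim)
        if ev.verdict == MUTUAL:
            g.nodes[ev.set_a].setdefault("mutual_with", set()).add(ev.set_b)
            g.nodes[ev.set_b].setdefault("mutual_with", set()).add(ev.set_a)
    return g


def resolve_invalidations(graph: nx.DiGraph) -> tuple:
    """Fixpoint resolution of the invalidation graph.

    Layered rule, applied until stable: a node with no unresolved
    invalidators and no *retained* invalidator is retained; a node with
    at least one retained invalidator is discarded.  Sources are thus
    retained, their victims discarded, and a victim-of-a-victim (the
    chain A -> B -> C) is retained again because its only invalidator
    was itself discarded.  Nodes on directed cycles with no external
    retained invalidator are retained conservatively: no member of the
    cycle is a clean witness against the others.

    Returns ``(discarded, retained, mutual_flags)`` where mutual_flags
    maps set IDs to the partners of mutual (intersection-only) pairs.
    """
    RETAINED, DISCARDED = "retained", "discarded"
    status = {}
    changed = True
    while changed:
        changed = False
        for node in sorted(graph.nodes):
            if node in status:
                continue
            preds = [p for p in graph.predecessors(node) if p != node]
            if any(status.get(p) == RETAINED for p in preds):
                status[node] = DISCARDED
                changed = True
            elif all(status.get(p) == DISCARDED for p in preds):
                # vacuously true for sources
                status[node] = RETAINED
                changed = True
    # Remaining nodes sit on cycles (or depend only on cycles) with no
    # retained invalidator: retain them.
    for node in graph.nodes:
        status.setdefault(node, RETAINED)
    discarded = {n for n, st in status.items() if st == DISCARDED}
    retained = {n for n, st in status.items() if st == RETAINED}
    mutual_flags = {n: frozenset(d["mutual_with"])
                    for n, d in graph.nodes(data=True) if d.get("mutual_with")}
    return discarded, retained, mutual_flags


def eliminate_false_positives(collection: GeneSetCollection, input_data,
                              sig_sets: dict,
                              set_p_cutoff: float = 0.05,
                              intersection_cutoff: float = 0.01) -> tuple:
    """Full elimination stage: pairs, verdicts, graph, resolution.

    Returns ``(discarded, retained, mutual_flags, pair_evals)``.
    """
    l = len(input_data.gene_universe())
    pairs = candidate_pairs(sig_sets.keys(), collection, l, intersection_cutoff)
    evals = evaluate_all_pairs(pairs, collection, input_data, set_p_cutoff, l=l)
    graph = build_invalidation_graph(sig_sets.keys(), evals)
    discarded, retained, mutual_flags = resolve_invalidations(graph)
    return discarded, retained, mutual_flags, evals


def pair_evaluations_frame(pair_evals):
    """Pair-evaluation table for debugging/export (TSV-friendly)."""
    import pandas as pd

    rows = [
        {
            "set_a": ev.set_a,
            "set_b": ev.set_b,
            "intersection_size": ev.intersection_size,
            "p_intersection": ev.p_intersection,
            "p_prime_a": ev.p_prime_a,
            "p_prime_b": ev.p_prime_b,
            "verdict": ev.verdict,
        }
        for ev in pair_evals
    ]
    cols = ["set_a", "set_b", "intersection_size", "p_intersection",
            "p_prime_a", "p_prime_b", "verdict"]
    return pd.DataFrame(rows, columns=cols)
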