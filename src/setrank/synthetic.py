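"""Seeded synthetic fixtures for every pipeline stage.

Three generators are provided: ranked gene lists with one or more
planted enriched sets among overlapping decoy sets; the matching
gene-set collections; and expression matrices containing rows with low
mean and low variance that represent undetected transcripts.  A fourth
constructor builds small, fully determined collection/list pairs that
realise the canonical overlap topologies (significance borrowed through
an overlap, significance confined to an intersection, a proper subset,
and a three-set invalidation chain) together with their expected
qualitative outcome, for use as test oracles.

The noise model: genes unrelated to the signal carry p-values drawn
uniformly from (0, 1); members of a truly affected set carry p-values
drawn uniformly from (0, 0.01), a continuous version of the
significant/non-significant dichotomy.  Identical seeds give
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collections import GeneSet, GeneSetCollection
from .stats import RankedGeneList

#: Upper bound of the significant-gene p-value pool.
SIG_P_MAX = 0.01


@dataclass
class SyntheticScenario:
    """Parameters of a planted-enrichment simulation.

    One gene set of ``planted_size`` genes is planted in a background
    of ``l`` genes; a fraction ``enriched_fraction`` of its members
    draw their p-values from the significant pool Uniform(0, 0.01),
    the rest (and every other gene) from Uniform(0, 1).  ``n_decoys``
    decoy sets of the same size overlap the planted set by fractions
    spaced across ``decoy_overlap`` but contain no signal of their own.
    """

    seed: int = 0
    l: int = 2000
    planted_size: int = 30
    enriched_fraction: float = 0.6
    n_decoys: int = 8
    decoy_overlap: tuple = (0.4, 0.8)
    decoy_size: int | None = None
    n_samples: int = 10
    n_expressed_rows: int = 200
    n_silent_rows: int = 50

    def __post_init__(self):
        lo, hi = self.decoy_overlap
        if not (0 <= lo <= hi <= 1):
            raise ValueError("decoy_overlap fractions must satisfy 0 <= lo <= hi <= 1")
        if not (0 <= self.enriched_fraction <= 1):
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if self.planted_size > self.l:
            raise ValueError("planted set larger than background")

    def gene_ids(self) -> np.ndarray:
        return np.array([f"g{k:06d}" for k in range(self.l)], dtype=object)

    def _rng(self, stream: int) -> np.random.Generator:
        # Independent, reproducible streams per generator.
        return np.random.default_rng([int(self.seed), stream])


def _memberships(scn: SyntheticScenario) -> dict:
    """Planted and decoy memberships, deterministic in the seed."""
    rng = scn._rng(1)
    genes = scn.gene_ids()
    planted = rng.choice(genes, size=scn.planted_size, replace=False)
    members = {"PLANTED": frozenset(planted)}
    decoy_size = scn.decoy_size or scn.planted_size
    lo, hi = scn.decoy_overlap
    fracs = np.linspace(lo, hi, scn.n_decoys) if scn.n_decoys > 1 else [lo]
    outside = np.array(sorted(set(genes) - set(planted)), dtype=object)
    for k, frac in enumerate(fracs):
        n_shared = int(round(frac * decoy_size))
        shared = rng.choice(planted, size=n_shared, replace=False)
        own = rng.choice(outside, size=decoy_size - n_shared, replace=False)
        members[f"DECOY{k:02d}"] = frozenset(shared) | frozenset(own)
    return members


def make_ranked_list(scn: SyntheticScenario) -> RankedGeneList:
    """Ranked list with the planted set's enriched members at the top."""
    rng = scn._rng(2)
    genes = scn.gene_ids()
    pvals = rng.uniform(0.0, 1.0, size=scn.l)
    planted = sorted(_memberships(scn)["PLANTED"])
    n_sig = int(round(scn.enriched_fraction * len(planted)))
    sig_members = scn._rng(3).choice(planted, size=n_sig, replace=False)
    pos = {g: k for k, g in enumerate(genes)}
    idx = np.array([pos[g] for g in sig_members], dtype=int)
    pvals[idx] = scn._rng(4).uniform(0.0, SIG_P_MAX, size=n_sig)
    return RankedGeneList(genes, pvals)


def make_decoy_collection(scn: SyntheticScenario) -> GeneSetCollection:
    """Planted set plus overlapping signal-free decoys."""
    members = _memberships(scn)
    sets = [GeneSet(sid, sid, "synthetic", genes)
            for sid, genes in sorted(members.items())]
    return GeneSetCollection(sets)


def make_expression_matrix(scn: SyntheticScenario) -> pd.DataFrame:
    """Non-log intensity matrix with known expressed and silent rows.

    Expressed rows are log-normal with high location (log2 mean ~
    N(8, 1.5)) and substantial per-row biological noise (log2 sd drawn
    from U(0.3, 0.9)); silent rows sit near the detection floor (log2
    mean ~ N(3, 0.3)) with only residual technical noise (log2 sd
    0.05).  Row IDs carry an ``EXPR_``/``SILENT_`` prefix so tests know
    the ground truth.
    """
    rng = scn._rng(5)
    n_expr, n_sil, n_samp = scn.n_expressed_rows, scn.n_silent_rows, scn.n_samples
    expr_loc = rng.normal(8.0, 1.5, size=n_expr)
    expr_sd = rng.uniform(0.3, 0.9, size=n_expr)
    expr = 2.0 ** (expr_loc[:, None] + rng.normal(0, 1, (n_expr, n_samp)) * expr_sd[:, None])
    sil_loc = rng.normal(3.0, 0.3, size=n_sil)
    sil = 2.0 ** (sil_loc[:, None] + rng.normal(0, 0.05, (n_sil, n_samp)))
    values = np.vstack([expr, sil])
    index = ([f"EXPR_{k:04d}" for k in range(n_expr)]
             + [f"SILENT_{k:04d}" for k in range(n_sil)])
    cols = [f"sample_{k:02d}" for k in range(n_samp)]
    return pd.DataFrame(values, index=index, columns=cols)


# ---------------------------------------------------------------------------
# Deterministic figure cases

def _figure_ranked_list(l: int, assigned: dict) -> RankedGeneList:
    """Ranked list of ``l`` genes with explicit p-values for some genes.

    The remaining genes are fillers with p-values evenly spread over
    (0.02, 1), so a p-value of x lands near rank x*l.
    """
    genes = list(assigned)
    pvals = [assigned[g] for g in genes]
    n_fill = l - len(genes)
    fillers = [f"FILL{k:04d}" for k in range(n_fill)]
    fill_p = np.linspace(0.02, 1.0, n_fill, endpoint=False)
    return RankedGeneList(np.array(genes + fillers, dtype=object),
                          np.array(pvals + list(fill_p)))


def make_figure_case(case: str):
    """Fully determined (collection, ranked list, expected) oracle cases.

    ``case`` is one of:

    ``"fig1"``
        Set A holds the signal; B shares exactly A's significant genes
        and nothing else significant, so B's enrichment is borrowed.
        Expected: B invalidated by A and discarded.
    ``"fig2_intersection"``
        All signal lies in the intersection of A and B; neither set
        difference is significant.  Expected: mutual pair, neither
        discarded, undirected intersection edge.
    ``"fig2_subset"``
        A is a proper subset of B carrying all the signal.  Expected:
        only the superset is re-evaluated, found empty, and discarded.
    ``"chain"``
        A invalidates B, B invalidates C, A is clean.  Expected:
        exactly B is discarded; C is retained because its only
        invalidator fell.

    Returns ``(collection, ranked_list, expected)`` where ``expected``
    records the discard/retain partition and qualitative verdicts.
    """
    sig = {f"S{k}": k * 1e-6 for k in range(1, 7)}  # ranks 1..6
    mid = lambda k: 0.30 + 0.05 * k  # noqa: E731  mid-list nulls

    if case == "fig1":
        a_own = {f"nA{k}": mid(k) for k in range(1, 4)}
        b_own = {f"nB{k}": mid(k + 3) for k in range(1, 7)}
        assigned = {**{k: sig[k] for k in ("S1", "S2", "S3", "S4", "S5")},
                    **a_own, **b_own}
        sets = [
            GeneSet("A", "signal set", "synthetic",
                    frozenset(["S1", "S2", "S3", "S4", "S5", *a_own])),
            GeneSet("B", "borrowing set", "synthetic",
                    frozenset(["S2", "S3", "S4", "S5", *b_own])),
        ]
        expected = {"discarded": {"B"}, "retained": {"A"},
                    "verdicts": {frozenset(("A", "B")): "b_invalidated"},
                    "mutual": set()}
        return GeneSetCollection(sets), _figure_ranked_list(1000, assigned), expected

    if case == "fig2_intersection":
        # Own genes spread over the whole list: a tight cluster of even
        # mid-list p-values would itself look mildly enriched.
        a_own = {f"nA{k}": 0.20 + 0.15 * k for k in range(1, 6)}
        b_own = {f"nB{k}": 0.27 + 0.14 * k for k in range(1, 6)}
        shared = ["S1", "S2", "S3", "S4", "S5"]
        assigned = {**{k: sig[k] for k in shared}, **a_own, **b_own}
        sets = [
            GeneSet("A", "intersection set A", "synthetic",
                    frozenset(shared) | frozenset(a_own)),
            GeneSet("B", "intersection set B", "synthetic",
                    frozenset(shared) | frozenset(b_own)),
        ]
        expected = {"discarded": set(), "retained": {"A", "B"},
                    "verdicts": {frozenset(("A", "B")): "mutual"},
                    "mutual": {"A", "B"}}
        return GeneSetCollection(sets), _figure_ranked_list(1000, assigned), expected

    if case == "fig2_subset":
        b_own = {f"nB{k}": mid(k) for k in range(1, 11)}
        core = ["S1", "S2", "S3", "S4", "S5"]
        assigned = {**{k: sig[k] for k in core}, **b_own}
        sets = [
            GeneSet("A", "core subset", "synthetic", frozenset(core)),
            GeneSet("B", "padded superset", "synthetic",
                    frozenset(core) | frozenset(b_own)),
        ]
        expected = {"discarded": {"B"}, "retained": {"A"},
                    "verdicts": {frozenset(("A", "B")): "subset"},
                    "mutual": set()}
        return GeneSetCollection(sets), _figure_ranked_list(1000, assigned), expected

    if case == "chain":
        # Small background: with a large l the A-C intersection (which
        # inevitably shares the chain's significant genes) would itself
        # become a candidate pair and A would invalidate C directly.
        a_own = {f"nA{k}": mid(k) for k in range(1, 5)}
        b_own = {f"nB{k}": mid(k + 4) for k in range(1, 7)}
        c_own = {f"nC{k}": 0.62 + 0.05 * k for k in range(1, 6)}
        assigned = {**sig, **a_own, **b_own, **c_own}
        sets = [
            GeneSet("A", "chain head", "synthetic",
                    frozenset(["S1", "S2", "S3", "S4", "S5", "S6", *a_own])),
            GeneSet("B", "chain middle", "synthetic",
                    frozenset(["S3", "S4", "S5", "S6", *b_own])),
            GeneSet("C", "chain tail", "synthetic",
                    frozenset(["S5", "S6", "nB1", "nB2", "nB3", *c_own])),
        ]
        expected = {"discarded": {"B"}, "retained": {"A", "C"},
                    "verdicts": {frozenset(("A", "B")): "b_invalidated",
                                 frozenset(("B", "C")): "b_invalidated"},
                    "mutual": set(),
                    "invalidation_edges": {("A", "B"), ("B", "C")}}
        return GeneSetCollection(sets), _figure_ranked_list(200, assigned), expected

    raise ValueError(f"unknown figure case {case!r}")


def write_fixtures(scn: SyntheticScenario, out_dir):
    """Write a scenario as the TSV/GMT files the CLI consumes."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    ranked = make_ranked_list(scn)
    coll = make_decoy_collection(scn)
    matrix = make_expression_matrix(scn)

    ranked_path = os.path.join(out_dir, "ranked_list.tsv")
    pd.DataFrame({"gene": ranked.genes, "p": ranked.pvalues}).to_csv(
        ranked_path, sep="\t", header=False, index=False)

    gmt_path = os.path.join(out_dir, "collection.gmt")
    with open(gmt_path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")

    matrix_path = os.path.join(out_dir, "expression_matrix.tsv")
    matrix.to_csv(matrix_path, sep="\t")
    return {"ranked_list": ranked_path, "collection": gmt_path,
            "expression_matrix": matrix_path}
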