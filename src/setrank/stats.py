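"""Primary enrichment statistics.

Two input modes are supported.  For a *ranked* gene list (every gene in
the experiment carries a significance p-value) the primary p-value of a
gene set is a cutoff-free minimum-hypergeometric statistic: at every
rank threshold realised by a member of the set, the hypergeometric
over-representation tail of the set within the top of the list is
computed, and the minimum over thresholds is returned.  No
multiple-testing correction is applied at this stage.

For *unranked* input (e.g. a cluster of selected genes against a
background) a single one-tailed Fisher exact test is used.

The same machinery provides the pairwise intersection-significance test
used to screen set pairs for overlap-driven false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .collections import GeneSet

_TINY = np.nextafter(0.0, 1.0)


@dataclass
class RankedGeneList:
    """Genes ordered by increasing significance p-value.

    ``genes`` and ``pvalues`` are parallel arrays sorted so that
    p-values are non-decreasing; ``l`` is the list length (the size of
    the background universe L every enrichment test is relative to).
    """

    genes: np.ndarray
    pvalues: np.ndarray

    def __post_init__(self):
        genes = np.asarray(self.genes, dtype=object)
        pvals = np.asarray(self.pvalues, dtype=float)
        if genes.shape != pvals.shape:
            raise ValueError("genes and pvalues must have equal length")
        if np.any((pvals < 0) | (pvals > 1)) or np.any(~np.isfinite(pvals)):
            raise ValueError("p-values must lie in [0, 1]")
        order = np.argsort(pvals, kind="stable")
        self.genes = genes[order]
        self.pvalues = pvals[order]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(
                "duplicate gene IDs in ranked list; collapse to the best "
                "p-value per gene before constructing (see from_frame)"
            )
        self._rank = {g: k for k, g in enumerate(self.genes)}

    @property
    def l(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self._rank

    def gene_universe(self) -> frozenset:
        return frozenset(self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene_col=0, p_col=1,
                   collapse_duplicates: bool = False) -> "RankedGeneList":
        """Build from a two-column DataFrame (gene ID, p-value).

        With ``collapse_duplicates`` repeated genes keep their best
        (smallest) p-value; otherwise duplicates raise.
        """
        genes = df.iloc[:, gene_col] if isinstance(gene_col, int) else df[gene_col]
        pvals = df.iloc[:, p_col] if isinstance(p_col, int) else df[p_col]
        sub = pd.DataFrame({"gene": genes.astype(str), "p": pvals.astype(float)})
        if collapse_duplicates:
            sub = sub.groupby("gene", as_index=False)["p"].min()
        return cls(sub["gene"].to_numpy(), sub["p"].to_numpy())

    @classmethod
    def from_tsv(cls, path, collapse_duplicates: bool = False) -> "RankedGeneList":
        """Read a 2-column TSV (gene ID, p-value), no header."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls.from_frame(df, collapse_duplicates=collapse_duplicates)

    def rank_profile(self, members) -> tuple[np.ndarray, np.ndarray]:
        """Per-member (i, l_i) profile of a gene set within this list.

        Members are ordered by their p-value; ``i`` runs 1..s and
        ``l_i`` counts the genes in L ranking above or equal — i.e. with
        a p-value less than or equal to — member i.  Tied genes all
        receive the count of the full tied block.
        """
        idx = np.array([self._rank[g] for g in members], dtype=int)
        member_p = self.pvalues[idx]
        member_p.sort()
        l_i = np.searchsorted(self.pvalues, member_p, side="right")
        i = np.arange(1, len(member_p) + 1)
        return i, l_i


@dataclass
class ClusterInput:
    """Unranked input: a cluster C of selected genes within a background L."""

    background: frozenset
    cluster: frozenset

    def __post_init__(self):
        self.background = frozenset(self.background)
        self.cluster = frozenset(self.cluster)
        if not self.cluster <= self.background:
            raise ValueError("cluster must be a subset of the background")

    @property
    def l(self) -> int:
        return len(self.background)

    @property
    def c(self) -> int:
        return len(self.cluster)

    def gene_universe(self) -> frozenset:
        return self.background


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """Over-representation tail of a 2x2 table [[a, b], [c, d]].

    Returns ``P(X >= a)`` under the hypergeometric law with the table's
    margins (population ``a+b+c+d``, successes ``a+b``, draws ``a+c``).
    Never underflows to exactly 0.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("contingency counts must be non-negative")
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    p = float(hypergeom.sf(a - 1, n_total, a + b, a + c))
    return min(max(p, _TINY), 1.0)


def primary_pvalue_ranked(ranked: RankedGeneList, gene_set) -> float:
    """Minimum-hypergeometric primary p-value of a set on a ranked list.

    For each member rank ``i`` with threshold count ``l_i``, computes
    the tail ``P(X >= i)`` of a hypergeometric with population ``l``,
    ``s`` successes and ``l_i`` draws, and returns the minimum over
    ``i``.  The minimum is taken only at thresholds realised by set
    members.
    """
    members = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    if not members:
        raise ValueError("gene set is empty")
    missing = [g for g in members if g not in ranked]
    if missing:
        raise ValueError(
            f"{len(missing)} set member(s) absent from the ranked list "
            f"(e.g. {sorted(missing)[:3]}); intersect with the background first"
        )
    s = len(members)
    i, l_i = ranked.rank_profile(members)
    tails = hypergeom.sf(i - 1, ranked.l, s, l_i)
    p = float(np.min(tails))
    return min(max(p, _TINY), 1.0)


def primary_pvalue_unranked(cluster_input: ClusterInput, gene_set) -> float:
    """Fisher exact over-representation p of a set within a cluster.

    Tests the table [[n, s-n], [c-n, l-(c+s-n)]] with ``n = |C ∩ S|``.
    """
    members = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    if not members:
        raise ValueError("gene set is empty")
    if not members <= cluster_input.background:
        raise ValueError("gene set must be a subset of the background")
    l = cluster_input.l
    c = cluster_input.c
    s = len(members)
    n = len(members & cluster_input.cluster)
    return fisher_one_tailed(n, s - n, c - n, l - (c + s - n))


def primary_pvalue(input_data, gene_set) -> float:
    """Dispatch on input mode (ranked list vs. cluster)."""
    if isinstance(input_data, RankedGeneList):
        return primary_pvalue_ranked(input_data, gene_set)
    if isinstance(input_data, ClusterInput):
        return primary_pvalue_unranked(input_data, gene_set)
    raise TypeError(f"unsupported input type {type(input_data).__name__}")


def intersection_significance(set_m, set_n, l: int) -> float:
    """Probability that two sets share at least their observed overlap.

    Over-representation tail ``P(|M ∩ N| >= i)`` of a hypergeometric
    with population ``l``, ``m`` successes and ``n`` draws; symmetric in
    the two sets.
    """
    genes_m = set_m.genes if isinstance(set_m, GeneSet) else frozenset(set_m)
    genes_n = set_n.genes if isinstance(set_n, GeneSet) else frozenset(set_n)
    m, n = len(genes_m), len(genes_n)
    i = len(genes_m & genes_n)
    if l < len(genes_m | genes_n):
        raise ValueError("background size l smaller than |M ∪ N|")
    # canonical argument order keeps the result bit-identical under swap
    big, small = (m, n) if m >= n else (n, m)
    p = float(hypergeom.sf(i - 1, l, big, small))
    return min(max(p, _TINY), 1.0)
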