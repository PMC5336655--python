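"""Model/Results interface to the full enrichment pipeline.

:class:`SetRankAnalysis` is built from a gene-set collection plus either
a ranked gene list or a cluster-within-background input; ``fit()`` runs
the four pipeline stages (primary screen, pairwise elimination, network
construction, SetRank scoring and correction cascade) and returns a
:class:`SetRankResults` holding the ordered result table, the typed
network, the pair evaluations and the stage diagnostics, with a
``summary()`` in the style of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .collections import GeneSetCollection, filter_collection
from .stats import ClusterInput, RankedGeneList
from . import elimination as elim
from . import network as netmod


class SetRankAnalysis:
    """Overlap-aware gene-set enrichment analysis.

    Parameters
    ----------
    collection : GeneSetCollection
        Gene sets to test; intersected with the input's gene universe
        and size-filtered on construction so that every downstream
        statistic is relative to the same background L.
    input_data : RankedGeneList or ClusterInput
        Ranked mode (per-gene significance p-values) or unranked mode
        (a cluster of selected genes within a background).
    set_p_cutoff : float, default 0.05
        Primary-screen cutoff; loose on purpose, later stages remove
        the false positives it admits.
    intersection_cutoff : float, default 0.01
        Cutoff on the pairwise intersection-significance screen.
    fdr_cutoff : float, default 0.05
        Cutoff on component-level Holm-adjusted p-values; components
        above it are dropped from the final table.
    min_set_size, max_set_size : int
        Size window applied after intersecting sets with the
        background (defaults 3 and 500).
    n_random_networks : int, default 100
        Random networks used for the empirical SetRank null.
    """

    def __init__(self, collection: GeneSetCollection, input_data, *,
                 set_p_cutoff: float = 0.05,
                 intersection_cutoff: float = 0.01,
                 fdr_cutoff: float = 0.05,
                 min_set_size: int = 3,
                 max_set_size: int = 500,
                 n_random_networks: int = 100):
        for name, v in (("set_p_cutoff", set_p_cutoff),
                        ("intersection_cutoff", intersection_cutoff),
                        ("fdr_cutoff", fdr_cutoff)):
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not isinstance(input_data, (RankedGeneList, ClusterInput)):
            raise TypeError("input_data must be a RankedGeneList or ClusterInput")
        self.input_data = input_data
        self.background = input_data.gene_universe()
        self.collection = filter_collection(collection, min_set_size,
                                            max_set_size, self.background)
        self.set_p_cutoff = set_p_cutoff
        self.intersection_cutoff = intersection_cutoff
        self.fdr_cutoff = fdr_cutoff
        self.min_set_size = min_set_size
        self.max_set_size = max_set_size
        self.n_random_networks = n_random_networks

    @classmethod
    def from_files(cls, gmt_paths, ranked_list_path=None, *, db_labels=None,
                   cluster_path=None, background_path=None,
                   collapse_duplicates=False, **kwargs) -> "SetRankAnalysis":
        """Build from GMT file(s) and a ranked-list TSV or cluster list."""
        from .collections import read_gmt, merge_collections

        if isinstance(gmt_paths, (str, bytes)) or hasattr(gmt_paths, "__fspath__"):
            gmt_paths = [gmt_paths]
        labels = list(db_labels) if db_labels else [None] * len(gmt_paths)
        coll = merge_collections(*[read_gmt(p, db=lab)
                                   for p, lab in zip(gmt_paths, labels)])
        if ranked_list_path is not None:
            input_data = RankedGeneList.from_tsv(
                ranked_list_path, collapse_duplicates=collapse_duplicates)
        elif cluster_path is not None:
            if background_path is None:
                raise ValueError("unranked mode needs a background gene list")
            cluster = frozenset(_read_gene_list(cluster_path))
            background = frozenset(_read_gene_list(background_path))
            input_data = ClusterInput(background, cluster)
        else:
            raise ValueError("provide either ranked_list_path or cluster_path")
        return cls(coll, input_data, **kwargs)

    @property
    def mode(self) -> str:
        return "ranked" if isinstance(self.input_data, RankedGeneList) else "unranked"

    def fit(self, seed=None, n_random_networks=None) -> "SetRankResults":
        """Run the full pipeline; ``seed`` fixes the empirical null."""
        n_rand = n_random_networks or self.n_random_networks
        sig = elim.initial_significant_sets(self.collection, self.input_data,
                                            self.set_p_cutoff)
        discarded, retained, mutual_flags, pair_evals = \
            elim.eliminate_false_positives(self.collection, self.input_data, sig,
                                           self.set_p_cutoff,
                                           self.intersection_cutoff)
        net = netmod.build_network(retained, pair_evals, self.collection, sig,
                                   mutual_flags)
        netmod.setrank_values(net)
        if len(net):
            netmod.setrank_pvalues(net, n_random=n_rand, seed=seed)
        netmod.corrected_pvalues(net, pair_evals)
        netmod.component_correction(net, self.fdr_cutoff)
        table = netmod.order_results(net, fdr_cutoff=self.fdr_cutoff)
        n_components = len({d.get("component_id")
                            for _, d in net.graph.nodes(data=True)})
        return SetRankResults(
            model=self, network=net, table=table,
            significant_sets=sig, discarded=frozenset(discarded),
            retained=frozenset(retained), mutual_flags=mutual_flags,
            pair_evaluations=pair_evals, seed=seed,
            stage_counts={
                "collection_sets": len(self.collection),
                "background_genes": len(self.background),
                "initially_significant": len(sig),
                "pairs_screened": len(pair_evals),
                "sets_discarded": len(discarded),
                "sets_retained": len(retained),
                "components": n_components,
                "reported": len(table),
            })


@dataclass
class SetRankResults:
    """Fitted pipeline output.

    ``table`` is the final ordered result table (components past the
    FDR cutoff excluded); ``network`` the typed gene-set network with
    the per-node score blocks; ``pair_evaluations`` the elimination
    stage's evidence.
    """

    model: SetRankAnalysis
    network: "netmod.GeneSetNetwork"
    table: pd.DataFrame
    significant_sets: dict
    discarded: frozenset
    retained: frozenset
    mutual_flags: dict
    pair_evaluations: list
    seed: object = None
    stage_counts: dict = field(default_factory=dict)

    @property
    def ranked_set_ids(self) -> list:
        return self.table["set_id"].tolist()

    def full_table(self) -> pd.DataFrame:
        """Result table without the component-level FDR filter."""
        return netmod.order_results(self.network, fdr_cutoff=None)

    def pair_table(self) -> pd.DataFrame:
        return elim.pair_evaluations_frame(self.pair_evaluations)

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path):
        netmod.export_graphml(self.network, path)

    def summary(self) -> str:
        """Human-readable run summary with stage counts and top sets."""
        m = self.model
        lines = [
            "Gene-set enrichment analysis (SetRank prioritisation)",
            "=" * 56,
            f"mode:                 {m.mode}",
            f"background genes (l): {len(m.background)}",
            f"gene sets tested:     {len(m.collection)}",
            f"set p cutoff:         {m.set_p_cutoff}",
            f"intersection cutoff:  {m.intersection_cutoff}",
            f"component FDR cutoff: {m.fdr_cutoff}",
            "-" * 56,
        ]
        for key in ("initially_significant", "pairs_screened",
                    "sets_discarded", "sets_retained", "components",
                    "reported"):
            lines.append(f"{key.replace('_', ' '):<22}{self.stage_counts.get(key, 0)}")
        lines.append("-" * 56)
        if len(self.table):
            top = self.table.head(10)[["rank", "set_id", "name", "size",
                                       "p_setrank", "p_setrank_holm",
                                       "p_corrected", "setrank_value"]]
            lines.append(top.to_string(index=False,
                                       float_format=lambda x: f"{x:.3g}"))
        else:
            lines.append("no gene set passed the correction cascade")
        return "\n".join(lines)


def _read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
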