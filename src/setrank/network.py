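"""Gene-set network construction and SetRank prioritisation.

Retained gene sets become nodes of a typed network: *subset* edges
(directed from subset to superset), *intersection* edges (undirected;
the pair's significance lives entirely in the shared genes) and
*overlap* edges (directed toward the set with the stronger, i.e. lower,
p-value after subtracting the intersection).  Each edge carries the
Jaccard similarity of the two memberships.

The SetRank value of a node is its PageRank on the overlap-edge
subgraph (damping 0.85): sets that absorb significance from many
overlapping neighbours accumulate score.  An empirical null built from
random networks with the same node and edge count converts the scores
into p-values, which are Holm-adjusted.  A second Holm pass over the
weakly connected components — which by construction share no genes —
controls the component-level error rate; components above the FDR
cutoff are dropped from the final output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from statsmodels.stats.multitest import multipletests

from .elimination import MUTUAL, SUBSET_AB, SUBSET_BA

EDGE_SUBSET = "subset"
EDGE_INTERSECTION = "intersection"
EDGE_OVERLAP = "overlap"


def holm(pvalues) -> np.ndarray:
    """Holm step-down FWER adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


@dataclass
class GeneSetNetwork:
    """Typed network over retained gene sets with per-node score blocks.

    ``graph`` is a directed graph; intersection edges are stored once
    with ``directed=False``.  Node attributes accumulate the score
    block: p_primary, p_corrected, setrank_value, p_setrank,
    p_setrank_holm, component_id, p_component_holm.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def overlap_subgraph(self) -> nx.DiGraph:
        """Directed subgraph of overlap edges over all nodes."""
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from((u, v) for u, v, d in self.graph.edges(data=True)
                         if d["edge_type"] == EDGE_OVERLAP)
        return g

    def undirected_view(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False)


def build_network(retained, pair_evals, collection, sig_pvalues,
                  mutual_flags=None) -> GeneSetNetwork:
    """Assemble the typed gene-set network over retained sets.

    One edge per significantly intersecting retained pair: a subset edge
    when one membership properly contains the other, an intersection
    edge for mutual pairs, and an overlap edge otherwise, directed from
    the less significant set toward the one with the smaller p' after
    subtracting the intersection.
    """
    net = GeneSetNetwork()
    by_id = collection.by_id
    for sid in sorted(retained):
        s = by_id[sid]
        net.graph.add_node(sid, name=s.name, db=s.db, size=s.size,
                           p_primary=float(sig_pvalues[sid]),
                           intersection_only=False)
    if mutual_flags:
        for sid in mutual_flags:
            if sid in net.graph:
                net.graph.nodes[sid]["intersection_only"] = True

    for ev in pair_evals:
        a, b = ev.set_a, ev.set_b
        if a not in net.graph or b not in net.graph:
            continue
        ga, gb = by_id[a], by_id[b]
        inter = len(ga.genes & gb.genes)
        if inter == 0:
            continue
        jac = inter / len(ga.genes | gb.genes)
        attrs = {"jaccard": float(jac), "intersection_size": inter,
                 "directed": True}
        if ev.verdict == SUBSET_AB:
            net.graph.add_edge(a, b, edge_type=EDGE_SUBSET, **attrs)
        elif ev.verdict == SUBSET_BA:
            net.graph.add_edge(b, a, edge_type=EDGE_SUBSET, **attrs)
        elif ev.verdict == MUTUAL:
            attrs["directed"] = False
            net.graph.add_edge(*sorted((a, b)), edge_type=EDGE_INTERSECTION,
                               **attrs)
        else:
            # Overlap: direction toward the stronger (lower) p'.
            if ev.p_prime_a <= ev.p_prime_b:
                net.graph.add_edge(b, a, edge_type=EDGE_OVERLAP, **attrs)
            else:
                net.graph.add_edge(a, b, edge_type=EDGE_OVERLAP, **attrs)
    return net


def pagerank(graph: nx.DiGraph, damping: float = 0.85,
             tol: float = 1e-12, max_iter: int = 10_000) -> dict:
    """PageRank by power iteration with uniform teleport.

    Dangling mass is redistributed uniformly; iteration stops when the
    L1 change drops below ``tol``.  Scores sum to 1.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    idx = {v: k for k, v in enumerate(nodes)}
    out_deg = np.zeros(n)
    edges = []
    for u, v in graph.edges:
        if u == v:
            continue
        edges.append((idx[u], idx[v]))
        out_deg[idx[u]] += 1
    src = np.array([e[0] for e in edges], dtype=int)
    dst = np.array([e[1] for e in edges], dtype=int)
    dangling = out_deg == 0

    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        contrib = np.zeros(n)
        if len(src):
            np.add.at(contrib, dst, x[src] / out_deg[src])
        dangling_mass = x[dangling].sum()
        x_new = (1 - damping) / n + damping * (contrib + dangling_mass / n)
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return {v: float(x[idx[v]]) for v in nodes}


def setrank_values(net: GeneSetNetwork, damping: float = 0.85) -> dict:
    """SetRank value per node: PageRank on the overlap-edge subgraph."""
    scores = pagerank(net.overlap_subgraph(), damping=damping)
    for node, sc in scores.items():
        net.graph.nodes[node]["setrank_value"] = sc
    return scores


def _random_digraph(n: int, m: int, rng: np.random.Generator) -> nx.DiGraph:
    """Uniform directed G(n, m): m distinct ordered pairs, no self-loops."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    max_edges = n * (n - 1)
    m = min(m, max_edges)
    if m == 0 or n < 2:
        return g
    # Sample edge codes without replacement; code k -> pair (u, v), u != v.
    codes = rng.choice(max_edges, size=m, replace=False)
    u = codes // (n - 1)
    r = codes % (n - 1)
    v = np.where(r >= u, r + 1, r)
    g.add_edges_from(zip(u.tolist(), v.tolist()))
    return g


def setrank_pvalues(net: GeneSetNetwork, n_random: int = 100,
                    seed=None, damping: float = 0.85) -> dict:
    """Empirical-null p-values for the SetRank scores, Holm-adjusted.

    Pools the PageRank values of ``n_random`` random directed networks
    with the same node and edge count as the overlap subgraph, fits a
    normal distribution to the pooled values and assigns each node the
    upper-tail probability of its observed score, followed by a Holm
    adjustment across nodes.  A degenerate null (zero variance) yields
    p = 1 for every node.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    sub = net.overlap_subgraph()
    nodes = sorted(sub.nodes)
    n, m = sub.number_of_nodes(), sub.number_of_edges()
    if n == 0:
        return {}
    observed = np.array([net.graph.nodes[v].get("setrank_value", 1.0 / n)
                         for v in nodes])
    rng = np.random.default_rng(seed)
    null_values = []
    for _ in range(n_random):
        g = _random_digraph(n, m, rng)
        null_values.extend(pagerank(g, damping=damping).values())
    null_values = np.asarray(null_values)
    mu, sd = float(null_values.mean()), float(null_values.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raw = np.ones(n)
    else:
        from scipy.stats import norm
        raw = norm.sf(observed, loc=mu, scale=sd)
        raw = np.clip(raw, np.nextafter(0.0, 1.0), 1.0)
    adj = holm(raw)
    for k, v in enumerate(nodes):
        net.graph.nodes[v]["p_setrank"] = float(raw[k])
        net.graph.nodes[v]["p_setrank_holm"] = float(adj[k])
    return {v: float(raw[k]) for k, v in enumerate(nodes)}


def corrected_pvalues(net: GeneSetNetwork, pair_evals) -> dict:
    """Corrected p per node: max of its p' against every network neighbour.

    Every edge marks genuine gene sharing, so all edge types contribute.
    On the subset side of a subset pair no difference is evaluated and
    the set's primary p stands in for its p' against that neighbour.
    An isolated node keeps its primary p.
    """
    pprime = {}  # (node, neighbour) -> node's p' against neighbour
    for ev in pair_evals:
        pprime[(ev.set_a, ev.set_b)] = ev.p_prime_a
        pprime[(ev.set_b, ev.set_a)] = ev.p_prime_b
    out = {}
    und = net.graph.to_undirected(as_view=True)
    for node, data in net.graph.nodes(data=True):
        vals = [pprime[(node, nb)] for nb in und.neighbors(node)
                if (node, nb) in pprime]
        p = max(vals) if vals else data["p_primary"]
        data["p_corrected"] = float(p)
        out[node] = float(p)
    return out


def component_correction(net: GeneSetNetwork, fdr_cutoff: float = 0.05) -> dict:
    """Component-level Holm correction.

    Weakly connected components (over all edge types; components share
    no genes) each get the minimum corrected p of their members; the
    component p-values are Holm-adjusted and inherited by every member.
    Components with adjusted p above ``fdr_cutoff`` are flagged for
    exclusion from the final output.
    """
    comps = sorted(nx.weakly_connected_components(net.graph),
                   key=lambda c: sorted(c)[0])
    if not comps:
        return {}
    comp_p = np.array([min(net.graph.nodes[v]["p_corrected"] for v in comp)
                       for comp in comps])
    adj = holm(comp_p)
    out = {}
    for cid, (comp, p_adj) in enumerate(zip(comps, adj)):
        passes = bool(p_adj <= fdr_cutoff)
        for v in comp:
            net.graph.nodes[v]["component_id"] = cid
            net.graph.nodes[v]["p_component_holm"] = float(p_adj)
            net.graph.nodes[v]["component_passes_fdr"] = passes
            out[v] = float(p_adj)
    return out


RESULT_COLUMNS = ["rank", "set_id", "name", "db", "size", "p_primary",
                  "p_corrected", "setrank_value", "p_setrank",
                  "p_setrank_holm", "component", "p_component_holm", "flags"]


def order_results(net: GeneSetNetwork, fdr_cutoff: float | None = 0.05
                  ) -> pd.DataFrame:
    """Final ordered result table.

    Stable three-key ascending sort: SetRank p-value, then its
    Holm-adjusted value, then the corrected p-value.  Components whose
    Holm-adjusted p exceeds the FDR cutoff are dropped (pass
    ``fdr_cutoff=None`` to keep everything).
    """
    rows = []
    for node, d in net.graph.nodes(data=True):
        if fdr_cutoff is not None and not d.get("component_passes_fdr", True):
            continue
        rows.append({
            "set_id": node,
            "name": d.get("name", node),
            "db": d.get("db", ""),
            "size": d.get("size", np.nan),
            "p_primary": d.get("p_primary", np.nan),
            "p_corrected": d.get("p_corrected", np.nan),
            "setrank_value": d.get("setrank_value", np.nan),
            "p_setrank": d.get("p_setrank", np.nan),
            "p_setrank_holm": d.get("p_setrank_holm", np.nan),
            "component": d.get("component_id", -1),
            "p_component_holm": d.get("p_component_holm", np.nan),
            "flags": "intersection_only" if d.get("intersection_only") else "",
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[1:])
    if len(df):
        df = df.sort_values(["p_setrank", "p_setrank_holm", "p_corrected"],
                            kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def export_tsv(net: GeneSetNetwork, path, fdr_cutoff: float | None = 0.05):
    """Write the ordered result table as TSV."""
    order_results(net, fdr_cutoff=fdr_cutoff).to_csv(path, sep="\t", index=False)


def export_graphml(net: GeneSetNetwork, path):
    """Write the network as GraphML (Cytoscape-compatible attributes).

    Node attributes: name, db, size and the full score block.  Edge
    attributes: edge_type, directed flag, Jaccard similarity and
    intersection size.
    """
    g = nx.DiGraph()
    for node, d in net.graph.nodes(data=True):
        attrs = {k: v for k, v in d.items()
                 if isinstance(v, (str, int, float, bool, np.floating, np.integer))}
        g.add_node(node, **attrs)
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, **{k: val for k, val in d.items()
                            if isinstance(val, (str, int, float, bool))})
    nx.write_graphml(g, path)


def load_graphml(path) -> GeneSetNetwork:
    """Re-read an exported GraphML file into a GeneSetNetwork."""
    g = nx.read_graphml(path)
    net = GeneSetNetwork()
    net.graph = nx.DiGraph(g)
    return net
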