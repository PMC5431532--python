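"""Typed TF-miRNA-gene regulatory networks, FFL motifs and null models.

The regulatory graph is directed with three node classes (TF, miRNA, gene)
and four legal edge types (TF->gene, TF->miRNA, miRNA->gene, miRNA->TF);
since the classes are disjoint, an ordered node pair determines its edge
type.  Feed-forward loops are the circuits of interest:

* 3-node TF-FFL:    TF->miRNA, TF->gene, miRNA->gene
* 3-node miRNA-FFL: miRNA->TF, TF->gene, miRNA->gene
* 4-node composite: one TF and one miRNA that both target two genes, plus a
  TF->miRNA or miRNA->TF edge between the regulators.

Motif significance is assessed per motif against networks randomized by
double-edge swaps confined within each edge type, which preserves every
node's per-type in/out degree exactly: the empirical p is the smoothed
fraction of randomized networks that contain the same typed circuit on the
same node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import EDGE_TYPES, FFLMotif

log = logging.getLogger(__name__)


@dataclass
class NullModelConfig:
    """Parameters of the degree-preserving randomization null."""

    n_random: int = 1000
    swap_multiplier: int = 10  # attempted swaps per edge (Q)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swap_multiplier < 1:
            raise ValueError("swap_multiplier must be >= 1")


class TypedRegNetwork:
    """Directed regulatory graph with disjoint TF/miRNA/gene node classes.

    Thin wrapper over a :class:`networkx.DiGraph`: node attribute ``klass``,
    edge attributes ``edge_type``, ``r`` (optional expression correlation)
    and ``evidence``.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    def node_class(self, node: str) -> str:
        return self.graph.nodes[node]["klass"]

    def nodes_of_class(self, klass: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["klass"] == klass]

    def edges_of_type(self, edge_type: str) -> list[tuple[str, str]]:
        return [(u, v) for u, v, t in self.graph.edges(data="edge_type")
                if t == edge_type]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "TypedRegNetwork":
        return TypedRegNetwork(self.graph.copy())

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges())

    def per_type_degree_table(self) -> pd.DataFrame:
        """Per-node in/out degree split by edge type (null-model invariant)."""
        rows = []
        for etype in EDGE_TYPES.values():
            for u, v in self.edges_of_type(etype):
                rows.append((u, etype, "out"))
                rows.append((v, etype, "in"))
        df = pd.DataFrame(rows, columns=["node", "edge_type", "side"])
        return df.groupby(["node", "edge_type", "side"]).size().rename("degree").reset_index()


def assemble_grn(edges: pd.DataFrame, node_classes: dict[str, str]) -> TypedRegNetwork:
    """Build a typed network from a (source, target, edge_type, ...) table.

    Duplicate (source, target, edge_type) rows collapse to one edge.  Every
    edge's declared type must match its endpoint classes; offenders are
    collected and reported together.
    """
    g = nx.DiGraph()
    offenders = []
    for row in edges.itertuples(index=False):
        src, tgt, etype = row.source, row.target, row.edge_type
        for node in (src, tgt):
            if node not in node_classes:
                offenders.append(f"{src}->{tgt}: unknown class for {node}")
                break
        else:
            expected = EDGE_TYPES.get((node_classes[src], node_classes[tgt]))
            if expected is None or etype != expected:
                offenders.append(
                    f"{src}->{tgt}: declared {etype}, endpoint classes give {expected}")
                continue
            r = getattr(row, "r", None)
            evidence = getattr(row, "evidence", "")
            if g.has_edge(src, tgt):
                continue
            g.add_node(src, klass=node_classes[src])
            g.add_node(tgt, klass=node_classes[tgt])
            g.add_edge(src, tgt, edge_type=etype, r=r, evidence=evidence)
    if offenders:
        raise ValueError("class-inconsistent edges:\n" + "\n".join(offenders[:20]))
    return TypedRegNetwork(g)


def network_metrics(net: TypedRegNetwork) -> pd.DataFrame:
    """Per-node in/out degree, betweenness and closeness centrality.

    Betweenness is the unnormalized shortest-path count on the directed
    graph; closeness follows the reachable-set (Wasserman-Faust) convention
    over incoming paths, 0 for unreachable nodes.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    betw = nx.betweenness_centrality(g, normalized=False)
    close = nx.closeness_centrality(g, wf_improved=True)
    return pd.DataFrame({
        "node": list(g.nodes),
        "klass": [net.node_class(n) for n in g.nodes],
        "in_degree": [g.in_degree(n) for n in g.nodes],
        "out_degree": [g.out_degree(n) for n in g.nodes],
        "betweenness": [betw[n] for n in g.nodes],
        "closeness": [close[n] for n in g.nodes],
    }).set_index("node")


def identify_hubs(net: TypedRegNetwork, top_n: int = 5) -> dict[str, list[str]]:
    """Top regulators by out-degree and top genes by in-degree.

    Ties break toward the lexicographically smaller node identifier.
    """
    g = net.graph

    def top(nodes, degree_of):
        ranked = sorted(nodes, key=lambda n: (-degree_of(n), n))
        return ranked[:top_n]

    return {
        "tf_hubs": top(net.nodes_of_class("TF"), g.out_degree),
        "mirna_hubs": top(net.nodes_of_class("miRNA"), g.out_degree),
        "gene_hubs": top(net.nodes_of_class("gene"), g.in_degree),
    }


def _canonical_motif(motif_class: str, nodes: tuple[str, ...],
                     classes: tuple[str, ...],
                     edges: list[tuple[str, str]]) -> FFLMotif:
    return FFLMotif(nodes=nodes, node_classes=classes, motif_class=motif_class,
                    edges=tuple(sorted(edges)))


def enumerate_ffls(net: TypedRegNetwork, include_four_node: bool = True) -> list[FFLMotif]:
    """Enumerate all 3-node and 4-node feed-forward loops, each once.

    A TF/miRNA pair linked in both directions yields both a TF-FFL and a
    miRNA-FFL on the same triangle (distinct circuits).
    """
    g = net.graph
    tfs = net.nodes_of_class("TF")
    motifs: list[FFLMotif] = []

    for tf in tfs:
        tf_targets = {v for v in g.successors(tf) if net.node_class(v) == "gene"}
        if not tf_targets:
            continue
        partner_mirnas = {v for v in g.successors(tf) if net.node_class(v) == "miRNA"}
        partner_mirnas |= {u for u in g.predecessors(tf) if net.node_class(u) == "miRNA"}
        for m in sorted(partner_mirnas):
            m_targets = {v for v in g.successors(m) if net.node_class(v) == "gene"}
            shared = sorted(tf_targets & m_targets)
            if not shared:
                continue
            tf_to_m = g.has_edge(tf, m)
            m_to_tf = g.has_edge(m, tf)
            for gene in shared:
                base = [(tf, gene), (m, gene)]
                if tf_to_m:
                    motifs.append(_canonical_motif(
                        "TF-FFL", (tf, m, gene), ("TF", "miRNA", "gene"),
                        base + [(tf, m)]))
                if m_to_tf:
                    motifs.append(_canonical_motif(
                        "miRNA-FFL", (tf, m, gene), ("TF", "miRNA", "gene"),
                        base + [(m, tf)]))
            if include_four_node and len(shared) >= 2:
                reg_edges = ([(tf, m)] if tf_to_m else []) + ([(m, tf)] if m_to_tf else [])
                for g1, g2 in combinations(shared, 2):
                    motifs.append(_canonical_motif(
                        "composite-4", (tf, m, g1, g2),
                        ("TF", "miRNA", "gene", "gene"),
                        [(tf, g1), (tf, g2), (m, g1), (m, g2)] + reg_edges))
    return motifs


def clique_percolation(net: TypedRegNetwork, k: int = 3) -> list[frozenset[str]]:
    """k-clique percolation communities of the undirected simple projection.

    Communities are unions of k-cliques reachable through (k-1)-node
    overlaps; a node may belong to several communities.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    und = nx.Graph()
    und.add_nodes_from(net.graph.nodes)
    und.add_edges_from((u, v) for u, v in net.graph.edges() if u != v)
    comms = nx.community.k_clique_communities(und, k)
    return sorted((frozenset(c) for c in comms), key=lambda c: sorted(c))


def randomize_preserving_degree(
    net: TypedRegNetwork,
    config: NullModelConfig,
    rng: np.random.Generator | None = None,
) -> TypedRegNetwork:
    """Degree-preserving randomization by typed double-edge swaps.

    For each edge type, ``Q x |E_type|`` swap attempts are made; a swap
    exchanges targets of two edges of that type and is rejected when it
    would duplicate an existing edge (self-loops cannot arise because the
    endpoint classes of every type differ).  Per-node, per-type in/out
    degrees are invariant.  Networks with no swappable pair are returned as
    a copy with a log notice.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = net.graph
    new = nx.DiGraph()
    new.add_nodes_from(g.nodes(data=True))
    for etype in EDGE_TYPES.values():
        edges = net.edges_of_type(etype)
        if len(edges) < 2:
            if edges:
                log.debug("edge type %s has <2 edges; kept as-is", etype)
            for u, v in edges:
                new.add_edge(u, v, edge_type=etype)
            continue
        eset = set(edges)
        n_attempts = config.swap_multiplier * len(edges)
        picks = rng.integers(0, len(edges), size=(n_attempts, 2))
        for i, j in picks:
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if a == c or b == d:
                continue
            e1, e2 = (a, d), (c, b)
            if e1 in eset or e2 in eset:
                continue
            eset.remove(edges[i])
            eset.remove(edges[j])
            eset.add(e1)
            eset.add(e2)
            edges[i], edges[j] = e1, e2
        for u, v in edges:
            new.add_edge(u, v, edge_type=etype)
    return TypedRegNetwork(new)


def ffl_significance(
    net: TypedRegNetwork,
    motifs: list[FFLMotif],
    config: NullModelConfig,
) -> tuple[list[FFLMotif], list[FFLMotif]]:
    """Empirical per-motif significance against randomized networks.

    For each motif, ``p = (1 + B) / (1 + n_random)`` where ``B`` counts
    randomized networks containing every defining edge of the motif (same
    node set and topology).  Returns ``(annotated, retained)`` where
    ``retained`` keeps motifs with ``p <= alpha``.
    """
    rng = np.random.default_rng(config.seed)
    hits = np.zeros(len(motifs), dtype=int)
    for _ in range(config.n_random):
        rnet = randomize_preserving_degree(net, config, rng=rng)
        eset = rnet.edge_set()
        for i, motif in enumerate(motifs):
            if all(e in eset for e in motif.edges):
                hits[i] += 1
    annotated = [m.with_p((1 + int(h)) / (1 + config.n_random))
                 for m, h in zip(motifs, hits)]
    retained = [m for m in annotated if m.p_empirical <= config.alpha]
    return annotated, retained


def motifs_to_frame(motifs: list[FFLMotif]) -> pd.DataFrame:
    rows = [{
        "nodes": ";".join(m.nodes),
        "classes": ";".join(m.node_classes),
        "motif_class": m.motif_class,
        "p_empirical": m.p_empirical,
    } for m in motifs]
    return pd.DataFrame(rows, columns=["nodes", "classes", "motif_class", "p_empirical"])


def summarize_network(net: TypedRegNetwork) -> dict:
    """Node counts per class, edge counts per type, and degree summary."""
    g = net.graph
    degrees = [d for _, d in g.degree()]
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "nodes_per_class": {k: len(net.nodes_of_class(k)) for k in ("TF", "miRNA", "gene")},
        "edges_per_type": {t: len(net.edges_of_type(t)) for t in EDGE_TYPES.values()},
        "degree_min": int(min(degrees)) if degrees else 0,
        "degree_max": int(max(degrees)) if degrees else 0,
        "degree_mean": float(np.mean(degrees)) if degrees else 0.0,
    }


def random_typed_network(
    n_tf: int,
    n_mirna: int,
    n_gene: int,
    edge_prob: float,
    seed: int = 0,
) -> TypedRegNetwork:
    """Erdos-Renyi-style random typed network (each legal directed pair kept
    independently with ``edge_prob``); handy for null studies and testing."""
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:03d}" for i in range(n_tf)]
    mirs = [f"MIR{i:03d}" for i in range(n_mirna)]
    genes = [f"G{i:04d}" for i in range(n_gene)]
    g = nx.DiGraph()
    for n in tfs:
        g.add_node(n, klass="TF")
    for n in mirs:
        g.add_node(n, klass="miRNA")
    for n in genes:
        g.add_node(n, klass="gene")
    pairs = (
        [(t, x, "TF->gene") for t in tfs for x in genes]
        + [(t, m, "TF->miRNA") for t in tfs for m in mirs]
        + [(m, x, "miRNA->gene") for m in mirs for x in genes]
        + [(m, t, "miRNA->TF") for m in mirs for t in tfs]
    )
    keep = rng.random(len(pairs)) < edge_prob
    for (u, v, etype), kp in zip(pairs, keep):
        if kp:
            g.add_edge(u, v, edge_type=etype, r=None, evidence="random")
    return TypedRegNetwork(g)
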