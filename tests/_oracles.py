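"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive (quadratic/exhaustive) and shares no
code path with the package.
"""

from collections import deque
from itertools import combinations, product

import networkx as nx
import numpy as np


def brute_force_ffls(net):
    """Exhaustive scan over all class-valid node tuples for 3-/4-node FFLs.

    Returns a set of (motif_class, nodes) keys comparable to the package's
    enumeration output.
    """
    g = net.graph
    tfs = sorted(net.nodes_of_class("TF"))
    mirs = sorted(net.nodes_of_class("miRNA"))
    genes = sorted(net.nodes_of_class("gene"))
    found = set()
    for t in tfs:
        for m in mirs:
            t_to_m = g.has_edge(t, m)
            m_to_t = g.has_edge(m, t)
            if not (t_to_m or m_to_t):
                continue
            for gene in genes:
                if g.has_edge(t, gene) and g.has_edge(m, gene):
                    if t_to_m:
                        found.add(("TF-FFL", (t, m, gene)))
                    if m_to_t:
                        found.add(("miRNA-FFL", (t, m, gene)))
            for g1, g2 in combinations(genes, 2):
                if (g.has_edge(t, g1) and g.has_edge(t, g2)
                        and g.has_edge(m, g1) and g.has_edge(m, g2)):
                    found.add(("composite-4", (t, m, g1, g2)))
    return found


def brute_force_cpm(graph: nx.Graph, k: int):
    """Clique-graph components: all k-cliques, joined on (k-1)-node overlap."""
    cliques = [frozenset(c) for c in combinations(sorted(graph.nodes), k)
               if all(graph.has_edge(u, v) for u, v in combinations(c, 2))]
    meta = nx.Graph()
    meta.add_nodes_from(range(len(cliques)))
    for i, j in combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) >= k - 1:
            meta.add_edge(i, j)
    return sorted(
        (frozenset().union(*(cliques[i] for i in comp))
         for comp in nx.connected_components(meta)),
        key=lambda c: sorted(c),
    )


def quadratic_crosstalk_count(pathway_a, pathway_b, ppi_edges, min_confidence=0):
    """Double loop over exclusive gene pairs against the raw edge table."""
    shared = pathway_a & pathway_b
    a_only = pathway_a - shared
    b_only = pathway_b - shared
    edge_conf = {}
    for a, b, c in ppi_edges.itertuples(index=False):
        key = (a, b) if a < b else (b, a)
        edge_conf[key] = max(edge_conf.get(key, -1), c)
    count = 0
    for x in a_only:
        for y in b_only:
            key = (x, y) if x < y else (y, x)
            if edge_conf.get(key, -1) >= min_confidence:
                count += 1
    return count


def quadratic_overlap_counts(reads, precursors, stranded=False):
    """All-pairs interval overlap scan (half-open, >=1 bp)."""
    counts = {name: 0 for name in precursors["name"]}
    for pre in precursors.itertuples(index=False):
        for rd in reads.itertuples(index=False):
            if rd.chrom != pre.chrom:
                continue
            if stranded and rd.strand != "." and pre.strand != "." \
                    and rd.strand != pre.strand:
                continue
            if rd.start < pre.end and rd.end > pre.start:
                counts[pre.name] += 1
    return counts


def brute_force_betweenness(graph: nx.DiGraph):
    """Unnormalized betweenness via explicit shortest-path counting.

    sigma_st(v) = sigma_sv * sigma_vt when dist(s,v) + dist(v,t) = dist(s,t).
    """
    nodes = list(graph.nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in graph.successors(u):
                if v not in d:
                    d[v] = d[u] + 1
                    sig[v] = 0
                    queue.append(v)
                if d[v] == d[u] + 1:
                    sig[v] += sig[u]
        dist[s], sigma[s] = d, sig
    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bc


def exhaustive_crosstalk_p(pathways, matcher, adj_lookup, observed, pair):
    """Exact degree-matched-assignment null tail probability for one pair.

    Enumerates every per-degree-class combination for both pathways
    (uniform over assignments, matching the sampler) and returns
    P(count >= observed).
    """
    def assignments(genes):
        by_degree = {}
        for g in sorted(genes):
            by_degree.setdefault(matcher.degree_of[g], []).append(g)
        per_class = []
        for d in sorted(by_degree):
            k = len(by_degree[d])
            per_class.append(list(combinations(matcher.pools[d], k)))
        out = []
        for combo in product(*per_class):
            flat = [g for grp in combo for g in grp]
            if len(set(flat)) == len(flat):  # without replacement within pathway
                out.append(set(flat))
        return out

    a_opts = assignments(pathways[pair[0]])
    b_opts = assignments(pathways[pair[1]])
    total = hits = 0
    for a in a_opts:
        for b in b_opts:
            shared = a & b
            count = sum(1 for x in a - shared for y in b - shared
                        if adj_lookup(x, y))
            total += 1
            if count >= observed:
                hits += 1
    return hits / total
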