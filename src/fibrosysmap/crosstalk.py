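"""Pathway crosstalk against a degree-matched permutation null.

Two pathways "crosstalk" when the number of protein-protein interactions
linking their (non-shared) members exceeds what degree-matched random gene
sets would produce.  The null shuffles each pathway by replacing every gene
with a random gene of the same PPI degree (exact degree class when it has
enough members, else the nearest class by log-degree distance), repeated
``n_random`` times; the empirical p is the smoothed upper-tail fraction
``(1 + #{null >= observed}) / (1 + n_random)``.

Downstream filters follow the pipeline: pathways below a minimum size are
dropped up front, significant pairs are flagged for containing upregulated
genes on both sides, high-confidence first neighbors are collected, and
gene-set enrichment uses the one-sided hypergeometric test with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CrosstalkResult

log = logging.getLogger(__name__)


class PPINetwork:
    """Undirected weighted PPI network (STRING-style 0-1000 confidences).

    Built from a (node_a, node_b, confidence) edge table; self-loops are
    rejected, duplicate pairs keep the highest confidence.
    """

    def __init__(self, edges: pd.DataFrame):
        conf = edges["confidence"].to_numpy()
        if ((conf < 0) | (conf > 1000)).any():
            raise ValueError("confidence values must lie in [0, 1000]")
        if (edges["node_a"] == edges["node_b"]).any():
            raise ValueError("self-loops are not allowed")
        best: dict[tuple[str, str], int] = {}
        for a, b, c in zip(edges["node_a"], edges["node_b"], conf):
            key = (a, b) if a < b else (b, a)
            if best.get(key, -1) < c:
                best[key] = int(c)
        self.edges = pd.DataFrame(
            [(a, b, c) for (a, b), c in sorted(best.items())],
            columns=["node_a", "node_b", "confidence"],
        )
        self.adj: dict[str, dict[str, int]] = {}
        for a, b, c in self.edges.itertuples(index=False):
            self.adj.setdefault(a, {})[b] = c
            self.adj.setdefault(b, {})[a] = c

    @property
    def nodes(self) -> list[str]:
        return sorted(self.adj)

    def degree(self, node: str, min_confidence: int = 0) -> int:
        return sum(1 for c in self.adj.get(node, {}).values() if c >= min_confidence)

    def confidence(self, a: str, b: str) -> int | None:
        return self.adj.get(a, {}).get(b)


def filter_pathways(
    pathways: dict[str, set[str]],
    min_genes: int = 6,
    restrict_to: set[str] | None = None,
) -> dict[str, set[str]]:
    """Drop pathways with fewer than ``min_genes`` members, optionally after
    intersecting each pathway with a context gene set (e.g. the consensus
    DEG signature)."""
    out = {}
    for pid, genes in pathways.items():
        kept = genes & restrict_to if restrict_to is not None else set(genes)
        if len(kept) >= min_genes:
            out[pid] = kept
    return out


def crosstalk_count(
    pathway_a: set[str],
    pathway_b: set[str],
    ppi: PPINetwork,
    min_confidence: int = 0,
    include_shared: bool = False,
) -> int:
    """Number of PPI edges linking A-only genes to B-only genes.

    Genes in both pathways are excluded from both sides unless
    ``include_shared`` (then an edge counts whenever its endpoints fall on
    different sides or either endpoint is shared-to-exclusive).
    """
    if include_shared:
        a_side, b_side = set(pathway_a), set(pathway_b)
    else:
        shared = pathway_a & pathway_b
        a_side, b_side = pathway_a - shared, pathway_b - shared
    count = 0
    for g in a_side:
        nbrs = ppi.adj.get(g)
        if not nbrs:
            continue
        for h, c in nbrs.items():
            if h in b_side and c >= min_confidence and (include_shared or h != g):
                count += 1
    if include_shared:
        # edges with both endpoints in the overlap would be double counted
        shared = pathway_a & pathway_b
        for g, h in combinations(sorted(shared), 2):
            c = ppi.confidence(g, h)
            if c is not None and c >= min_confidence:
                count -= 1
    return count


class DegreeMatcher:
    """Degree-matched candidate pools over a PPI network.

    Genes absent from the PPI are treated as degree 0 and shuffled within
    the degree-0 class.  A degree class with fewer than
    ``min_candidates`` members is expanded with the nearest degree classes
    by |log1p(d) - log1p(d')| until it is large enough.
    """

    def __init__(self, ppi: PPINetwork, universe: set[str],
                 min_candidates: int = 5):
        self.degree_of = {g: ppi.degree(g) for g in universe}
        absent = [g for g in universe if g not in ppi.adj]
        if absent:
            log.warning("%d pathway genes absent from the PPI; treated as degree 0",
                        len(absent))
        by_degree: dict[int, list[str]] = {}
        for g, d in self.degree_of.items():
            by_degree.setdefault(d, []).append(g)
        for d in by_degree:
            by_degree[d].sort()
        self.pools: dict[int, list[str]] = {}
        degrees = sorted(by_degree)
        for d in degrees:
            pool = list(by_degree[d])
            if len(pool) < min_candidates:
                others = sorted(
                    (dd for dd in degrees if dd != d),
                    key=lambda dd: abs(np.log1p(dd) - np.log1p(d)),
                )
                for dd in others:
                    pool.extend(by_degree[dd])
                    if len(pool) >= min_candidates:
                        break
            self.pools[d] = pool

    def shuffle_pathway(self, genes: set[str], rng: np.random.Generator) -> set[str]:
        """Replace each gene by a random same-degree-class gene, without
        replacement within the shuffled pathway."""
        by_degree: dict[int, int] = {}
        for g in genes:
            d = self.degree_of[g]
            by_degree[d] = by_degree.get(d, 0) + 1
        chosen: set[str] = set()
        for d in sorted(by_degree):
            k = by_degree[d]
            candidates = [g for g in self.pools[d] if g not in chosen]
            if len(candidates) < k:
                log.warning("degree class %d exhausted; completing from universe", d)
                candidates.extend(g for g in sorted(self.degree_of)
                                  if g not in chosen and g not in candidates)
            picks = rng.choice(len(candidates), size=k, replace=False)
            chosen.update(candidates[i] for i in picks)
        return chosen

    def degree_histogram(self, genes: set[str]) -> dict[int, int]:
        hist: dict[int, int] = {}
        for g in genes:
            d = self.degree_of[g]
            hist[d] = hist.get(d, 0) + 1
        return hist


def crosstalk_significance(
    pathways: dict[str, set[str]],
    ppi: PPINetwork,
    n_random: int = 1000,
    seed: int = 0,
    min_confidence: int = 0,
    min_candidates: int = 5,
) -> list[CrosstalkResult]:
    """Permutation test of inter-pathway PPI connectivity for every
    unordered pathway pair.

    Each replicate shuffles every pathway once with degree-matched
    replacement genes and recounts all pairs, so null counts share
    replicates across pairs.  ``p = (1 + #{null >= observed}) / (1 + n_random)``.
    """
    if len(pathways) < 2:
        raise ValueError("need >= 2 pathways")
    ids = sorted(pathways)
    universe = set().union(*pathways.values()) | set(ppi.adj)
    matcher = DegreeMatcher(ppi, universe, min_candidates=min_candidates)

    # boolean adjacency over an integer index for fast pair recounting
    index = {g: i for i, g in enumerate(sorted(universe))}
    n = len(index)
    adj = np.zeros((n, n), dtype=bool)
    for a, b, c in ppi.edges.itertuples(index=False):
        if c >= min_confidence and a in index and b in index:
            adj[index[a], index[b]] = True
            adj[index[b], index[a]] = True

    def pair_count(a_genes: set[str], b_genes: set[str]) -> int:
        shared = a_genes & b_genes
        ai = np.fromiter((index[g] for g in a_genes - shared), dtype=int)
        bi = np.fromiter((index[g] for g in b_genes - shared), dtype=int)
        if len(ai) == 0 or len(bi) == 0:
            return 0
        return int(adj[np.ix_(ai, bi)].sum())

    pairs = list(combinations(ids, 2))
    observed = {p: pair_count(pathways[p[0]], pathways[p[1]]) for p in pairs}

    rng = np.random.default_rng(seed)
    exceed = {p: 0 for p in pairs}
    null_sum = {p: 0.0 for p in pairs}
    null_sq = {p: 0.0 for p in pairs}
    for _ in range(n_random):
        shuffled = {pid: matcher.shuffle_pathway(pathways[pid], rng) for pid in ids}
        for p in pairs:
            c = pair_count(shuffled[p[0]], shuffled[p[1]])
            if c >= observed[p]:
                exceed[p] += 1
            null_sum[p] += c
            null_sq[p] += c * c

    results = []
    for p in pairs:
        mean = null_sum[p] / n_random
        var = max(null_sq[p] / n_random - mean * mean, 0.0)
        results.append(CrosstalkResult(
            pathway_a=p[0],
            pathway_b=p[1],
            observed_count=observed[p],
            null_mean=mean,
            null_sd=float(np.sqrt(var)),
            p_empirical=(1 + exceed[p]) / (1 + n_random),
        ))
    return results


def filter_up_up_pairs(
    results: list[CrosstalkResult],
    pathways: dict[str, set[str]],
    deg_directions: dict[str, str],
) -> list[CrosstalkResult]:
    """Set ``passes_up_up`` on each result: true iff both pathways of the
    pair contain at least one upregulated gene."""
    up = {g for g, d in deg_directions.items() if d == "up"}
    for res in results:
        res.passes_up_up = bool(pathways[res.pathway_a] & up) and \
            bool(pathways[res.pathway_b] & up)
    return results


def extract_neighborhood(
    genes: set[str],
    ppi: PPINetwork,
    min_confidence: int = 500,
) -> set[str]:
    """Input genes plus every first neighbor linked by an edge with
    confidence >= ``min_confidence`` (boundary inclusive)."""
    out = set(genes)
    for g in genes:
        for h, c in ppi.adj.get(g, {}).items():
            if c >= min_confidence:
                out.add(h)
    return out


def enrich(
    gene_set: set[str],
    term_to_genes: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with BH adjustment.

    Terms with no gene in the universe are skipped.  Returns a DataFrame
    with p, BH-adjusted q and a ``significant`` flag (q < alpha).
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    M, N = len(universe), len(gene_set)
    rows = []
    for term, genes in sorted(term_to_genes.items()):
        in_universe = genes & universe
        if not in_universe:
            continue
        k = len(in_universe & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, len(in_universe), N))
        rows.append({"term": term, "n_term": len(in_universe), "overlap": k, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "n_term", "overlap", "p", "q", "significant"])
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] < alpha
    return df.sort_values("p").reset_index(drop=True)


def enrich_partitioned(
    neighborhood: set[str],
    deg_directions: dict[str, str],
    term_to_genes: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Enrichment run separately on the up- and down-regulated partitions of
    a neighborhood: an operational stand-in for "benefited" (up) and
    "compromised" (down) system chains."""
    up = {g for g in neighborhood if deg_directions.get(g) == "up"}
    down = {g for g in neighborhood if deg_directions.get(g) == "down"}
    return {
        "benefited": enrich(up & universe, term_to_genes, universe, alpha),
        "compromised": enrich(down & universe, term_to_genes, universe, alpha),
    }


def results_to_frame(results: list[CrosstalkResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pathway_a": r.pathway_a,
        "pathway_b": r.pathway_b,
        "observed": r.observed_count,
        "null_mean": r.null_mean,
        "null_sd": r.null_sd,
        "p_empirical": r.p_empirical,
        "passes_up_up": r.passes_up_up,
    } for r in results])
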