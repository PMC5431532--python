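"""Pathway filtering, crosstalk counting/permutation test, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import exhaustive_crosstalk_p, quadratic_crosstalk_count
from fibrosysmap.crosstalk import (
    DegreeMatcher,
    PPINetwork,
    crosstalk_count,
    crosstalk_significance,
    enrich,
    extract_neighborhood,
    filter_pathways,
    filter_up_up_pairs,
)
from fibrosysmap.synthetic import SyntheticConfig, generate_ppi_and_pathways


def ppi_from(edges):
    return PPINetwork(pd.DataFrame(edges, columns=["node_a", "node_b", "confidence"]))


class TestFilterPathways:
    def test_size_boundary(self):
        pathways = {"small": set("abcde"), "exact": set("abcdef"),
                    "big": set("abcdefgh")}
        out = filter_pathways(pathways, min_genes=6)
        assert set(out) == {"exact", "big"}

    def test_restriction_applies_before_size_check(self):
        pathways = {"p": set("abcdefgh")}
        out = filter_pathways(pathways, min_genes=6, restrict_to=set("abcde"))
        assert out == {}


class TestCrosstalkCount:
    def test_within_pathway_edges_ignored(self):
        ppi = ppi_from([("a", "c", 900), ("b", "d", 900), ("a", "b", 900)])
        assert crosstalk_count({"a", "b"}, {"c", "d"}, ppi) == 2

    def test_no_cross_edges(self):
        ppi = ppi_from([("a", "b", 900)])
        assert crosstalk_count({"a", "b"}, {"c", "d"}, ppi) == 0

    def test_shared_genes_excluded(self):
        ppi = ppi_from([("a", "s", 900), ("s", "b", 900), ("a", "b", 900)])
        # s in both pathways: its edges leave the between-count
        assert crosstalk_count({"a", "s"}, {"b", "s"}, ppi) == 1

    def test_symmetry(self):
        ppi = ppi_from([("a", "c", 900), ("b", "c", 500)])
        a, b = {"a", "b"}, {"c", "d"}
        assert crosstalk_count(a, b, ppi) == crosstalk_count(b, a, ppi)

    def test_confidence_threshold_monotone(self):
        ppi = ppi_from([("a", "c", 400), ("b", "d", 900)])
        a, b = {"a", "b"}, {"c", "d"}
        counts = [crosstalk_count(a, b, ppi, min_confidence=m)
                  for m in (0, 500, 950)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        rows = []
        seen = set()
        for _ in range(120):
            a, b = rng.choice(genes, 2, replace=False)
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            rows.append((a, b, int(rng.integers(0, 1001))))
        edges = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
        ppi = PPINetwork(edges)
        pa = set(rng.choice(genes, 8, replace=False))
        pb = set(rng.choice(genes, 8, replace=False))
        for min_conf in (0, 500):
            assert crosstalk_count(pa, pb, ppi, min_confidence=min_conf) == \
                quadratic_crosstalk_count(pa, pb, edges, min_confidence=min_conf)


class TestDegreeMatcher:
    def test_shuffle_preserves_degree_histogram(self):
        cfg = SyntheticConfig(seed=3, n_genes=400, n_pathways=6,
                              planted_crosstalk_pairs=0)
        ppi_df, pathways, _ = generate_ppi_and_pathways(cfg)
        ppi = PPINetwork(ppi_df)
        universe = set(ppi.adj) | set().union(*pathways.values())
        matcher = DegreeMatcher(ppi, universe, min_candidates=1)
        rng = np.random.default_rng(0)
        for genes in pathways.values():
            for _ in range(20):
                shuffled = matcher.shuffle_pathway(genes, rng)
                assert len(shuffled) == len(genes)
                assert matcher.degree_histogram(shuffled) == \
                    matcher.degree_histogram(genes)

    def test_small_class_expanded_by_log_distance(self):
        ppi = ppi_from([("a", "b", 900), ("a", "c", 900), ("a", "d", 900)])
        matcher = DegreeMatcher(ppi, {"a", "b", "c", "d"}, min_candidates=3)
        # degree-3 class has only "a"; nearest classes fill the pool
        assert len(matcher.pools[3]) >= 3


class TestSignificance:
    def test_planted_excess_is_significant(self, small_config):
        ppi_df, pathways, planted = generate_ppi_and_pathways(small_config)
        ppi = PPINetwork(ppi_df)
        filtered = filter_pathways(pathways, min_genes=6)
        results = crosstalk_significance(filtered, ppi, n_random=500, seed=0)
        for pa, pb in planted:
            res = next(r for r in results
                       if {r.pathway_a, r.pathway_b} == {pa, pb})
            assert res.p_empirical <= 0.05
            assert res.observed_count > res.null_mean

    def test_p_bounds(self, small_config):
        ppi_df, pathways, _ = generate_ppi_and_pathways(small_config)
        results = crosstalk_significance(
            filter_pathways(pathways, min_genes=6), PPINetwork(ppi_df),
            n_random=50, seed=1)
        for r in results:
            assert 1 / 51 <= r.p_empirical <= 1.0

    def test_matches_exhaustive_null_on_tiny_universe(self):
        """<=8 genes, <=3 genes per pathway: the sampled p agrees with the
        exhaustively enumerated degree-matched-assignment p."""
        genes = list("abcdefgh")
        edges = pd.DataFrame([
            ("a", "e", 900), ("a", "f", 900), ("b", "e", 900),
            ("c", "g", 900), ("d", "h", 900), ("b", "f", 900),
        ], columns=["node_a", "node_b", "confidence"])
        ppi = PPINetwork(edges)
        pathways = {"A": {"a", "b"}, "B": {"e", "f", "g"}}
        n_random = 1000
        results = crosstalk_significance(pathways, ppi, n_random=n_random,
                                         seed=5, min_candidates=1)
        res = results[0]
        matcher = DegreeMatcher(ppi, set(genes), min_candidates=1)
        q = exhaustive_crosstalk_p(
            pathways, matcher,
            lambda x, y: (ppi.confidence(x, y) or 0) > 0,
            res.observed_count, ("A", "B"))
        lo = (1 + stats.binom.ppf(0.005, n_random, q)) / (n_random + 1)
        hi = (1 + stats.binom.ppf(0.995, n_random, q)) / (n_random + 1)
        assert lo <= res.p_empirical <= hi


class TestUpUpFilter:
    def _results(self, pathways):
        ppi = ppi_from([("a", "x", 900)])
        return crosstalk_significance(pathways, ppi, n_random=20, seed=0), ppi

    def test_flag_rules(self):
        pathways = {"A": {"a", "b"}, "B": {"x", "y"}, "C": {"p", "q"}}
        results, _ = self._results(pathways)
        directions = {"a": "up", "x": "up", "p": "down", "q": "down", "b": "down"}
        filter_up_up_pairs(results, pathways, directions)
        flags = {(r.pathway_a, r.pathway_b): r.passes_up_up for r in results}
        assert flags[("A", "B")] is True       # up in both
        assert flags[("A", "C")] is False      # up in A only
        assert flags[("B", "C")] is False      # down-only partner


class TestNeighborhood:
    def test_confidence_boundary(self):
        ppi = ppi_from([("g", "n499", 499), ("g", "n500", 500)])
        out = extract_neighborhood({"g"}, ppi, min_confidence=500)
        assert out == {"g", "n500"}

    def test_matches_adjacency_scan(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(25)]
        rows = []
        seen = set()
        for _ in range(80):
            a, b = rng.choice(genes, 2, replace=False)
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                rows.append((a, b, int(rng.integers(0, 1001))))
        edges = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
        ppi = PPINetwork(edges)
        seeds = set(rng.choice(genes, 5, replace=False))
        got = extract_neighborhood(seeds, ppi, min_confidence=500)
        expect = set(seeds)
        for a, b, c in ppi.edges.itertuples(index=False):
            if c >= 500:
                if a in seeds:
                    expect.add(b)
                if b in seeds:
                    expect.add(a)
        assert got == expect

    def test_raising_confidence_never_grows(self):
        ppi = ppi_from([("g", "a", 300), ("g", "b", 600), ("g", "c", 900)])
        n1 = extract_neighborhood({"g"}, ppi, min_confidence=200)
        n2 = extract_neighborhood({"g"}, ppi, min_confidence=700)
        assert n2 <= n1


class TestEnrich:
    def test_closed_form_extreme(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        out = enrich(term, {"T": term}, universe)
        # drawing all 5 term genes in a 5-gene sample: p = 1/C(20,5)
        assert out["p"].iat[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_expected_overlap_not_significant(self):
        universe = {f"g{i}" for i in range(1000)}
        term = {f"g{i}" for i in range(100)}
        sample = {f"g{i}" for i in range(90, 190)}  # overlap 10 = expectation
        out = enrich(sample, {"T": term}, universe)
        assert out["p"].iat[0] > 0.4
        assert not out["significant"].iat[0]

    def test_bh_retains_small_ps(self):
        universe = {f"g{i}" for i in range(30)}
        terms = {
            "t1": {f"g{i}" for i in range(8)},
            "t2": {f"g{i}" for i in range(4, 12)},
            "t3": {f"g{i}" for i in range(20, 28)},
        }
        sample = {f"g{i}" for i in range(8)}
        out = enrich(sample, terms, universe).set_index("term")
        assert out.loc["t1", "significant"]
        assert not out.loc["t3", "significant"]

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"x"}, {"T": {"a"}}, {"a", "b"})
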