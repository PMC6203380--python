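"""Network enrichment: partner selection vs a neighbor-counting oracle,
hypergeometric p vs exhaustive enumeration, term filtering boundaries, DAG
condensation vs a transitive-closure oracle, systems-map edge counting."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crosstum import (
    AnnotationDAG,
    GeneSetCollection,
    InteractionNetwork,
    SimConfig,
    build_systems_map,
    condense_dag,
    filter_enriched_terms,
    gen_gene_sets_and_dag,
    gen_ppi_network,
    hypergeom_enrich,
    select_binding_partners,
)


class TestBindingPartners:
    def test_star_graph(self):
        net = InteractionNetwork.from_pairs(
            [("center", h) for h in ("h1", "h2", "h3")]
            + [("h1", "leaf1"), ("h2", "leaf2")]
        )
        universe = ["center", "h1", "h2", "h3", "leaf1", "leaf2"]
        partners = select_binding_partners(["h1", "h2", "h3"], net, universe)
        assert partners == ["center"]

    def test_min_degree_one_gives_all_neighbors(self):
        net = InteractionNetwork.from_pairs([("h1", "a"), ("h2", "b")])
        partners = select_binding_partners(
            ["h1", "h2"], net, ["h1", "h2", "a", "b"], min_hit_degree=1
        )
        assert partners == ["a", "b"]

    def test_hits_never_partners(self):
        net = InteractionNetwork.from_pairs([("h1", "h2"), ("h1", "h3"), ("h2", "h3")])
        assert select_binding_partners(["h1", "h2", "h3"], net, ["h1", "h2", "h3"]) == []

    def test_random_graph_counting_oracle(self, rng):
        nodes = [f"g{i}" for i in range(120)]
        pairs = set()
        while len(pairs) < 400:
            a, b = rng.choice(120, 2, replace=False)
            pairs.add((nodes[min(a, b)], nodes[max(a, b)]))
        net = InteractionNetwork.from_pairs(pairs)
        hits = list(rng.choice(nodes, 30, replace=False))
        partners = select_binding_partners(hits, net, nodes)
        g = net.to_graph()
        hit_set = set(hits)
        brute = sorted(
            n
            for n in g.nodes
            if n not in hit_set and sum(nb in hit_set for nb in g.neighbors(n)) >= 2
        )
        assert partners == brute


def hypergeom_tail_enumeration(M, n_term, N, k):
    """P(overlap >= k) by counting all C(M, N) query draws."""
    total = math.comb(M, N)
    favorable = sum(
        math.comb(n_term, j) * math.comb(M - n_term, N - j)
        for j in range(k, min(n_term, N) + 1)
    )
    return favorable / total


class TestHypergeom:
    def _enrich_one(self, universe, term, query):
        sets = GeneSetCollection(sets={"t": ("t", set(term))})
        return hypergeom_enrich(set(query), sets, set(universe)).iloc[0]

    def test_term_equals_universe_p_one(self):
        u = [f"g{i}" for i in range(10)]
        row = self._enrich_one(u, u, u[:5])
        assert row["p"] == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        u = [f"g{i}" for i in range(10)]
        row = self._enrich_one(u, u[:4], u[4:9])
        assert row["p"] == pytest.approx(1.0)

    def test_worked_enumeration(self):
        u = [f"g{i}" for i in range(10)]
        term, query = u[:4], u[1:6]  # overlap 3
        row = self._enrich_one(u, term, query)
        assert row["n_candidates_in_term"] == 3
        assert row["p"] == pytest.approx(hypergeom_tail_enumeration(10, 4, 5, 3))
        assert row["expected"] == pytest.approx(5 * 4 / 10)

    def test_exhaustive_enumeration_all_small_universes(self, rng):
        for _ in range(60):
            M = int(rng.integers(4, 13))
            u = [f"g{i}" for i in range(M)]
            n_term = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            term = list(rng.choice(u, n_term, replace=False))
            query = set(rng.choice(u, N, replace=False))
            row = self._enrich_one(u, term, query)
            k = len(set(term) & query)
            assert row["p"] == pytest.approx(
                hypergeom_tail_enumeration(M, n_term, N, k), abs=1e-12
            )

    def test_p_monotone_in_overlap(self):
        from scipy.stats import hypergeom

        ps = [hypergeom.sf(k - 1, 50, 10, 15) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_null_fraction_near_alpha(self, rng):
        # uniformly drawn query: ~5% of terms significant at 0.05 on average
        u = [f"g{i}" for i in range(300)]
        hits = []
        for rep in range(40):
            sets = GeneSetCollection(
                sets={
                    f"t{j}": (
                        "",
                        set(rng.choice(u, 30, replace=False)),
                    )
                    for j in range(25)
                }
            )
            query = set(rng.choice(u, 40, replace=False))
            res = hypergeom_enrich(query, sets, set(u))
            hits.append((res["p"] <= 0.05).mean())
        assert np.mean(hits) == pytest.approx(0.05, abs=0.025)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(set(), GeneSetCollection(sets={"t": ("", {"g"})}), set())


class TestFilterTerms:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["term", "p", "n_term", "n_candidates_in_term"])

    def test_boundaries_inclusive(self):
        res = self._results(
            [["a", 0.05, 500, 3], ["b", 0.051, 10, 3], ["c", 0.04, 501, 9]]
        )
        kept = filter_enriched_terms(res)
        assert list(kept["term"]) == ["a"]

    def test_predicate_oracle(self, rng):
        res = self._results(
            [
                [f"t{i}", float(rng.random()), int(rng.integers(1, 700)), int(rng.integers(0, 8))]
                for i in range(200)
            ]
        )
        kept = filter_enriched_terms(res, alpha=0.05, max_term_size=500)
        brute = res[(res.p <= 0.05) & (res.n_term <= 500)]
        assert list(kept["term"]) == list(brute["term"])

    def test_min_candidates_flag(self):
        res = self._results([["a", 0.01, 10, 2], ["b", 0.01, 10, 3]])
        kept = filter_enriched_terms(res, min_candidates=2)
        assert list(kept["term"]) == ["b"]


def _dag_from_edges(edges, annot=None):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return AnnotationDAG(graph=g, annot=annot or {n: set() for n in g.nodes})


class TestCondenseDag:
    def test_all_significant_is_identity(self):
        dag = _dag_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        out = condense_dag(dag, {"A", "B", "C"})
        assert set(out.edges) == {("A", "B"), ("B", "C"), ("A", "C")}

    def test_chain_reconnects_to_grandparent(self):
        dag = _dag_from_edges([("A", "B"), ("B", "C")])
        out = condense_dag(dag, {"A", "C"})
        assert set(out.nodes) == {"A", "C"}
        assert set(out.edges) == {("A", "C")}

    def test_cycle_raises(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError):
            AnnotationDAG(graph=g, annot={"A": set(), "B": set()})

    def test_idempotent(self, rng):
        dag = _random_dag(rng, 20)
        sig = set(rng.choice(list(dag.graph.nodes), 8, replace=False))
        once = condense_dag(dag, sig)
        again = condense_dag(
            AnnotationDAG(graph=once, annot={n: set() for n in once.nodes}), sig
        )
        assert set(once.edges) == set(again.edges)
        assert set(once.nodes) == set(again.nodes)

    def test_reachability_matches_transitive_closure(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 31))
            dag = _random_dag(rng, n)
            nodes = list(dag.graph.nodes)
            k = int(rng.integers(1, n + 1))
            sig = set(rng.choice(nodes, k, replace=False))
            out = condense_dag(dag, sig)
            assert set(out.nodes) == sig
            closure = nx.transitive_closure_dag(dag.graph)
            for u in sig:
                for v in sig:
                    if u == v:
                        continue
                    expect = closure.has_edge(u, v)
                    got = nx.has_path(out, u, v) if u in out and v in out else False
                    assert got == expect, (u, v)


def _random_dag(rng, n):
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.15:
                g.add_edge(i, j)  # edges point to higher index: acyclic
    return AnnotationDAG(graph=g, annot={x: set() for x in g.nodes})


class TestSystemsMap:
    def test_no_terms_all_unassigned(self):
        net = InteractionNetwork.from_pairs([("h1", "h2")])
        empty = pd.DataFrame(columns=["term", "members"])
        smap = build_systems_map(["h1", "h2"], [], empty, net)
        c = smap.counts()
        assert c["terms"] == 0 and c["ppi"] == 1 and c["unassigned"] == 2

    def test_edge_counts_match_brute_force(self, rng):
        genes = [f"g{i}" for i in range(40)]
        hits, partners = genes[:15], genes[15:25]
        pairs = set()
        while len(pairs) < 100:
            a, b = rng.choice(40, 2, replace=False)
            pairs.add((genes[min(a, b)], genes[max(a, b)]))
        net = InteractionNetwork.from_pairs(pairs)
        members = {
            f"t{j}": sorted(rng.choice(genes, 12, replace=False)) for j in range(5)
        }
        enriched = pd.DataFrame(
            [{"term": t, "members": m} for t, m in members.items()]
        )
        smap = build_systems_map(hits, partners, enriched, net)
        in_map = set(hits) | set(partners)
        expect_g2t = sum(
            1 for t, m in members.items() for g in m if g in in_map
        )
        expect_ppi = sum(1 for a, b in net.edge_list() if a in in_map and b in in_map)
        c = smap.counts()
        assert c["gene_to_term"] == expect_g2t
        assert c["ppi"] == expect_ppi
        # every ppi edge joins two gene nodes
        for a, b, d in smap.graph.edges(data=True):
            if d["type"] == "ppi":
                assert smap.graph.nodes[a]["type"] in ("hit", "partner")
                assert smap.graph.nodes[b]["type"] in ("hit", "partner")


class TestGenerators:
    def test_ppi_simple_graph_invariants(self, small_cfg):
        net = gen_ppi_network(small_cfg)
        assert len(net.edges) == small_cfg.ppi_edges
        universe = set(f"HS{i:04d}" for i in range(1, small_cfg.n_genes + 1))
        for e in net.edges:
            a, b = tuple(e)
            assert a != b and a in universe and b in universe

    def test_ppi_zero_edges(self):
        cfg = SimConfig(seed=0, ppi_edges=0, n_genes=50)
        assert gen_ppi_network(cfg).edges == set()

    def test_ppi_right_skewed_degrees(self):
        maxdeg, meandeg = [], []
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_genes=300, ppi_edges=900)
            g = gen_ppi_network(cfg).to_graph()
            degs = [d for _, d in g.degree]
            maxdeg.append(max(degs))
            meandeg.append(np.mean(degs))
        assert np.mean(maxdeg) > 3 * np.mean(meandeg)

    def test_dag_upward_closure_and_root(self, small_cfg):
        _, dag = gen_gene_sets_and_dag(small_cfg)
        for child, parent in dag.graph.edges:
            assert dag.annot[child] <= dag.annot[parent]
        roots = [n for n in dag.graph.nodes if dag.graph.out_degree(n) == 0]
        assert len(roots) == 1
        all_genes = set().union(*dag.annot.values())
        assert dag.annot[roots[0]] == all_genes

    def test_dag_node_count_and_determinism(self):
        cfg = SimConfig(seed=13, n_genes=100, dag_depth=4, dag_branching=3)
        _, a = gen_gene_sets_and_dag(cfg)
        _, b = gen_gene_sets_and_dag(cfg)
        expected_nodes = sum(3**d for d in range(5))  # full tree, no extra nodes
        assert a.graph.number_of_nodes() == expected_nodes
        assert set(a.graph.edges) == set(b.graph.edges)
        assert a.annot == b.annot

    def test_size_filter_exercised(self):
        cfg = SimConfig(seed=1, n_genes=600)
        _, dag = gen_gene_sets_and_dag(cfg)
        assert max(dag.term_sizes().values()) > 500
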