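"""Binding-partner expansion, gene-set enrichment, DAG condensation, and
systems-map assembly.

Hits are expanded with first-degree protein-interaction partners that touch
at least two distinct hits; gene-set over-representation is a one-sided
hypergeometric (Fisher exact) test against an explicit universe; the
annotation DAG is condensed to significant terms by iteratively deleting
non-significant parents and rewiring their children to the grandparents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "GeneSetCollection",
    "AnnotationDAG",
    "SystemsMap",
    "select_binding_partners",
    "hypergeom_enrich",
    "filter_enriched_terms",
    "condense_dag",
    "build_systems_map",
]


@dataclass
class InteractionNetwork:
    """Undirected simple PPI graph: no self-loops, no duplicate edges."""

    edges: set[frozenset]

    @classmethod
    def from_pairs(cls, pairs) -> "InteractionNetwork":
        edges = set()
        for a, b in pairs:
            if a == b:
                continue
            edges.add(frozenset((a, b)))
        return cls(edges=edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.edges)


@dataclass
class GeneSetCollection:
    """Named gene sets: term id -> (description, member set)."""

    sets: dict[str, tuple[str, set]]

    def __post_init__(self) -> None:
        empty = [t for t, (_, members) in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def members(self, term: str) -> set:
        return self.sets[term][1]


@dataclass
class AnnotationDAG:
    """Rooted term hierarchy (edges child -> parent) with upward-closed
    gene annotation: a gene annotated to a child is annotated to every
    ancestor, so the root annotates all annotated genes."""

    graph: nx.DiGraph  # edge u -> v means v is a parent of u
    annot: dict[str, set]

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("annotation hierarchy contains a cycle")

    def term_sizes(self) -> dict[str, int]:
        return {t: len(g) for t, g in self.annot.items()}

    def as_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            sets={t: (t, set(g)) for t, g in self.annot.items() if g}
        )


def select_binding_partners(
    hits: list[str],
    net: InteractionNetwork,
    universe: list[str],
    min_hit_degree: int = 2,
) -> list[str]:
    """Non-hit universe genes adjacent to >= ``min_hit_degree`` distinct hits.

    Hits are never returned as their own partners. Default requires
    interaction with at least two hits.
    """
    hit_set = set(hits)
    if not hit_set <= set(universe):
        raise ValueError("hits must be contained in the universe")
    counts: dict[str, int] = {}
    for e in net.edges:
        a, b = tuple(e)
        if a in hit_set and b not in hit_set:
            counts[b] = counts.get(b, 0) + 1
        elif b in hit_set and a not in hit_set:
            counts[a] = counts.get(a, 0) + 1
    uni = set(universe)
    return sorted(
        g for g, c in counts.items() if c >= min_hit_degree and g in uni
    )


def hypergeom_enrich(
    query: set,
    sets: GeneSetCollection,
    universe: set,
) -> pd.DataFrame:
    """Over-representation of each gene set in the query.

    For a term of size ``n_term`` (after intersection with the universe),
    the p-value is P(X >= k) with X ~ Hypergeometric(|universe|, n_term,
    |query|) and k the observed overlap — the one-sided Fisher exact test on
    the 2x2 table. Benjamini-Hochberg FDR is reported alongside the nominal
    p; the expected overlap is |query| * n_term / |universe|.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for term, (desc, members) in sets.sets.items():
        members_u = members & universe
        n_term = len(members_u)
        if n_term == 0:
            continue
        overlap = sorted(members_u & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, n_term, N))
        rows.append(
            {
                "term": term,
                "description": desc,
                "n_candidates_in_term": k,
                "n_term": n_term,
                "expected": N * n_term / M,
                "p": min(p, 1.0),
                "members": overlap,
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["fdr"] = stats.false_discovery_control(res["p"], method="bh")
        res = res.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return res


def filter_enriched_terms(
    results: pd.DataFrame,
    alpha: float = 0.05,
    max_term_size: int = 500,
    min_candidates: int | None = None,
) -> pd.DataFrame:
    """Keep terms with nominal p <= alpha and term size <= max_term_size
    (both inclusive: terms with *more than* ``max_term_size`` genes are
    discarded as too generic). ``min_candidates`` optionally additionally
    requires more than that many candidate genes in the term."""
    if len(results) == 0:
        return results
    keep = (results["p"] <= alpha) & (results["n_term"] <= max_term_size)
    if min_candidates is not None:
        keep &= results["n_candidates_in_term"] > min_candidates
    return results.loc[keep].reset_index(drop=True)


def condense_dag(dag: AnnotationDAG, significant: set) -> nx.DiGraph:
    """Condense the term hierarchy to the significant terms.

    Non-significant terms are removed iteratively in reverse topological
    order (roots first); when a term is removed, each of its children gains
    an edge to each of its parents, so significant-to-significant ancestry
    (reachability) is exactly preserved. The output is a simple graph over
    the significant terms only (multi-edges from diamond ancestry are
    deduplicated, self-loops impossible in a DAG).
    """
    g = dag.graph
    if not significant <= set(g.nodes):
        raise ValueError("significant terms must be nodes of the hierarchy")
    out = nx.DiGraph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(g.edges)
    # edges point child -> parent, so parents precede children in the
    # *reverse* topological order of the edge direction; process roots first
    order = list(nx.topological_sort(out))  # children before parents
    for node in reversed(order):  # parents (roots) first
        if node in significant:
            continue
        parents = list(out.successors(node))
        children = list(out.predecessors(node))
        out.remove_node(node)
        out.add_edges_from(
            (c, p) for c in children for p in parents if c != p
        )
    return out


@dataclass
class SystemsMap:
    """Typed graph of hits, binding partners and enriched terms.

    Gene-to-term edges join a gene node to a term annotating it; PPI edges
    join two gene nodes. Hits without any term membership are flagged
    unassigned (candidate novel genes).
    """

    graph: nx.Graph
    unassigned_hits: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        types = nx.get_node_attributes(self.graph, "type")
        etypes = nx.get_edge_attributes(self.graph, "type")
        return {
            "hits": sum(1 for t in types.values() if t == "hit"),
            "partners": sum(1 for t in types.values() if t == "partner"),
            "terms": sum(1 for t in types.values() if t == "term"),
            "gene_to_term": sum(1 for t in etypes.values() if t == "gene_to_term"),
            "ppi": sum(1 for t in etypes.values() if t == "ppi"),
            "unassigned": len(self.unassigned_hits),
        }


def build_systems_map(
    hits: list[str],
    partners: list[str],
    enriched: pd.DataFrame,
    net: InteractionNetwork,
) -> SystemsMap:
    """Assemble the systems map from hits, partners and (already filtered)
    enriched terms."""
    g = nx.Graph()
    gene_nodes = list(dict.fromkeys(list(hits) + list(partners)))
    hit_set = set(hits)
    for gene in gene_nodes:
        g.add_node(gene, type="hit" if gene in hit_set else "partner")
    assigned = set()
    for row in enriched.itertuples(index=False):
        g.add_node(row.term, type="term")
        for gene in row.members:
            if gene in g.nodes and g.nodes[gene]["type"] in ("hit", "partner"):
                g.add_edge(gene, row.term, type="gene_to_term")
                assigned.add(gene)
    genes = set(gene_nodes)
    for a, b in net.edge_list():
        if a in genes and b in genes:
            g.add_edge(a, b, type="ppi")
    unassigned = sorted(h for h in hits if h not in assigned)
    if unassigned:
        logger.info("%d hits could not be assigned to any term", len(unassigned))
    return SystemsMap(graph=g, unassigned_hits=unassigned)
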