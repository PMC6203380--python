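"""Binding-partner expansion, gene-set enrichment and DAG condensation.

Partners must touch at least two distinct hits; enrichment is a one-sided
hypergeometric test against the screened-gene universe; the annotation DAG
is condensed so only significant terms remain, children rewired to
grandparents.
"""

from crosstum import (
    SimConfig,
    build_systems_map,
    condense_dag,
    filter_enriched_terms,
    gen_gene_sets_and_dag,
    gen_ppi_network,
    hypergeom_enrich,
    select_binding_partners,
)

cfg = SimConfig(seed=5, n_genes=400, ppi_edges=1200)
universe = [f"HS{i:04d}" for i in range(1, 401)]
hits = universe[:60]

net = gen_ppi_network(cfg)
partners = select_binding_partners(hits, net, universe, min_hit_degree=2)
print(f"{len(partners)} binding partners interact with >=2 of the {len(hits)} hits")

sets, dag = gen_gene_sets_and_dag(cfg, planted_genes=hits[:30])
res = hypergeom_enrich(set(hits) | set(partners), sets, set(universe))
enriched = filter_enriched_terms(res, alpha=0.05, max_term_size=500)
print(f"{len(enriched)}/{len(res)} terms enriched at p <= 0.05 (terms > 500 genes discarded)")

condensed = condense_dag(dag, set(enriched["term"]))
print(f"condensed annotation graph: {condensed.number_of_nodes()} significant terms, "
      f"{condensed.number_of_edges()} ancestry edges")

smap = build_systems_map(hits, partners, enriched, net)
c = smap.counts()
print(f"systems map: {c['gene_to_term']} gene-to-term associations, "
      f"{c['ppi']} protein interactions, {c['unassigned']} unassigned hits")
# Unassigned hits — present in no enriched term — are the candidate novel
# genes the map is designed to surface.
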