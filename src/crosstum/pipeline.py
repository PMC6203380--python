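"""End-to-end orchestration on synthetic data.

Runs the full chain — primary screen hit calling, ortholog expansion,
direction scoring and TSOS with its resampling null, top-candidate ranking,
secondary-screen validation, binding-partner/gene-set enrichment with DAG
condensation and systems-map assembly, and survival stratification — from a
single config, writing every stage's tables plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from ._rng import substream
from .config import PipelineConfig
from .enrichment import (
    build_systems_map,
    condense_dag,
    filter_enriched_terms,
    hypergeom_enrich,
    select_binding_partners,
)
from .orthologs import OrthologTable, expand_orthologs, restrict_to_platform
from .screen import call_primary_hits, filter_rnai_quality, validate_secondary
from .simulate import (
    gen_expression_panel,
    gen_gene_sets_and_dag,
    gen_ortholog_table,
    gen_patient_cohort,
    gen_ppi_network,
    gen_screen_table,
)
from .survival import filter_cohort, stratify_and_test
from .tsos import (
    compute_direction_matrix,
    empirical_pvalue,
    rank_top_candidates,
    sample_null_tsos,
    tsos_score,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "report"]


def _simulate_secondary_scores(
    genes: list[str], truly_planted: set, seed: int
) -> pd.DataFrame:
    """Secondary-screen phenotype scores (0-3) for retested genes: two RNAi
    lines per gene; true modifiers enhance the rough-eye phenotype."""
    rng = substream(seed, "secondary")
    rows = []
    for g in genes:
        for _ in range(2):
            mu = 1.6 if g in truly_planted else 0.35
            rows.append({"fly_gene": g, "score": float(np.clip(rng.normal(mu, 0.45), 0, 3))})
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage in order; returns the run directory.

    The synthetic study is wired coherently: the fly genes carrying planted
    screen effects map to the human genes carrying the planted
    tumor-downregulation, which in turn annotate a dedicated term and drive
    the planted survival split — so a correct pipeline recovers the same
    gene set at every stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim
    counts: dict[str, int] = {}

    # --- stage 1: primary screen ------------------------------------------
    screen = gen_screen_table(sim)
    cio.write_screen_table(screen.records, out / "screen_records.tsv")
    kept = filter_rnai_quality(screen.records)
    calls = call_primary_hits(kept, screen.control, z_cutoff=cfg.z_cutoff)
    cio.write_tsv(calls, out / "hit_calls.tsv")
    fly_hits = sorted(calls.loc[calls["is_hit"], "fly_gene"])
    counts.update(
        lines_total=len(screen.records), lines_kept=len(kept), fly_hits=len(fly_hits)
    )

    # --- stage 2: ortholog expansion --------------------------------------
    orth_df = gen_ortholog_table(sim, n_fly=sim.n_lines)
    cio.write_ortholog_table(orth_df, out / "orthologs.tsv")
    table = OrthologTable(table=orth_df)
    human_hits, unmapped = expand_orthologs(fly_hits, table, cfg.include_inparalogs)
    human_universe_all, _ = expand_orthologs(
        table.fly_genes, table, cfg.include_inparalogs
    )
    counts.update(human_hit_orthologs=len(human_hits), fly_hits_unmapped=len(unmapped))

    # --- stage 3: expression panel + TSOS ---------------------------------
    planted_fly = set(screen.records.loc[screen.planted_hits, "fly_gene"])
    planted_human_all, _ = expand_orthologs(
        sorted(planted_fly), table, include_inparalogs=False
    )
    universe_ids = set(f"HS{i:04d}" for i in range(1, sim.n_genes + 1))
    planted_panel = sorted(set(planted_human_all) & universe_ids)
    panel = gen_expression_panel(sim, planted_genes=planted_panel)
    cio.write_expression_panel(panel, out / "panel")
    measurable, dropped = restrict_to_platform(human_hits, panel.probe_to_gene)
    universe_measurable, _ = restrict_to_platform(
        human_universe_all, panel.probe_to_gene
    )
    counts.update(hits_measurable=len(measurable), hits_unprobed=len(dropped))

    dm = compute_direction_matrix(
        panel, alpha=cfg.alpha_probe, log_transform=cfg.rnaseq_mode
    )
    cio.write_tsv(
        dm.scores.assign(n_probes=dm.n_probes), out / "direction_matrix.tsv", index=True
    )
    observed, per_tissue = tsos_score(measurable, dm)
    null = sample_null_tsos(
        universe_measurable,
        set_size=len(measurable),
        n_samplings=cfg.n_samplings,
        dm=dm,
        seed=cfg.seed,
    )
    p_emp = empirical_pvalue(observed, null, tail="lower")
    np.savetxt(out / "null_tsos.tsv", null, header="null_tsos", comments="")
    top = rank_top_candidates(dm, n_top=cfg.n_top)
    cio.write_tsv(top, out / "top_candidates.tsv")
    counts.update(top_candidates=len(top))

    # --- stage 4: secondary validation ------------------------------------
    # retest the fly orthologs of the top-ranked human genes
    seed_to_fly = {}
    for row in orth_df.itertuples(index=False):
        for hs in row.human_seed:
            seed_to_fly[hs] = row.fly_gene
    retest_fly = sorted({seed_to_fly[g] for g in top["gene"] if g in seed_to_fly})
    secondary = _simulate_secondary_scores(retest_fly, planted_fly, sim.seed)
    validation = validate_secondary(secondary, cutoff=cfg.secondary_cutoff)
    cio.write_tsv(validation, out / "secondary_validation.tsv")
    validated_fly = sorted(validation.loc[validation["validated"], "fly_gene"])
    validated_human, _ = expand_orthologs(validated_fly, table, include_inparalogs=False)
    validated_human = sorted(set(validated_human) & set(universe_measurable))
    counts.update(validated_genes=len(validated_fly))

    # --- stage 5: network enrichment + systems map ------------------------
    gene_sets, dag = gen_gene_sets_and_dag(sim, planted_genes=planted_panel)
    cio.write_gmt(gene_sets, out / "gene_sets.gmt")
    cio.write_dag_edges(dag, out / "dag_edges.tsv")
    net = gen_ppi_network(sim)
    cio.write_ppi_edges(net, out / "ppi_edges.tsv")
    universe_set = sorted(set(universe_measurable) | set(validated_human))
    partners = select_binding_partners(
        validated_human, net, universe_set, min_hit_degree=cfg.min_hit_degree
    )
    query = set(validated_human) | set(partners)
    enr = hypergeom_enrich(query & set(universe_set), gene_sets, set(universe_set))
    cio.write_tsv(enr.drop(columns=["members"]), out / "enrichment.tsv")
    enriched = filter_enriched_terms(
        enr, alpha=cfg.alpha_enrich, max_term_size=cfg.max_term_size
    )
    sig_terms = set(enriched["term"]) if len(enriched) else set()
    condensed = condense_dag(dag, sig_terms & set(dag.graph.nodes))
    pd.DataFrame(sorted(condensed.edges), columns=["child", "parent"]).to_csv(
        out / "condensed_dag.tsv", sep="\t", index=False
    )
    smap = build_systems_map(validated_human, partners, enriched, net)
    cio.write_systems_map(smap, out / "systems_map")
    counts.update(
        binding_partners=len(partners),
        enriched_terms=len(enriched),
        **{f"map_{k}": v for k, v in smap.counts().items()},
    )

    # --- stage 6: survival stratification ---------------------------------
    signature = validated_human if validated_human else measurable
    cohort = gen_patient_cohort(sim, signature=signature)
    cio.write_cohort(cohort, out / "cohort")
    filtered = filter_cohort(cohort)
    strat = stratify_and_test(
        filtered, signature, mode="rnaseq", reps=cfg.kmeans_reps, seed=cfg.seed
    )
    cio.write_tsv(
        strat.labels.rename("label").rename_axis("sample").reset_index(),
        out / "stratification_labels.tsv",
    )
    counts.update(
        cohort_total=len(cohort.samples), cohort_retained=len(filtered.samples)
    )

    summary = {
        "tsos_observed": observed,
        "tsos_per_tissue": per_tissue,
        "tsos_p_empirical": p_emp,
        "tsos_n_samplings": cfg.n_samplings,
        "tsos_set_size": len(measurable),
        "survival_p_logrank": strat.p_logrank,
        "survival_fisher_p_g12": strat.fisher_p_g12,
        "survival_contingency": strat.contingency.to_dict(),
        "counts": counts,
    }
    cio.write_json(summary, out / "summary.json")

    cfg_dict = asdict(cfg)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "stage_counts": counts,
    }
    cio.write_json(manifest, out / "manifest.json")
    return out


def report(run_dir: str | Path, make_plots: bool = True) -> str:
    """Human-readable run summary; also writes KM-curve and null-TSOS
    histogram figures when plotting is enabled. Side-effect-free on the
    stage tables themselves."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    summary = json.loads((run_dir / "summary.json").read_text())
    counts = manifest["stage_counts"]

    p_emp = summary["tsos_p_empirical"]
    n_samp = summary["tsos_n_samplings"]
    p_str = f"< {1.0 / n_samp:g}" if p_emp == 0 else f"{p_emp:g}"
    lines = [
        f"run directory: {run_dir}",
        f"seed: {manifest['seed']}  (config hash {manifest['config_hash'][:12]})",
        "",
        "screen funnel:",
        f"  lines screened           {counts['lines_total']}",
        f"  passed quality filter    {counts['lines_kept']}",
        f"  primary fly hits         {counts['fly_hits']}",
        f"  human orthologs          {counts['human_hit_orthologs']}"
        f" ({counts['hits_measurable']} measurable on platform)",
        f"  validated in secondary   {counts['validated_genes']}",
        "",
        f"TSOS (set of {summary['tsos_set_size']} genes): "
        f"{summary['tsos_observed']:.3f}, empirical p {p_str} "
        f"({n_samp} samplings)",
        "",
        "network:",
        f"  binding partners (>=2 hits)  {counts['binding_partners']}",
        f"  enriched terms               {counts['enriched_terms']}",
        f"  gene-to-term edges           {counts['map_gene_to_term']}",
        f"  protein interactions         {counts['map_ppi']}",
        f"  unassigned hits              {counts['map_unassigned']}",
        "",
        "survival:",
        f"  cohort retained    {counts['cohort_retained']}/{counts['cohort_total']}",
        f"  log-rank p         {summary['survival_p_logrank']:.4g}",
        f"  G12 Fisher p       {summary['survival_fisher_p_g12']:.4g}",
        f"  contingency        {summary['survival_contingency']}",
    ]
    text = "\n".join(lines)
    if make_plots:
        _plots(run_dir, summary)
    return text


def _plots(run_dir: Path, summary: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    null = np.loadtxt(run_dir / "null_tsos.tsv", skiprows=1)
    fig, ax = plt.subplots()
    ax.hist(null, bins=60, color="grey")
    ax.axvline(summary["tsos_observed"], color="red", label="observed TSOS")
    ax.set_xlabel("null TSOS")
    ax.set_ylabel("samplings")
    ax.legend()
    fig.savefig(run_dir / "null_tsos_hist.png", dpi=100)
    plt.close(fig)

    labels = pd.read_csv(run_dir / "stratification_labels.tsv", sep="\t")
    clinical = pd.read_csv(run_dir / "cohort" / "clinical.tsv", sep="\t", index_col=0)
    merged = labels.set_index("sample").join(clinical, how="inner")
    fig, ax = plt.subplots()
    for group, color in (("low", "black"), ("high", "red")):
        sub = merged[merged["label"] == group]
        if len(sub):
            KaplanMeierFitter(label=f"{group} (n={len(sub)})").fit(
                sub["time"], sub["event"]
            ).plot_survival_function(ax=ax, color=color)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    fig.savefig(run_dir / "km_curves.png", dpi=100)
    plt.close(fig)
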