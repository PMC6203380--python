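"""Synthetic study generator.

Emulates every input the pipeline consumes with the statistical structure
the analysis assumes: an RNAi screen with hit-dependent pupariation failure,
probe-level tumor/normal expression panels with a planted tumor-
downregulated gene set, a one-to-one/one-to-many ortholog table, a
scale-free-ish PPI network, a small annotation DAG with upward-closed gene
annotation, and patient cohorts whose survival hazard and KRAS-G12 status
depend on a latent low/high signature-expression group.

All generators draw from independent named substreams of the single config
seed, so outputs are bit-identical under a fixed seed and adding one
generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream
from .config import SimConfig
from .enrichment import AnnotationDAG, GeneSetCollection, InteractionNetwork
from .screen import ControlStats
from .survival import PatientCohort
from .tsos import ExpressionPanel

__all__ = [
    "ScreenTable",
    "gen_screen_table",
    "gen_expression_panel",
    "gen_ortholog_table",
    "gen_gene_sets_and_dag",
    "gen_ppi_network",
    "gen_patient_cohort",
    "fly_gene_ids",
    "human_gene_ids",
]


def fly_gene_ids(n: int) -> list[str]:
    return [f"Dm{i:04d}" for i in range(1, n + 1)]


def human_gene_ids(n: int) -> list[str]:
    return [f"HS{i:04d}" for i in range(1, n + 1)]


@dataclass
class ScreenTable:
    """Per-line screen records plus the control summary and planted truth."""

    records: pd.DataFrame
    control: ControlStats
    planted_hits: pd.Series  # per line, boolean truth


def gen_screen_table(cfg: SimConfig) -> ScreenTable:
    """Simulate the primary screen.

    Non-hit lines draw their pupariation percentage from the control
    distribution (Gaussian with the control mean/SD, clipped to [0, 100] —
    clipping rather than resampling keeps the lower tail, and hence the
    null false-positive rate at any Z cutoff, exactly normal); hit lines
    have the mean reduced by ``pupariation_effect`` percentage points. A
    configurable fraction of hits additionally shows mouth-hook invasion or
    ectopic foci. Line annotations (S19 score, CAN repeats) are drawn so
    roughly ``quality_fail_rate`` of lines fail the specificity filter.
    """
    rng = substream(cfg.seed, "screen")
    n = cfg.n_lines
    genes = fly_gene_ids(n)  # one line per gene at this scale
    is_hit = rng.random(n) < cfg.hit_fraction

    mean = np.where(
        is_hit, cfg.control_mean - cfg.pupariation_effect, cfg.control_mean
    )
    pupariation = np.clip(rng.normal(mean, cfg.control_sd), 0.0, 100.0)
    pct_larvae_d8 = 100.0 - pupariation
    # day 12: most arrested larvae remain arrested; recorded, not used
    pct_larvae_d12 = np.clip(
        pct_larvae_d8 * rng.uniform(0.7, 1.0, size=n), 0.0, 100.0
    )

    invasion = is_hit & (rng.random(n) < cfg.invasion_fraction)
    which = rng.random(n) < 0.5
    mouthhook = invasion & which
    foci = invasion & ~which

    # quality annotations: ~quality_fail_rate of lines fail S19/CAN rules
    fail = rng.random(n) < cfg.quality_fail_rate
    s19 = np.where(
        fail & (rng.random(n) < 0.5),
        rng.uniform(0.3, 0.795, size=n),
        rng.uniform(0.8, 1.0, size=n),
    )
    can = np.where(fail & (s19 >= 0.8), rng.integers(7, 15, size=n), rng.integers(0, 7, size=n))

    records = pd.DataFrame(
        {
            "transformant_id": [f"GD{i:05d}" for i in range(1, n + 1)],
            "construct_id": [f"C{i:05d}" for i in range(1, n + 1)],
            "fly_gene": genes,
            "s19_score": np.round(s19, 3),
            "can_repeats": can.astype(int),
            "off_targets": rng.integers(0, 3, size=n),
            "pct_larvae_day8": np.round(pct_larvae_d8, 2),
            "pct_larvae_day12": np.round(pct_larvae_d12, 2),
            "mouthhook_invasion": mouthhook,
            "ectopic_foci": foci,
        }
    )
    return ScreenTable(
        records=records,
        control=ControlStats(cfg.control_mean, cfg.control_sd),
        planted_hits=pd.Series(is_hit, index=records.index, name="planted_hit"),
    )


def gen_expression_panel(
    cfg: SimConfig, planted_genes: list[str] | None = None
) -> ExpressionPanel:
    """Simulate probe-level tumor/normal expression for every tissue pair.

    Each gene carries k probe sets with k drawn from ``probe_multiplicity``.
    Probe intensities are Gaussian on a log-like scale (per-probe baseline ~
    N(8, 1), unit noise SD). Planted genes have the normal-arm mean above
    the tumor-arm mean by ``planted_effect`` noise SDs in a
    ``planted_pair_fraction`` of pairs — the tumor-downregulation signature
    the screen is designed to find.
    """
    rng = substream(cfg.seed, "expression")
    genes = human_gene_ids(cfg.n_genes)
    if planted_genes is None:
        planted_genes = []
    unknown = set(planted_genes) - set(genes)
    if unknown:
        raise ValueError(f"planted genes outside the universe: {sorted(unknown)[:5]}")

    ks, probs = zip(*sorted(cfg.probe_multiplicity.items()))
    k_per_gene = rng.choice(ks, size=cfg.n_genes, p=probs)
    probes, gene_of = [], []
    for g, k in zip(genes, k_per_gene):
        for j in range(k):
            probes.append(f"{g}_at{j + 1}")
            gene_of.append(g)
    probe_to_gene = pd.Series(gene_of, index=probes, name="gene")
    baseline = rng.normal(8.0, 1.0, size=len(probes))
    planted_mask = probe_to_gene.isin(planted_genes).to_numpy()

    pairs = [f"pair{i:02d}" for i in range(1, cfg.n_tissue_pairs + 1)]
    tissue_labels = {p: (f"normal_{p}", f"tumor_{p}") for p in pairs}
    tumor, normal = {}, {}
    for pair in pairs:
        affected = rng.random() < cfg.planted_pair_fraction
        shift = cfg.planted_effect if affected else 0.0
        t = rng.normal(
            baseline[:, None] - np.where(planted_mask, shift, 0.0)[:, None],
            1.0,
            size=(len(probes), cfg.n_tumor),
        )
        m = rng.normal(baseline[:, None], 1.0, size=(len(probes), cfg.n_normal))
        tumor[pair] = pd.DataFrame(
            t, index=probes, columns=[f"{pair}_T{i}" for i in range(cfg.n_tumor)]
        )
        normal[pair] = pd.DataFrame(
            m, index=probes, columns=[f"{pair}_N{i}" for i in range(cfg.n_normal)]
        )
    return ExpressionPanel(
        pairs=pairs,
        tissue_labels=tissue_labels,
        tumor=tumor,
        normal=normal,
        probe_to_gene=probe_to_gene,
    )


def gen_ortholog_table(cfg: SimConfig, n_fly: int | None = None) -> pd.DataFrame:
    """Simulate the fly -> human/mouse ortholog table.

    Every fly gene maps to exactly one human seed ortholog (no human gene
    seeds two fly genes); a ``one_to_many_rate`` fraction additionally carry
    one or more human inparalogs. Mouse columns mirror the human structure
    and are carried for table fidelity only.
    """
    rng = substream(cfg.seed, "orthologs")
    n = n_fly if n_fly is not None else cfg.n_genes
    fly = fly_gene_ids(n)
    human_seed = human_gene_ids(n)
    rows = []
    next_inp = n + 1
    next_mouse = 1
    for i, f in enumerate(fly):
        hs = [human_seed[i]]
        inp: list[str] = []
        if rng.random() < cfg.one_to_many_rate:
            n_inp = 1 + rng.geometric(0.6)
            inp = [f"HS{j:04d}" for j in range(next_inp, next_inp + n_inp)]
            next_inp += n_inp
        ms = [f"MM{next_mouse:04d}"]
        minp: list[str] = []
        if rng.random() < cfg.one_to_many_rate:
            minp = [f"MM{next_mouse + 1:04d}"]
            next_mouse += 1
        next_mouse += 1
        rows.append(
            {
                "fly_gene": f,
                "human_seed": hs,
                "human_inparalogs": inp,
                "mouse_seed": ms,
                "mouse_inparalogs": minp,
            }
        )
    return pd.DataFrame(rows)


def gen_ppi_network(
    cfg: SimConfig, universe: list[str] | None = None
) -> InteractionNetwork:
    """Simulate a protein-interaction network by preferential attachment.

    Edges are sampled one at a time with endpoint probability proportional
    to (degree + 1), rejecting self-loops and duplicates, which yields the
    right-skewed degree distribution of real interactomes.
    """
    rng = substream(cfg.seed, "ppi")
    nodes = universe if universe is not None else human_gene_ids(cfg.n_genes)
    n = len(nodes)
    max_edges = n * (n - 1) // 2
    if cfg.ppi_edges > max_edges:
        raise ValueError("requested more edges than a simple graph allows")
    degree = np.ones(n)
    edges: set[frozenset] = set()
    while len(edges) < cfg.ppi_edges:
        p = degree / degree.sum()
        a, b = rng.choice(n, size=2, replace=False, p=p)
        e = frozenset((nodes[a], nodes[b]))
        if e in edges:
            continue
        edges.add(e)
        degree[a] += 1
        degree[b] += 1
    return InteractionNetwork(edges=edges)


def gen_gene_sets_and_dag(
    cfg: SimConfig, planted_genes: list[str] | None = None
) -> tuple[GeneSetCollection, AnnotationDAG]:
    """Simulate a rooted annotation DAG and its flat gene-set view.

    A tree of depth ``dag_depth`` and branching ``dag_branching`` is built,
    then a ``dag_crosslink_rate`` fraction of non-root terms gain a second
    parent (making it a genuine DAG). Genes are annotated directly to leaf
    terms and the annotation is closed upward, so the root annotates every
    annotated gene and — when the universe is large enough — exceeds the
    500-gene informativeness cutoff. If ``planted_genes`` is given, one
    dedicated leaf term annotates exactly that set.
    """
    rng = substream(cfg.seed, "genesets")
    genes = human_gene_ids(cfg.n_genes)
    g = nx.DiGraph()  # edges child -> parent
    root = "T:root"
    g.add_node(root)
    levels = [[root]]
    counter = 0
    for _ in range(cfg.dag_depth):
        nxt = []
        for parent in levels[-1]:
            for _ in range(cfg.dag_branching):
                counter += 1
                node = f"T:{counter:04d}"
                g.add_edge(node, parent)
                nxt.append(node)
        levels.append(nxt)
    # cross-links: a second parent from an earlier level (keeps acyclicity)
    for depth in range(2, len(levels)):
        for node in levels[depth]:
            if rng.random() < cfg.dag_crosslink_rate:
                candidates = [t for t in levels[depth - 1] if not g.has_edge(node, t)]
                if candidates:
                    g.add_edge(node, candidates[rng.integers(len(candidates))])

    leaves = levels[-1]
    annot: dict[str, set] = {t: set() for t in g.nodes}
    # every gene lands in 1-3 random leaves
    for gene in genes:
        for leaf in rng.choice(len(leaves), size=rng.integers(1, 4), replace=False):
            annot[leaves[leaf]].add(gene)
    if planted_genes:
        planted_term = "T:planted"
        parent = leaves[0]
        # attach beside the leaves, under the first leaf's parent
        grand = next(iter(g.successors(parent)))
        g.add_edge(planted_term, grand)
        annot[planted_term] = set(planted_genes)
    # upward closure along child -> parent edges
    for node in nx.topological_sort(g):  # children before parents
        for parent in g.successors(node):
            annot[parent] |= annot[node]
    dag = AnnotationDAG(graph=g, annot=annot)
    return dag.as_collection(), dag


def gen_patient_cohort(
    cfg: SimConfig, signature: list[str]
) -> PatientCohort:
    """Simulate a tumor cohort with a latent low/high signature group.

    Half the patients belong to a latent "low" group whose signature-gene
    expression is shifted down by ``cohort_shift_sd`` standard deviations on
    the log scale, whose death hazard is multiplied by
    ``hazard_ratio_low_vs_high``, and whose odds of carrying a KRAS-G12
    mutation are multiplied by ``g12_odds_low_vs_high`` over the base rate.
    Methylation betas anti-correlate with expression for signature genes
    (promoter hypermethylation silencing). A ``missing_rate`` fraction of
    samples lacks survival or mutation records; survival is right-censored
    at ``censoring_rate``.
    """
    if not signature:
        raise ValueError("signature must be nonempty")
    rng = substream(cfg.seed, "cohort")
    n = cfg.n_patients
    samples = [f"P{i:04d}" for i in range(1, n + 1)]
    low = rng.random(n) < 0.5

    sig = list(signature)
    background = [g for g in human_gene_ids(cfg.n_genes) if g not in set(sig)][:100]
    all_genes = sig + background
    # log-scale expression, then back to RSEM-like counts
    base = rng.normal(6.0, 0.5, size=len(all_genes))
    logx = rng.normal(base[:, None], 1.0, size=(len(all_genes), n))
    sig_mask = np.array([g in set(sig) for g in all_genes])
    logx[np.ix_(sig_mask, low)] -= cfg.cohort_shift_sd
    expr = pd.DataFrame(np.expm1(logx.clip(min=0)), index=all_genes, columns=samples)

    # methylation: anti-correlated with expression for signature genes
    z = (logx - logx.mean(axis=1, keepdims=True)) / logx.std(axis=1, keepdims=True)
    logit = np.where(sig_mask[:, None], -z, rng.normal(0, 1, size=z.shape)) + rng.normal(
        0, 0.5, size=z.shape
    )
    beta = pd.DataFrame(1 / (1 + np.exp(-logit)), index=all_genes, columns=samples)

    # survival: exponential, hazard multiplied in the low group
    base_hazard = 1.0 / 600.0  # median ~ 416 days, pancreatic-cancer scale
    hazard = base_hazard * np.where(low, cfg.hazard_ratio_low_vs_high, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < cfg.censoring_rate
    t_obs = np.where(censored, t_event * rng.uniform(0.1, 1.0, size=n), t_event)
    event = (~censored).astype(int)

    # mutation category: G12 odds multiplied in the low group
    p0 = cfg.g12_base_rate
    odds = p0 / (1 - p0) * np.where(low, cfg.g12_odds_low_vs_high, 1.0)
    p_g12 = odds / (1 + odds)
    is_g12 = rng.random(n) < p_g12
    other = ~is_g12 & (rng.random(n) < 0.4)
    category = np.where(is_g12, "G12", np.where(other, "other", "none"))

    miss = rng.random(n) < cfg.missing_rate
    which = rng.random(n) < 0.5
    has_survival = ~(miss & which)
    has_mutation = ~(miss & ~which)

    clinical = pd.DataFrame(
        {
            "time": np.round(t_obs, 1),
            "event": event,
            "mutation_category": category,
            "has_survival": has_survival,
            "has_mutation_call": has_mutation,
        },
        index=pd.Index(samples, name="sample"),
    )
    return PatientCohort(
        expr=expr,
        beta=beta,
        clinical=clinical,
        latent_group=pd.Series(
            np.where(low, "low", "high"), index=samples, name="latent_group"
        ),
    )
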