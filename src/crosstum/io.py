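"""Plain-text readers and writers for every pipeline table.

All files are TSV with a header line; missing values are written as "NA".
Multi-valued ortholog cells are semicolon-separated; gene sets use the GMT
convention (set name, description, then members, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import AnnotationDAG, GeneSetCollection, InteractionNetwork, SystemsMap
from .orthologs import OrthologTable
from .survival import PatientCohort
from .tsos import ExpressionPanel

_NA = "NA"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=_NA)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False, **kwargs)


# -- screen -----------------------------------------------------------------

def write_screen_table(records: pd.DataFrame, path: str | Path) -> None:
    write_tsv(records, path)


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("mouthhook_invasion", "ectopic_foci"):
        if df[col].dtype == object:
            df[col] = df[col].isin(["True", "Y", "yes", "1", True])
        else:
            df[col] = df[col].astype(bool)
    return df


# -- orthologs --------------------------------------------------------------

_ORTH_COLS = {
    "human_seed": "HOMSA",
    "human_inparalogs": "HOMSA-INP",
    "mouse_seed": "MUSMU",
    "mouse_inparalogs": "MUSMU-INP",
}


def write_ortholog_table(table: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"fly_gene": table["fly_gene"]})
    for field, col in _ORTH_COLS.items():
        out[col] = table[field].map(lambda xs: ";".join(xs) if xs else _NA)
    write_tsv(out, path)


def read_ortholog_table(path: str | Path) -> OrthologTable:
    raw = read_tsv(path)

    def split(cell) -> list[str]:
        if pd.isna(cell) or cell == "":
            return []
        return list(dict.fromkeys(str(cell).split(";")))

    table = pd.DataFrame({"fly_gene": raw["fly_gene"].astype(str)})
    for field, col in _ORTH_COLS.items():
        table[field] = raw[col].map(split)
    return OrthologTable(table=table)


# -- expression panel -------------------------------------------------------

def write_expression_panel(panel: ExpressionPanel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.probe_to_gene.rename_axis("probe").reset_index().to_csv(
        outdir / "probe_to_gene.tsv", sep="\t", index=False
    )
    meta = pd.DataFrame(
        [
            {"pair": p, "ss1_normal": panel.tissue_labels[p][0], "ss2_tumor": panel.tissue_labels[p][1]}
            for p in panel.pairs
        ]
    )
    write_tsv(meta, outdir / "tissue_pairs.tsv")
    for pair in panel.pairs:
        write_tsv(panel.tumor[pair], outdir / f"{pair}_tumor.tsv", index=True)
        write_tsv(panel.normal[pair], outdir / f"{pair}_normal.tsv", index=True)


def read_expression_panel(outdir: str | Path) -> ExpressionPanel:
    outdir = Path(outdir)
    p2g = read_tsv(outdir / "probe_to_gene.tsv").set_index("probe")["gene"]
    meta = read_tsv(outdir / "tissue_pairs.tsv")
    pairs = list(meta["pair"])
    labels = {r.pair: (r.ss1_normal, r.ss2_tumor) for r in meta.itertuples(index=False)}
    tumor = {p: read_tsv(outdir / f"{p}_tumor.tsv", index_col=0) for p in pairs}
    normal = {p: read_tsv(outdir / f"{p}_normal.tsv", index_col=0) for p in pairs}
    return ExpressionPanel(
        pairs=pairs, tissue_labels=labels, tumor=tumor, normal=normal, probe_to_gene=p2g
    )


# -- gene sets / DAG / PPI --------------------------------------------------

def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets.sets):
            desc, members = sets.sets[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = (parts[1], set(parts[2:]))
    return GeneSetCollection(sets=sets)


def write_dag_edges(dag: AnnotationDAG, path: str | Path) -> None:
    rows = sorted(dag.graph.edges)
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def read_dag(edge_path: str | Path, gmt_path: str | Path) -> AnnotationDAG:
    edges = read_tsv(edge_path)
    g = nx.DiGraph()
    g.add_edges_from(edges.itertuples(index=False, name=None))
    sets = read_gmt(gmt_path)
    annot = {t: set(members) for t, (_, members) in sets.sets.items()}
    for node in g.nodes:
        annot.setdefault(node, set())
    return AnnotationDAG(graph=g, annot=annot)


def write_ppi_edges(net: InteractionNetwork, path: str | Path) -> None:
    pd.DataFrame(net.edge_list(), columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_ppi_edges(path: str | Path) -> InteractionNetwork:
    df = read_tsv(path)
    return InteractionNetwork.from_pairs(df.itertuples(index=False, name=None))


# -- cohort -----------------------------------------------------------------

def write_cohort(cohort: PatientCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(cohort.clinical, outdir / "clinical.tsv", index=True)
    write_tsv(cohort.expr, outdir / "expression.tsv", index=True)
    write_tsv(cohort.beta, outdir / "methylation.tsv", index=True)


def read_cohort(outdir: str | Path) -> PatientCohort:
    outdir = Path(outdir)
    clinical = read_tsv(outdir / "clinical.tsv", index_col=0)
    for col in ("has_survival", "has_mutation_call"):
        if clinical[col].dtype == object:
            clinical[col] = clinical[col] == "True"
        clinical[col] = clinical[col].astype(bool)
    return PatientCohort(
        expr=read_tsv(outdir / "expression.tsv", index_col=0),
        beta=read_tsv(outdir / "methylation.tsv", index_col=0),
        clinical=clinical,
    )


# -- systems map / results --------------------------------------------------

def write_systems_map(smap: SystemsMap, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unassigned = set(smap.unassigned_hits)
    nodes = pd.DataFrame(
        [
            {"id": n, "type": d["type"], "unassigned": n in unassigned}
            for n, d in sorted(smap.graph.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {"source": a, "target": b, "type": d["type"]}
            for a, b, d in sorted(smap.graph.edges(data=True))
        ]
    )
    write_tsv(nodes, outdir / "map_nodes.tsv")
    write_tsv(edges, outdir / "map_edges.tsv")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
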