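"""Fly-to-human ortholog expansion and platform restriction.

Orthology arrives as a precomputed table of seed orthologs (the primary
cross-species prediction) and inparalogs (within-species duplicates carried
along in one-to-many mappings). Mouse columns are parsed and kept for table
fidelity but unused downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["OrthologTable", "expand_orthologs", "restrict_to_platform"]


@dataclass
class OrthologTable:
    """Rows of fly gene -> human/mouse seed orthologs and inparalogs."""

    table: pd.DataFrame  # columns: fly_gene, human_seed, human_inparalogs,
    #                                mouse_seed, mouse_inparalogs (list cells)
    _by_fly: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if (self.table["fly_gene"] == "").any():
            raise ValueError("empty fly_gene identifier in ortholog table")
        self._by_fly = {
            row.fly_gene: row for row in self.table.itertuples(index=False)
        }

    @property
    def fly_genes(self) -> list[str]:
        return list(self.table["fly_gene"])

    def human_genes(self, include_inparalogs: bool = True) -> set[str]:
        """All human genes appearing in the table."""
        out: set[str] = set()
        for row in self.table.itertuples(index=False):
            out.update(row.human_seed)
            if include_inparalogs:
                out.update(row.human_inparalogs)
        return out


def expand_orthologs(
    fly_hits: list[str],
    table: OrthologTable,
    include_inparalogs: bool = True,
) -> tuple[list[str], list[str]]:
    """Union of human orthologs over the fly hits.

    One-to-many mappings contribute every target: seed orthologs always, and
    inparalogs when ``include_inparalogs`` (the default, matching the
    all-targets convention). Returns ``(human_genes, unmapped_fly_hits)``;
    hits absent from the table are reported, never silently dropped. Output
    is deduplicated and sorted.
    """
    human: set[str] = set()
    unmapped: list[str] = []
    for fly in fly_hits:
        row = table._by_fly.get(fly)
        if row is None:
            unmapped.append(fly)
            continue
        human.update(row.human_seed)
        if include_inparalogs:
            human.update(row.human_inparalogs)
    if unmapped:
        logger.info("%d fly hits had no ortholog table entry", len(unmapped))
    return sorted(human), unmapped


def restrict_to_platform(
    genes: list[str], probe_to_gene: pd.Series
) -> tuple[list[str], list[str]]:
    """Partition genes by presence of >=1 probe set on the platform.

    ``probe_to_gene`` maps probe-set id -> gene id. Returns
    ``(measurable, dropped)``; the parts are disjoint and exhaustive, each
    preserving input order.
    """
    probed = set(probe_to_gene.values)
    measurable = [g for g in genes if g in probed]
    dropped = [g for g in genes if g not in probed]
    logger.info(
        "platform restriction: %d of %d genes measurable",
        len(measurable), len(genes),
    )
    return measurable, dropped
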