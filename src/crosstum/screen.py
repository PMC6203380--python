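"""Primary-screen hit calling and secondary-screen validation.

The in vivo screen crosses RNAi lines into an oncogenic-Ras background and
counts progeny arrested at the larval stage on day 8. A line is a hit when
tumor progression blocks pupariation — a Z-score of the pupariation rate
against the Ras-only control distribution exceeding the cutoff — or when the
tumor invades beyond the mouth hooks / seeds ectopic GFP foci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ControlStats",
    "filter_rnai_quality",
    "pupariation_zscore",
    "call_primary_hits",
    "validate_secondary",
]


@dataclass(frozen=True)
class ControlStats:
    """Mean and SD of the control crosses' pupariation percentage."""

    mean_pupariation: float
    sd_pupariation: float

    def __post_init__(self) -> None:
        if not self.sd_pupariation > 0:
            raise ValueError("control SD must be positive")


def filter_rnai_quality(
    lines: pd.DataFrame, s19_min: float = 0.8, can_max: int = 6
) -> pd.DataFrame:
    """Drop RNAi lines with insufficient targeting specificity.

    A line is excluded when its S19 specificity score is below ``s19_min``
    or it carries more than ``can_max`` CAN repeats; both boundaries are
    therefore inclusive on the *kept* side (s19 == 0.8 and can == 6 pass).
    Row order is preserved.
    """
    if not (np.isfinite(s19_min) and np.isfinite(can_max)):
        raise ValueError("quality thresholds must be finite")
    keep = (lines["s19_score"] >= s19_min) & (lines["can_repeats"] <= can_max)
    kept = lines.loc[keep].copy()
    logger.info("quality filter: %d of %d lines kept", len(kept), len(lines))
    return kept


def pupariation_zscore(
    pct_larvae_test: float | np.ndarray,
    control: ControlStats,
    *,
    input_is_pupariation: bool = False,
) -> float | np.ndarray:
    """Z = (control mean pupariation - test pupariation) / control SD.

    The assay records the percentage of progeny still larval; by default that
    is converted to a pupariation percentage as ``100 - pct_larvae`` before
    differencing, so the score compares pupariation rates (larger Z = fewer
    pupae = stronger arrest). Pass ``input_is_pupariation=True`` if the input
    is already a pupariation percentage.
    """
    pct = np.asarray(pct_larvae_test, dtype=float)
    pup = pct if input_is_pupariation else 100.0 - pct
    z = (control.mean_pupariation - pup) / control.sd_pupariation
    return float(z) if np.isscalar(pct_larvae_test) else z


def call_primary_hits(
    records: pd.DataFrame, control: ControlStats, z_cutoff: float = 1.65
) -> pd.DataFrame:
    """Call primary hits from quality-filtered screen records.

    A record is a larval-arrest hit iff its day-8 Z-score strictly exceeds
    ``z_cutoff``, an invasion hit iff mouth-hook invasion or ectopic foci
    were observed, and a hit iff either holds. Day-12 counts are carried for
    reporting but do not enter the call.
    """
    out = records.copy()
    out["z"] = pupariation_zscore(out["pct_larvae_day8"].to_numpy(), control)
    out["larval_arrest_hit"] = out["z"] > z_cutoff
    out["invasion_hit"] = (
        out["mouthhook_invasion"].astype(bool) | out["ectopic_foci"].astype(bool)
    )
    out["is_hit"] = out["larval_arrest_hit"] | out["invasion_hit"]
    logger.info(
        "hit calling: %d/%d hits (%d larval arrest, %d invasion) at Z > %g",
        int(out["is_hit"].sum()), len(out),
        int(out["larval_arrest_hit"].sum()), int(out["invasion_hit"].sum()),
        z_cutoff,
    )
    return out


def validate_secondary(
    scores: pd.DataFrame, cutoff: float = 0.75
) -> pd.DataFrame:
    """Aggregate secondary-screen phenotype scores per gene.

    ``scores`` needs columns ``fly_gene`` and ``score`` (0-3 scale, one row
    per RNAi line tested). A gene is validated iff the arithmetic mean over
    its lines is >= ``cutoff`` (inclusive). Genes with no scored lines are
    excluded with a warning.
    """
    if ((scores["score"] < 0) | (scores["score"] > 3)).any():
        raise ValueError("secondary scores must lie in [0, 3]")
    counted = scores.dropna(subset=["score"])
    missing = set(scores["fly_gene"]) - set(counted["fly_gene"])
    if missing:
        logger.warning("genes with zero scores excluded: %s", sorted(missing))
    table = (
        counted.groupby("fly_gene", sort=True)["score"]
        .agg(mean_score="mean", n_lines="size")
        .reset_index()
    )
    table["validated"] = table["mean_score"] >= cutoff
    return table
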