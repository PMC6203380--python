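"""Gene-set survival stratification and mutation enrichment.

Patients are split into low and high signature-expression groups by k-means
(k=2) repeated with random initializations; within each repetition the
cluster with the larger mean signature value is "high", and each patient's
final label is the majority over repetitions. The groups are compared by a
two-group log-rank test, and KRAS-G12 over-representation in the low group
by a one-sided Fisher exact test with the "none" and "other" mutation
categories aggregated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "PatientCohort",
    "StratificationResult",
    "filter_cohort",
    "preprocess_expression",
    "aggregate_methylation",
    "stratify_repeated_kmeans",
    "logrank_test",
    "mutation_enrichment",
]

MUTATION_CATEGORIES = ("G12", "other", "none")


@dataclass
class PatientCohort:
    """Expression, methylation, survival and mutation status per sample.

    ``expr`` is a gene x sample matrix of non-negative RSEM-like values;
    ``beta`` methylation fractions in [0, 1] (gene-level, mean-aggregated);
    ``clinical`` has per-sample columns ``time`` (days), ``event`` (1 death,
    0 censored), ``mutation_category`` in {G12, other, none},
    ``has_survival`` and ``has_mutation_call``.
    """

    expr: pd.DataFrame
    beta: pd.DataFrame
    clinical: pd.DataFrame
    latent_group: pd.Series | None = None  # synthetic truth, when known

    def __post_init__(self) -> None:
        valid_beta = self.beta.to_numpy()
        valid_beta = valid_beta[~np.isnan(valid_beta)]
        if ((valid_beta < 0) | (valid_beta > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        t = self.clinical["time"]
        if (t.dropna() < 0).any():
            raise ValueError("survival times must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.clinical.index)


@dataclass
class StratificationResult:
    labels: pd.Series  # sample -> "low" / "high"
    assignment_counts: pd.Series  # sample -> # of "high" assignments
    p_logrank: float
    fisher_p_g12: float
    contingency: pd.DataFrame  # (low, high) x (G12, not_G12)
    km_curves: dict = field(default_factory=dict)


def filter_cohort(cohort: PatientCohort) -> PatientCohort:
    """Keep samples that have both a mutation call and overall-survival
    information; retention is logged (e.g. 132 of 177 kept = 74%)."""
    keep = cohort.clinical["has_mutation_call"].astype(bool) & cohort.clinical[
        "has_survival"
    ].astype(bool)
    kept = keep[keep].index
    if len(kept) == 0:
        raise ValueError("cohort filter removed every sample")
    pct = int(100 * len(kept) / len(keep))  # truncated: 132/177 prints as 74%
    logger.info("cohort filter: %d/%d (%d%%) samples retained", len(kept), len(keep), pct)
    return PatientCohort(
        expr=cohort.expr.loc[:, kept],
        beta=cohort.beta.loc[:, kept],
        clinical=cohort.clinical.loc[kept],
        latent_group=None if cohort.latent_group is None else cohort.latent_group.loc[kept],
    )


def preprocess_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """log(1+x) transform, then z-score each sample across genes.

    ``expr`` is gene x sample with non-negative entries. A sample with zero
    variance across genes is scaled to zeros (logged).
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    logx = np.log1p(expr)
    centered = logx - logx.mean(axis=0)
    sd = logx.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance samples scaled to zeros", int(degenerate.sum()))
    sd = sd.replace(0, 1.0)
    return centered / sd


def aggregate_methylation(
    probe_betas: pd.DataFrame, probe_to_gene: pd.Series
) -> pd.DataFrame:
    """Mean-aggregate probe-level beta values to gene level, per sample.

    NA probes are excluded from each mean; a gene whose probes are all NA in
    a sample yields NA there.
    """
    genes = probe_to_gene.reindex(probe_betas.index)
    return probe_betas.groupby(genes).mean()


def _scale_per_sample(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample (column) centering and unit-variance scaling."""
    centered = matrix - matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1).replace(0, 1.0)
    return centered / sd


def stratify_repeated_kmeans(
    matrix: pd.DataFrame,
    k: int = 2,
    reps: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[pd.Series, pd.Series]:
    """Consensus low/high labels from repeated k-means.

    ``matrix`` is the preprocessed signature-gene x sample profile. Each
    repetition runs Lloyd's k-means (k=2) initialized from k distinct
    samples drawn uniformly; within the repetition the cluster with the
    larger mean signature value is "high". A sample's final label is its
    majority label over the repetitions; a 50/50 tie goes to the group whose
    accumulated centroid is nearer on average (logged). Deterministic under
    ``seed`` and invariant to sample order.

    Returns ``(labels, high_counts)``.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    # order-invariance: seed each rep's init from sorted sample ids so the
    # same cohort shuffled gives identical labels
    order = np.argsort(np.asarray(matrix.columns, dtype=str))
    Xs = X[order]
    rng = np.random.default_rng(seed)
    high_votes = np.zeros(n, dtype=int)
    dist_high = np.zeros(n)
    dist_low = np.zeros(n)
    for _ in range(reps):
        init_idx = rng.choice(n, size=k, replace=False)
        km = KMeans(
            n_clusters=k,
            init=Xs[init_idx],
            n_init=1,
            max_iter=max_iter,
            tol=tol,
            algorithm="lloyd",
        ).fit(Xs)
        means = [Xs[km.labels_ == j].mean() for j in range(k)]
        high_cluster = int(np.argmax(means))
        high_votes += (km.labels_ == high_cluster).astype(int)
        d = np.linalg.norm(Xs[:, None, :] - km.cluster_centers_[None], axis=2)
        dist_high += d[:, high_cluster]
        dist_low += d[:, 1 - high_cluster] if k == 2 else d.min(axis=1)
    is_high = high_votes * 2 > reps
    ties = high_votes * 2 == reps
    if ties.any():
        logger.info("%d majority ties broken by mean centroid distance", int(ties.sum()))
        is_high = np.where(ties, dist_high < dist_low, is_high)
    labels_sorted = np.where(is_high, "high", "low")
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    labels = pd.Series(labels_sorted[inv], index=matrix.columns, name="label")
    counts = pd.Series(high_votes[inv], index=matrix.columns, name="high_votes")
    return labels, counts


def logrank_test(
    labels: pd.Series, time: pd.Series, event: pd.Series
) -> tuple[float, float, dict]:
    """Two-group log-rank test (1 df) comparing low vs high survival.

    Returns ``(chi2, p, km_data)`` where ``km_data`` carries per-group
    (time, event) arrays for Kaplan-Meier plotting.
    """
    low = labels == "low"
    high = labels == "high"
    if not (low.any() and high.any()):
        raise ValueError("both label groups must be nonempty")
    res = _ll_logrank(
        time[low], time[high], event_observed_A=event[low], event_observed_B=event[high]
    )
    km_data = {
        "low": (time[low].to_numpy(), event[low].to_numpy()),
        "high": (time[high].to_numpy(), event[high].to_numpy()),
    }
    return float(res.test_statistic), float(res.p_value), km_data


def mutation_enrichment(
    labels: pd.Series, mutation_category: pd.Series
) -> tuple[float, pd.DataFrame]:
    """One-sided Fisher exact test for KRAS-G12 over-representation in the
    low group, with "none" and "other" aggregated into not-G12."""
    if not ((labels == "low").any() and (labels == "high").any()):
        raise ValueError("both label groups must be nonempty")
    is_g12 = mutation_category == "G12"
    table = pd.DataFrame(
        {
            "G12": [
                int((is_g12 & (labels == "low")).sum()),
                int((is_g12 & (labels == "high")).sum()),
            ],
            "not_G12": [
                int((~is_g12 & (labels == "low")).sum()),
                int((~is_g12 & (labels == "high")).sum()),
            ],
        },
        index=["low", "high"],
    )
    _, p = stats.fisher_exact(table.to_numpy(), alternative="greater")
    return float(p), table


def stratify_and_test(
    cohort: PatientCohort,
    signature: list[str],
    mode: str = "rnaseq",
    reps: int = 100,
    seed: int = 0,
    scale_before_restrict: bool = True,
) -> StratificationResult:
    """Full stratification: preprocess, consensus k-means, log-rank and
    G12 Fisher enrichment.

    ``mode='rnaseq'`` uses log(1+x)-transformed, per-sample-scaled
    expression; ``mode='methylation'`` uses beta values with per-sample
    scaling only (betas are already bounded). By default each patient's
    *whole* profile is scaled and clustering then uses the signature genes;
    per-sample scaling is only well-posed on the full profile — scaling
    after restriction would absorb any signature-wide shift into the
    per-sample mean and erase exactly the signal being sought. Set
    ``scale_before_restrict=False`` for the restriction-first variant.
    """
    present = [g for g in signature if g in cohort.expr.index]
    if not present:
        raise ValueError("no signature genes present in the cohort matrix")
    if mode == "rnaseq":
        source = cohort.expr
        mat = (
            preprocess_expression(source).loc[present]
            if scale_before_restrict
            else preprocess_expression(source.loc[present])
        )
    elif mode == "methylation":
        beta = cohort.beta.fillna(cohort.beta.mean(axis=1).mean())
        mat = (
            _scale_per_sample(beta).loc[present]
            if scale_before_restrict
            else _scale_per_sample(beta.loc[present])
        )
    else:
        raise ValueError("mode must be 'rnaseq' or 'methylation'")
    labels, counts = stratify_repeated_kmeans(mat, reps=reps, seed=seed)
    chi2, p_lr, km = logrank_test(
        labels, cohort.clinical["time"], cohort.clinical["event"]
    )
    p_fisher, table = mutation_enrichment(labels, cohort.clinical["mutation_category"])
    return StratificationResult(
        labels=labels,
        assignment_counts=counts,
        p_logrank=p_lr,
        fisher_p_g12=p_fisher,
        contingency=table,
        km_curves=km,
    )
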