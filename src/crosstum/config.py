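"""Simulation and pipeline configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _check_count(name: str, value: int, minimum: int = 1) -> None:
    if int(value) != value or value < minimum:
        raise ValueError(f"{name} must be an integer >= {minimum}, got {value!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the screen and cohort scale of the original study where
    stated (control pupariation 98.8% with SD 5; ~10% of RNAi lines failing
    the specificity filter; an 80-gene survival signature; hazard ratio 3 and
    G12 odds 4 between the latent expression groups), and otherwise use
    desk-scale sizes a simulation study in this field would call realistic.

    Attributes
    ----------
    seed
        Top-level seed; every generator derives an independent substream.
    n_lines, hit_fraction, pupariation_effect
        RNAi screen size, fraction of lines targeting true modifiers, and the
        percentage-point drop in mean pupariation caused by a true hit.
    control_mean, control_sd
        Pupariation percentage of the oncogene-only control crosses.
    invasion_fraction
        Fraction of true hits that additionally show mouth-hook invasion or
        ectopic GFP foci.
    n_genes, probe_multiplicity, n_tissue_pairs, n_tumor, n_normal
        Expression-panel geometry: gene universe size, distribution of
        probe sets per gene (probability of k = 1, 2, 3, ...), number of
        tumor/normal tissue pairs, and samples per arm.
    planted_set_size, planted_effect, planted_pair_fraction
        Size of the planted tumor-downregulated gene set, its standardized
        mean difference (normal minus tumor), and the fraction of tissue
        pairs in which the effect is present.
    one_to_many_rate
        Fraction of fly genes carrying >=1 human inparalog beyond the seed
        ortholog.
    ppi_edges
        Number of protein-interaction edges (preferential attachment).
    dag_depth, dag_branching, dag_crosslink_rate
        Annotation-DAG geometry; cross-links give some terms two parents.
    n_patients, signature_size, cohort_shift_sd, hazard_ratio_low_vs_high,
    g12_odds_low_vs_high, g12_base_rate, censoring_rate, missing_rate
        Patient-cohort geometry: latent low-expression group has signature
        expression shifted down by ``cohort_shift_sd`` standard deviations,
        death hazard multiplied by ``hazard_ratio_low_vs_high``, and KRAS-G12
        odds multiplied by ``g12_odds_low_vs_high`` relative to the base rate.
        ``missing_rate`` of samples lack survival or mutation records.
    """

    seed: int = 0

    # screen
    n_lines: int = 2000
    hit_fraction: float = 0.05
    pupariation_effect: float = 35.0
    control_mean: float = 98.8
    control_sd: float = 5.0
    invasion_fraction: float = 0.3
    quality_fail_rate: float = 0.1

    # expression panel
    n_genes: int = 619
    probe_multiplicity: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15}
    )
    n_tissue_pairs: int = 10
    n_tumor: int = 30
    n_normal: int = 30
    planted_set_size: int = 50
    planted_effect: float = 2.0
    planted_pair_fraction: float = 1.0

    # orthology
    one_to_many_rate: float = 0.3

    # PPI network
    ppi_edges: int = 2000

    # annotation DAG
    dag_depth: int = 4
    dag_branching: int = 3
    dag_crosslink_rate: float = 0.15

    # patient cohort
    n_patients: int = 200
    signature_size: int = 80
    cohort_shift_sd: float = 1.5
    hazard_ratio_low_vs_high: float = 3.0
    g12_odds_low_vs_high: float = 4.0
    g12_base_rate: float = 0.3
    censoring_rate: float = 0.3
    missing_rate: float = 0.15

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_count("seed", self.seed, minimum=0)
        for name in ("n_lines", "n_genes", "n_tissue_pairs", "n_tumor",
                     "n_normal", "planted_set_size", "dag_depth",
                     "dag_branching", "n_patients", "signature_size"):
            _check_count(name, getattr(self, name))
        _check_count("ppi_edges", self.ppi_edges, minimum=0)
        for name in ("hit_fraction", "invasion_fraction", "quality_fail_rate",
                     "planted_pair_fraction", "one_to_many_rate",
                     "dag_crosslink_rate", "censoring_rate", "missing_rate",
                     "g12_base_rate"):
            _check_fraction(name, getattr(self, name))
        if self.control_sd <= 0:
            raise ValueError("control_sd must be positive")
        if self.hazard_ratio_low_vs_high <= 0 or self.g12_odds_low_vs_high <= 0:
            raise ValueError("hazard and odds ratios must be positive")
        total = sum(self.probe_multiplicity.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("probe_multiplicity probabilities must sum to 1")
        if any(k < 1 for k in self.probe_multiplicity):
            raise ValueError("probe counts must be >= 1")


@dataclass
class PipelineConfig:
    """End-to-end run configuration: thresholds of every stage plus the seed.

    Threshold defaults are the study's published choices: Z > 1.65 for
    larval-arrest hits, probe-level alpha 0.01, enrichment alpha 0.05 with a
    500-gene term-size cap, top-100 candidate selection, secondary-screen
    cutoff 0.75, binding partners interacting with >=2 hits, 100 k-means
    repetitions.
    """

    seed: int = 0
    z_cutoff: float = 1.65
    alpha_probe: float = 0.01
    alpha_enrich: float = 0.05
    max_term_size: int = 500
    n_top: int = 100
    secondary_cutoff: float = 0.75
    min_hit_degree: int = 2
    kmeans_reps: int = 100
    n_samplings: int = 10000
    include_inparalogs: bool = True
    rnaseq_mode: bool = False
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.z_cutoff != self.z_cutoff:  # NaN guard
            raise ValueError("z_cutoff must be finite")
        for name in ("alpha_probe", "alpha_enrich"):
            _check_fraction(name, getattr(self, name))
        _check_count("max_term_size", self.max_term_size)
        _check_count("n_top", self.n_top, minimum=0)
        _check_count("n_samplings", self.n_samplings)
        _check_count("kmeans_reps", self.kmeans_reps)
        _check_count("min_hit_degree", self.min_hit_degree)
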