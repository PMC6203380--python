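# Methods

This note documents the models, the defaults and the numerical choices of
the package, and what the synthetic study does and does not establish.

## Screen model and hit calling

The primary screen reads out tumor progression as pupariation failure. The
control distribution is summarized by its mean and SD (defaults 98.8% and
5, the oncogene-only cross's empirical values), and a line's Z-score is
(control mean pupariation − test pupariation) / control SD. Two readings
are deliberate:

- **Control SD, not per-line SD.** A single cross yields one measurement
  per line, so no per-line SD exists; the divisor is the control SD.
- **Strict cutoff.** A line at exactly Z = 1.65 is not a hit.
- **Larval-% conversion.** The assay counts the percentage of progeny still
  larval; `pupariation_zscore` converts to pupariation % as 100 − larvae
  before differencing (an `input_is_pupariation` flag accepts the other
  convention). Day-12 counts are carried but never enter the call, which
  uses day 8.

The generator draws non-hit pupariation from N(control mean, control SD)
**clipped** to [0, 100] rather than resampled: clipping leaves the lower
tail intact, so the null probability of Z > z equals the normal tail mass
exactly — the property the calibration checks rely on — whereas rejection
sampling would shift the mean. Hit lines have the mean reduced by
`pupariation_effect` (default 35 points). Quality annotations are drawn so
~10% of lines fail the specificity filter, mirroring the screened-library
attrition.

## Direction scores and the TSOS

Probe-level calls use Welch's two-sample t-test (unequal variances),
two-sided at `alpha_probe` = 0.01, with the sign read from the arm means —
equivalent to two one-sided tests at alpha/2. Arms with fewer than two
values or zero variance are degenerate and score 0 (logged). Genes without
any probe set are excluded from scoring, not scored 0 (mirroring the
platform-census step). An RNA-seq mode applies log(1+x) before testing;
the direction logic is unchanged.

The TSOS divides the summed gene×pair scores by the gene count only —
per-pair values are not renormalized, so a gene unmeasured in a pair
contributes 0 there. The resampling null draws sets without replacement
(independently across samplings) from the universe of orthologs of all
screened genes, never from all genes, passed explicitly. The empirical
p counts null values strictly below the observed statistic (k/N); a
(k+1)/(N+1) estimator is available by flag. A p of 0 is stored as 0 but
printed as "< 1/N" to avoid over-claiming precision. Null sampling is
vectorized by random-key `argpartition` in chunks of 20,000 samplings to
bound memory.

Ranking uses per-gene totals (sum over pairs, no division), ascending, with
lexicographic gene-id tie-breaks for determinism.

## Enrichment and DAG condensation

Over-representation is P(X ≥ k), X ~ hypergeometric, after intersecting
each set with the explicit universe — identical to the one-sided Fisher
exact test on the 2×2 table. Benjamini–Hochberg FDR is reported alongside
but selection uses the nominal p (≤ 0.05 by default; ≤ 500-gene term cap,
both boundaries inclusive: "more than 500" is discarded). An optional
more-than-k-candidates filter supports the stricter map-building context
(alpha 0.01, > 2 candidates).

Condensation removes non-significant terms in reverse-topological order
(roots first), rewiring each removed term's children to all of its parents.
Order does not affect the final reachability — which equals the transitive
closure of the input restricted to significant terms, property-tested —
but fixing it makes the procedure deterministic. Diamond-ancestry
multi-edges are deduplicated (simple-graph output); cycles raise.

Binding partners are non-hit genes adjacent to ≥ `min_hit_degree` = 2
distinct hits; hits are never their own partners. The systems map types
nodes (hit / partner / term) and edges (gene-to-term / ppi) and flags hits
belonging to no enriched term — the candidate novel genes.

## Survival stratification

Consensus k-means: per repetition, Lloyd's algorithm (k = 2, Euclidean,
max 300 iterations, tolerance 1e-6) initialized from k distinct samples
drawn uniformly; within each repetition the cluster with the larger mean
signature value is "high" — aligning **before** voting, because majority
voting under label switching is ill-defined; each sample then takes its
majority label over the (default 100) repetitions. Exact 50/50 ties break
toward the group whose accumulated centroid is nearer (logged).
Repetition seeds are derived after sorting samples by id, so labels are
invariant to sample order.

**Scaling precedes restriction.** Expression is log(1+x)-transformed and
z-scaled per patient *across the patient's whole profile*, and clustering
then uses the signature genes. Scaling after restriction would absorb any
signature-wide shift into the per-sample mean and erase exactly the signal
being sought (a uniform δ shift of all signature genes leaves the
restricted z-scores unchanged — verified empirically: recovery drops to
chance). The restriction-first variant remains available via
`scale_before_restrict=False`. Methylation stratification reuses the same
machinery on beta values with per-sample scaling but no log transform
(betas are already bounded).

The log-rank test (lifelines, standard aggregated-risk-set tie handling) is
cross-checked against a permutation null in the tests. Mutation enrichment
aggregates "none"+"other" against G12 and tests one-sided for G12
over-representation in the low group. The cohort filter keeps samples with
both a mutation call and survival data, logging the retained percentage
truncated to an integer (132/177 prints as 74%).

## Synthetic study: what it emulates, and not

The generator fans a single seed into named, CRC-keyed substreams
(`crosstum._rng.substream`), so outputs are bit-identical under a fixed
seed and adding a generator never perturbs another — the determinism every
test relies on.

Emulated structure: hit-dependent pupariation failure; per-gene probe-set
multiplicity (60/25/15% for 1/2/3 probes); Gaussian probe noise on a
log-like intensity scale (baseline N(8,1), unit SD — the simplest model
consistent with t-testing); a planted tumor-downregulated set (default 50
genes, 2 SD, present in all pairs, fraction configurable); one-to-many
orthology with unique seed orthologs; preferential-attachment PPI edges
(right-skewed degrees); a rooted annotation DAG with cross-links (some
terms have two parents), upward-closed annotation, and a root exceeding the
500-gene cap when the universe permits; and cohorts whose latent low group
carries a 1.5-SD signature shift, hazard ratio 3 and G12 odds 4 (base rate
0.3), with methylation betas anti-correlated with signature expression
(promoter-hypermethylation silencing) and ~15% of samples missing survival
or mutation records. Cohort survival is exponential with baseline median
~416 days (pancreatic-cancer scale) and ~30% right-censoring.

Not emulated: microarray normalization artifacts, batch effects, probe
cross-hybridization, copy-number or full mutation spectra, covariate
structure in survival. Passing tests therefore establish the correctness
and calibration of the *statistical machinery* under the assumed models,
not robustness to real-data artifacts.

## Calibration and power checks: problem sizes

Null calibration uses 200 replicate panels of 200 genes × 6 tissue pairs ×
15 samples/arm with 2,000 samplings each: large enough that ties at
TSOS = 0 are rare (< 1%), which matters because the strict-less empirical
p is only uniform up to ties. Survival calibration uses 200 cohorts of
n = 2,000: the exact Fisher p is discrete with atoms of order 1/√n (~0.16
at n ≈ 130, where no implementation could look uniform), and n = 2,000
shrinks the atoms to ~0.04 so a KS test against Uniform(0,1) is
meaningful. Power checks use the planted defaults (50-gene set, 2 SD, 10
pairs, 30/arm; cohorts of 200 with HR 3 and odds 4 over 100 replicates,
25 k-means repetitions per cohort). These sizes are the package's own
choices for a desk-scale study; all are parameters.

## Known limitations

- The repeated-k-means consensus can, in principle, produce a majority
  label set that no single repetition produced; with well-separated groups
  this does not occur, and the assignment counts are exposed for auditing.
- The empirical p under the plain-count convention can be exactly 0;
  reporting uses the "< 1/N" form, but downstream numeric consumers see 0.
- The preferential-attachment sampler targets an exact edge count, so its
  degree distribution is only "scale-free-ish"; it is not a calibrated
  interactome model.
- `gene_total_score` warns rather than errors for genes scoring 0
  everywhere — an all-zero row is indistinguishable from "measured, no
  signal".
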