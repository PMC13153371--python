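# Methods

This note documents the statistical models, parameter choices, and
numerical conventions behind `panquant`, and what the synthetic
evaluation does and does not establish.

## Data model

Matrices are proteins × samples, log2 scale, with missing entries stored
as NaN (the `missing_mask` view is derived from it, so a masked cell can
never leak a numeric value into a computation). A cohort is an
(indication, tissue) pair; every cohort-aware operation validates that
each sample has a cohort before slicing columns. Protein and sample
identifiers are opaque strings; identifier mapping is an upstream
concern. The TSV dialect accepts "", "NA", "NaN" (case-insensitive) as
missing and writes values via `repr`, so a write/read round trip is
bit-exact.

## Robust-protein selection

The rule keeps protein *j* if some tumor indication has percentile rank
F > 0.5 of its median abundance and missing rate M < 0.25, both strict.
Conventions the rule statement leaves open:

- Percentile ranks use average ranks for ties, divided by the number of
  proteins with a *defined* median in that cohort. Proteins entirely
  missing in a cohort have no median and are excluded from that
  cohort's rank denominator.
- Cutoffs (0.5, 0.25) are configuration parameters; they are empirical
  trade-offs between discarding proteins and retaining unquantifiable
  ones, not estimated quantities.

Selection depends only on tumor cohorts; kept proteins are retained in
all cohorts. `selection_mass_report` quantifies the per-sample fraction
of total observed iBAQ mass retained, the natural check that selection
discards many proteins but little signal mass.

## Missingness-mechanism classification

Model: within a cohort, per-protein mean abundances would be
Normal(μ, σ²) if fully observed. Intensity-dependent dropout
(left-censoring) removes mass at the low end; the classifier compares
the theoretical CDF F_e of the fitted complete distribution against the
empirical CDF F_o of observed means with the objective
((F_e − F_o + 1)/(F_o + 1) − 1)·10, whose (F_o + 1) denominator
emphasizes the low-intensity range. Numerical conventions:

- (μ, σ) come from least squares on the normal Q-Q line restricted to
  plotting positions in [0.5, 1.0] (configurable) — the upper portion
  is the part least affected by left-censoring. Plotting positions are
  (c + k − 0.5)/(n + c), where c counts values known to be censored
  below the smallest observation (fully missing proteins for the
  classifier; missing cells of a column for QRILC). Ignoring c
  compresses the positions of a censored sample and biases even the
  upper-range fit; with it, (μ, σ) are recovered to ~0.1 log2 units at
  n = 5000 under 30% censoring.
- The objective is evaluated exactly at the sorted observed means: F_o
  is a right-continuous step function, so the maximizer lies at a data
  point. Ties break toward the smaller mean. A threshold is reported
  only when the maximum is strictly positive; on uncensored data F_o
  weakly dominates F_e at data points, so no threshold is typically
  found and every protein is MAR.
- Proteins with zero observed values in a cohort are MNAR by
  convention — left-censoring is the conservative mechanism when
  nothing was observed — and are flagged (`all_missing`) so downstream
  interpretation can treat them with caution.
- MAR and MCAR are deliberately not distinguished; both route to KNN.

**Identifiability.** The decision rule (mean observed ≤ threshold) is
informative only when censoring is sharp relative to the between-protein
abundance spread: then a censored protein is missing in most samples of
a cohort and its observed mean (if any) sits near the censoring point,
which is where the objective's maximum lands. When within-cohort noise
is comparable to the censoring scale, partially censored proteins have
truncated means well *above* the threshold and the rule's recall
degrades — a structural property of mean-based mechanism
classification, not of this implementation. The recovery benchmarks
therefore use the hard-censoring regime (step-like censoring at slope
50, between-protein SD 3, within-cohort noise SD 0.05, 10 samples per
cohort, 5% random dropout), where recall and precision both exceed 0.8
across seeds; diffuse-censoring regimes are expected to, and do, fall
below that.

## Cohort-hybrid imputation

MNAR holes: QRILC. Per sample column, (μ, σ) are estimated by the
shared Q-Q estimator with c = the column's missing count; missing
entries are drawn from Normal(μ, σ·tune_sigma) truncated above at
μ + σ·Φ⁻¹(missing fraction) — the complete-distribution quantile the
censored mass sits below. `tune_sigma` (default 1.0) rescales the draw
spread only. Columns with fewer than 10 observed values fall back to a
cohort-pooled estimate (logged).

MAR holes: protein-wise KNN, k = 10. Distance between proteins is the
root-mean-square difference over samples where both are observed
(proteins sharing no observed sample are not neighbors); a hole takes
the mean of the k nearest proteins observed at that sample, fewer if
fewer qualify, and the protein's own observed mean if none do. KNN is
deterministic; QRILC draws use a per-cohort RNG seeded from the master
seed and a CRC of the cohort label, so a cohort's imputations are
invariant to which other cohorts are present.

Routing is per protein-cohort (a protein may be MNAR in one cohort and
MAR in another), and provenance (observed / imputed_qrilc /
imputed_knn) is recorded per entry.

## Quantification

iBAQ divides linear-scale imputed abundance by the number of
theoretically observable peptides (annotation input; computing it from
sequences is out of scope). riBAQ and copy number are derived from the
*un-normalized* iBAQ table. The copy-number total (molecules per cell)
is a required configuration parameter with no default: the appropriate
constant is a property of the experiment, and only the
riBAQ-proportionality contract is implemented here.

## Normalization

Both quantile methods operate on log2(iBAQ) — the scale on which
distributions are compared and differential expression runs; quantile
normalization is monotone per column, so the choice of scale does not
reorder values within a sample. Ties receive the mean of the reference
values their run spans, which keeps the procedure exactly idempotent.

Smooth quantile normalization follows the published group-aware scheme:
at each rank, the total sum of squares of sample order statistics
around the overall reference splits into between-group and residual
parts; the raw weight 1 − SSB/SST is rolling-median smoothed (window =
5% of ranks) and clipped to [0, 1]; the normalized value blends
w·overall + (1−w)·group reference. With one group (or groups with
identical values) SSB = 0, w ≡ 1, and the method coincides with global
normalization; with i.i.d. groups of 40+ samples it agrees with global
normalization to ~1e-2 (sampling noise in group references times a
weight of order 1/N — exact agreement is a limit, not a finite-sample
identity). Grouping defaults to cohort and can be relaxed to
indication. Median normalization and batch correction beyond
normalization are out of scope.

## Differential expression

Per indication, unpaired two-group (tumor vs NAT) protein-wise linear
models: pooled variance s² on n₁+n₂−2 df. The variance prior is the
conjugate scaled-inverse-χ² — equivalently s² | σ² ~ σ²·χ²_df/df with
1/σ² ~ χ²_d0/(d₀·s₀²) — fitted by moment matching of log s²:
Var(log s²) − ψ′(df/2) = ψ′(d₀/2) is inverted by geometric bisection to
1e-8, and log s₀² = mean(e) + ψ(d₀/2) − log(d₀/2). Homogeneous
variances give d₀ = ∞ and posterior variances equal to s₀². The
moderated t uses the posterior variance on df + d₀ degrees of freedom
(normal reference when infinite); d₀ = 0 reproduces the ordinary pooled
t-test exactly. BH adjustment is the step-up rule implemented directly.
DEP thresholds default to |log2 FC| > 1 (fold change > 2) and
FDR < 0.01, strict. Tumor/NAT sample pairing is not modelled.

## Evaluation

Weighted rank concordance: validation proteins have protein-RNA
Pearson r > 0.5 (tumor samples, per indication) in a strict majority of
indications with a defined r; indications contributing fewer than 3
qualifying proteins are excluded by rule. For each validation protein,
indications are ranked (average ranks) by median tumor signal in the
protein matrix and in the RNA matrix, and v is the weighted Pearson
correlation of the two rank vectors with the per-indication protein-RNA
correlations (clipped at 0) as weights; with equal weights v is exactly
Spearman's rho. v is clipped to [−1, 1] against floating-point
overshoot. Correlation weights should be computed on the
pre-normalization matrix (the `correlation_matrix` argument).

Subset stability: all k-indication subsets are enumerated
(lexicographic); global quantile normalization is re-run independently
inside each subset's samples. One anchor subset is compared against all
others via per-overlapping-sample Pearson r (comparing one anchor
rather than all pairs keeps the cost linear in the number of subsets);
fold-change consistency re-runs the moderated-t analysis per subset for
a chosen indication and reports the pairwise correlation matrix of
log2 FC vectors and the DEP-count distribution (IQR).

## Synthetic data generator

The generator emulates the structure the analysis assumes:
per-protein baselines Normal(20, 2²) in log2 units (typical reporter-ion
intensity scale), per-indication offsets Normal(0, 0.5²) shared by the
indication's tumor and normal cohorts, per-protein×indication
biological effects Normal(0, 1²) — the signal that makes
cross-indication protein ranks meaningful and that rank-preserving
normalization should retain — tumor effects on a 10% protein fraction
(Normal(0, 1.5²), or fixed ±de_effect_size), within-cohort sample noise
Normal(0, 1²), logistic left-censoring P(MNAR) =
sigmoid(slope·(threshold − value)) with threshold 17 and slope 2
(slope 50 serves as the hard-censoring limit; slope 0 disables
censoring), independent uniform dropout at rate 0.05, peptide counts
uniform on 1-60 independent of abundance (so iBAQ arithmetic is
exercised without confounding), and RNA = latent protein value +
Normal(0, rna_noise_sd²), giving a within-indication protein-RNA
correlation of 1/√(1 + rna_noise_sd²/noise_sd²). Six indications with
10 tumor + 10 NAT samples each keep the default dataset desk-sized.
`apply_technical_scaling` adds per-cohort location shifts to model
platform/lab effects that normalization should remove.

What the generator does **not** model: TMT plex/batch structure and
reporter-ion-level noise, peptide-level quantities, missingness that
depends on peptide properties, heavy-tailed or multimodal abundance
distributions, correlated protein modules, and indication-specific
tumor effects. Passing tests therefore demonstrate that the
implementation honors its contracts and recovers truth under the stated
generative model — not that the method is optimal on real acquisitions.

## Benchmark problem sizes

The benchmark battery (`panquant.benchmarks`, reported by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`)
uses: 1000 random 50-protein × 4-indication toys for selection-oracle
equivalence; 2000-protein cohorts × 10 seeds for classification
recovery; 5000-value columns (5 replicates, pooled) for the QRILC tail
contract and a 2000-protein 2-indication dataset for hybrid-vs-KNN
error; 5000 simulated variances and 5000-protein null matrices for the
DEP engine; and 1500-protein 6-indication datasets for the end-to-end
normalization mirror (with technical scaling SD 2) and the size-3
subset-stability analysis. These sizes give stable statistics while the
whole battery completes in about a minute on one core.

## Known limitations

- Mechanism classification is identifiable only under sharp censoring
  (see above); its calls should be read as "predominantly censored",
  not per-entry truth.
- QRILC's truncation point inherits estimation error from (μ, σ); a
  small fraction of draws can land just above the true censoring point.
- The empirical-Bayes prior assumes a common variance model across
  proteins; strong variance heterogeneity with small d₀ weakens
  moderation benefits.
- The weighted rank correlation admits variants; the
  weighted-Pearson-on-ranks form used here is pinned down by the
  equal-weights-equals-Spearman property.
- With global quantile normalization, common (all-protein) indication
  offsets are removed along with technical shifts; only
  protein-specific indication signal survives, which is why the rank
  evaluation requires such signal to exist.
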