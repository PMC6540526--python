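# Methods

## Repertoire measurements

A repertoire is the set of unique assembled variable-region nucleotide
sequences (clones) of one immunoglobulin or TCR locus in one sample, with
read counts c₁…c_S and clone proportions pᵢ = cᵢ/Σc. Clone identity is the
exact nucleotide sequence within (sample, chain); reading a clone table
merges duplicate sequences by summing counts and drops zero-count rows.

Measurements, per (sample, chain):

* **total_count_norm** — Σc / library_size × 10⁶, clone reads per million
  total RNA-seq reads (CPM). The library size comes from a sidecar table
  (`sample_id`, `total_reads`); clone counts are treated as plain
  non-negative read counts.
* **richness** S — number of clones with positive count.
* **shannon** H = −Σ pᵢ ln pᵢ. Natural log by default; a log2 option
  rescales H and Pielou evenness together.
* **simpson_concentration** λ = Σ pᵢ² and **gini_simpson** 1 − λ. Both are
  always reported side by side because "Gini-Simpson" is used for either
  quantity in the literature; the two sum to 1 exactly.
* **evenness** — the literal H/S by default (this is the quantity whose
  hazard ratio the survival screen reports); Pielou's H/ln S (0 when
  S = 1) is available as `pielou` and is also written to output tables,
  since "entropy normalized by richness" admits both readings.
* **top_clone_prop / second_clone_prop** — largest and second-largest pᵢ;
  the second is an explicit NA when S = 1. Missing metrics are written as
  the NA token, never 0.
* **mean_v_identity** — percent identity of each clone to its best-matching
  germline V gene, averaged unweighted over unique clones (an
  abundance-weighted mean is available); a surrogate for somatic
  hypermutation load. Mean mismatch count is exposed alongside.

Rank-abundance structures keep clones with proportion strictly above 0.01
(configurable), ranked by descending proportion with proportion ties broken
by sequence lexicographic order.

### Germline alignment

Clone-vs-germline alignment is semi-global (free end gaps) with match +1,
mismatch −1, internal gap open −4, extend −1, via Biopython's
PairwiseAligner. When a clone carries a `v_call` present in the reference
only that gene is scored; otherwise all germlines are tried and the best
score wins, ties to the lexicographically first gene name. Identity is
matches over alignment columns between the first and last aligned pair
(internal gaps count against identity). One deliberate refinement: where
*both* sequences dangle at the same end of the optimal alignment, the
overlapping overhang is counted as mismatched columns. Without this, a
substitution at a terminal position scores better as a pair of free end
gaps than as an aligned mismatch and silently vanishes from the identity
denominator; with it, identity on substitution-only data equals
100 × (1 − substitution fraction) exactly, which the test suite checks to
1e-9. One-sided overhangs (a clone covering part of the V gene, or vice
versa) remain free. Clones containing N are counted in abundance metrics
but excluded from alignment.

## Expression classifiers

**Silhouette filtering.** Training cohorts are reduced to samples with
strictly positive silhouette width s(i) = (b − a)/max(a, b) (a = mean
within-class distance, b = smallest mean distance to another class;
identical samples get 0 by convention). Distances are Euclidean on
median-centered genes by default, correlation distance by option. A class
losing all samples, or containing a single sample, is an error.

**Nearest-centroid predictor.** Per gene g and class k the score is the
standardized mean difference (mean_k − mean_outside) / (s_pooled + s₀),
with s_pooled the pooled within-class SD and shrinkage s₀ the median pooled
SD across genes (keeps near-constant genes from dominating). The requested
gene count is allocated equally across classes round-robin by absolute
score, skipping genes already taken. Centroids are class means over the
selected genes; prediction is argmin distance with softmax(−d)
probabilities and lexicographic tie-break. The reported cv_error is the
pooled misclassification over seeded stratified 5-fold cross-validation
with gene selection redone inside each fold (avoiding selection bias);
training_error is resubstitution error. The published predictor this
emulates used 1260 genes; the per-class allocation there is unstated, so
equal allocation was chosen.

**Linear phenotype classifier.** The original distance-weighted
discrimination fit is a generic linear reference-profile classifier here;
any deterministic regularized linear multiclass model satisfies that role,
and a ridge-penalized logistic regression (lbfgs, fixed iteration cap) is
used. Calls are the highest softmax probability over the per-class linear
scores. The variance filter retains genes with sample SD (ddof = 1)
strictly above 0.2 on the log2 scale.

## Survival and association inference

Cox proportional-hazards models use Efron tie handling (lifelines).
Continuous measurements are **z-scored before fitting, so hazard ratios
are per SD of the measurement** — published cohort tables do not state
their unit, so absolute HR values are comparable only in sign and rough
magnitude. Covariates follow the clinical screen: tissue site, sex and
stage as indicator columns (first sorted level as reference; stage mapping
configurable), age continuous. Complete separation or non-convergence
triggers a warning and a ridge-penalized refit (penalizer 0.1).

The measurement's contribution is judged by the nested likelihood-ratio
test 2(LL_full − LL_reduced) ~ χ²(Δterms), clamped at 0 against solver
tolerance. For the univariable test the reduced model is empty; its Efron
partial log-likelihood at β = 0 is closed-form (a distinct event time with
d tied events and risk set n contributes −Σ_{j=0}^{d−1} ln(n − j)) and is
cross-checked in tests against a heavily penalized near-null fit. Both
Wald and LRT p-values are reported for the univariable column since
published tables are ambiguous about which they print.

Mann–Whitney U uses the exact null distribution when both groups have ≤ 12
observations and no ties, otherwise the normal approximation with tie
correction (all-tied input returns p = 1). Fisher's one-sided test is the
hypergeometric tail in the stated direction; the response analysis fixes
the direction as "absence of assembled IGHG enriched among
non-responders". Chi-square enrichment is Pearson's statistic without
continuity correction, warning when any expected count is below 5. ANOVA
panels are one-way F tests with Benjamini–Hochberg q-values across the
measurement set. Spearman matrices use midranks on pairwise-complete
observations and report NA below 3 complete pairs.

**Measurement-panel clustering.** Samples lacking an assembled chain are
excluded from that chain's per-measurement analyses, but enter the
clustering panel through fixed imputation rules: a missing metric becomes
0 (no B-cell signal), missing evenness becomes 1 (the one-clone limit of
H/S is bounded by 1 and a missing repertoire is treated as maximally
even), and missing V-region identity becomes the measurement's median
(identity has no natural "absent" value). Each measurement is then scaled
to unit SD (ddof 1; zero-SD columns pass through) and median-centered, and
both axes are clustered by average-linkage Euclidean hierarchy; samples
are cut at K = 4 by default.

## Synthetic cohorts

The generator emulates the statistical structure of a melanoma-scale bulk
RNA-seq cohort; its defaults are the package's study conditions:

* clone proportions ~ symmetric Dirichlet(α = 0.3) over S ~ U{5…80}
  clones — moderately clonal repertoires whose rank-abundance curves drop
  below 1% within a few dozen ranks;
* per-sample total clone reads log-normal around a median of 8301 (the
  IGHG read-count scale of a real melanoma cohort) with σ_log = 1, library
  size 5 × 10⁷ reads, counts multinomial given proportions;
* sequences derived from a bundled panel of 3 synthetic germline V genes
  of length 300 nt (fixed internal seed; any IMGT FASTA can be supplied
  instead) with i.i.d. substitutions at μ = 0.04 per base —
  substitution-only by default so the identity oracle is exact; indels sit
  behind a flag. Clones that mutation cannot distinguish (e.g. μ = 0) are
  merged rather than duplicated;
* overall survival exponential with hazard h₀ exp(β z), h₀ = ln 2 / 2000
  days (median OS ≈ 5.5 years) and β = ln 1.38 on the cohort-standardized
  evenness — the planted per-SD hazard ratio; censoring is an independent
  exponential whose rate is solved (Brent) so the expected censored
  fraction meets the 50% target;
* responders (30%) lack an assembled IGHG with probability 0.1,
  non-responders with probability 0.5; absence removes the repertoire from
  the output but survival is generated from the pre-removal evenness, so
  missingness is non-informative for the survival analyses;
* expression: K = 3 classes shift 40 marker genes each by δ = 2 log2 units
  over N(0, 1) noise on a baseline of 8.

One child RNG stream per sample is spawned from the master seed, so
per-sample draws are stable under reordering or parallel generation.
Clinical covariates (age, sex, stage, site) are drawn independently of the
hazard; the covariate-adjusted hazard ratio therefore equals the marginal
one, which is what the recovery checks exploit.

What the generator does **not** emulate: clone lineage structure
(phylogenies, class-switching), shared clones across samples, indel or
assembly error profiles, depth-dependent assembly failure (absence is
driven by the response model, not by read depth), covariate-outcome
confounding, and cross-platform normalization artifacts in expression.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to assembler artifacts
or confounded cohorts.

## Verification set-up

The test suite checks closed-form metrics against independent fsum
evaluation on 1,000 random proportion vectors (1e-10), the identity oracle
at μ ∈ {0, 0.02, 0.1} (1e-9), Cox recovery over 100 cohorts of n = 500 at
a true per-SD HR of 1.4 (mean in [1.3, 1.5], 95% CI coverage in
[90%, 99%]), LRT null calibration over 200 cohorts of n = 150 (KS
uniformity p > 0.01), classifier error in the separable (δ/σ = 10 → 0) and
label-permuted (→ 1 − 1/K ± 0.1 over 20 seeds) regimes, Fisher and
Mann–Whitney against full enumeration, the imputation rules exactly, and
clonality monotonicity across α ∈ {0.01…100} with 50 paired draws per α
(one spawned RNG stream per draw index, so the richness draw is common
across α values — a variance-reduction pairing without which the α = 10 vs
α = 100 ordering sits inside Monte-Carlo noise). These replicate counts
and cohort sizes are the package's chosen verification conditions;
`scripts/acceptance.py` re-runs the same computations from scratch under a
user-supplied seed.

## Known limitations

* Clone identity is the exact assembled nucleotide sequence; CDR3-keyed
  clonotyping is supported only insofar as the input table already keys on
  CDR3.
* No rarefaction or richness estimators (Chao etc.); observed richness is
  depth-dependent, which is why abundance and diversity correlate.
* No IGHG1–4 subclass resolution, no BAM/FASTQ parsing, no assembly, no
  batch correction or cross-platform gene mapping for the classifiers.
* No proportional-hazards diagnostics or competing-risks models.
* The nearest-centroid gene-scoring rule is a faithful surrogate for the
  published nearest-centroid-with-gene-selection method, not a line-by-line
  reimplementation of it; likewise the linear classifier stands in for
  distance-weighted discrimination (both uses are as generic reference
  classifiers).
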