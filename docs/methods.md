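# Methods

This note records the models behind each `miredit` module, the defaults
and why they were chosen, and what the synthetic generators do and do
not emulate.

## Editing-site model

Reads aligned to pre-miRNA references (SAM-lite: forward strand, CIGAR
restricted to M/S) are piled up per sample.  For a position with
reference base R, every alternative base a with ≥ 1 supporting read is
a candidate M/E (mutation/editing) site.  Its editing level is

    level = edited_reads / total_reads

over the reads covering the position.  Significance is tested against
the sequencing-error null: with a Phred quality floor Q applied
upstream, the per-base error probability is `p_err = 10^(-Q/10)`
(10⁻³ at Q30), spread uniformly over the three alternative bases, so
the count of a *specific* alternative is Binomial(total, p_err/3)
under no editing.  The one-sided upper-tail probability is corrected
per sample across that sample's candidate sites with the
Benjamini–Hochberg step-up.  A site is significant in a sample when

* level ≥ `min_level` (default 0.05),
* edited_reads ≥ `min_edited_reads` (default 10),
* BH-adjusted p < `max_fdr` (default 0.05),

and the cohort site set is the union over samples of per-sample
significant sites.  Candidate pairs with zero supporting reads carry
p = 1 and are not enumerated; including them could only enlarge the BH
family and make the procedure more conservative.

Design choices worth stating explicitly:

* **Null model.** The binomial-vs-sequencing-error null is this
  package's choice of significance test; upstream callers in this
  field do not all document their internal test, and nothing else in
  the pipeline depends on the specific choice.
* **3' additions as substitutions.** A non-templated nucleotide at the
  3' end of a mature miRNA is recorded as a substitution at the first
  reference position past the templated end.  This keeps one naming
  scheme for internal edits and 3' additions (`hsa-mir-182_48_G_u` is
  the 3'-uridylation of the miR-182 5p arm; the edited miRNA
  `hsa-mir-182_48u` has sequence `UUUGGCAAUGGUAGAACUCACACUGu`).
* **Missing levels.** A union site uncovered in some sample has no
  defined level there; the caller reports NaN and the feature builder
  imputes 0 (logged) before filtering.  Zero-vs-missing is a genuine
  ambiguity of count data with variable coverage; imputing 0 treats
  "not observed" as "not edited", the conservative direction for
  editing-level features.
* **Coordinates** are 1-based inclusive on the pre-miRNA throughout,
  matching the site-naming convention.
* **Upstream contract.** Read QC (per-base quality, library size
  thresholds), genome alignment and cross-mapping correction happen
  before this package's inputs and are out of scope.

## Feature families and filters

Editing levels are stored ×100 (percent).  Filters keep a feature when
its within-class mean exceeds the threshold in *either* class,
strictly: EL features need a class mean > 10 percent, count features
(original and edited miRNA abundances) a class mean > 10 raw counts.
Strict inequality matters only at exact boundaries but is fixed for
reproducibility.  Group means are taken over all samples of the class
(after 0-imputation of missing levels).  Filters are computed on the
full cohort before the train/test split — the upstream study's
ordering — which leaks a small amount of label information; the README
flags this rather than reordering the pipeline.

The three analysis datasets are AOM-only, editing (AEM + EL) and
combined (AOM + AEM + EL); feature names cannot collide across
families because edited-miRNA and site names embed position and
alternative base.

## Batch correction and normalization

Counts from multi-study cohorts carry between-batch location shifts on
the log scale.  Correction operates on raw counts with the class label
as a preserved covariate, through one of two backends with identical
contracts (same shape, non-negative integers):

* `combat-seq`: adapter around `sva::ComBat_seq` (Bioconductor),
  invoked via `Rscript` on temporary TSVs;
* `fallback` (default): for each class and feature, every batch's mean
  log1p count is shifted to the class grand mean, then values are
  exponentiated back, rounded and floored at 0.  This removes additive
  log-scale batch offsets — the dominant artifact the simulator plants
  — but, unlike ComBat-seq, does not model batch-specific dispersion.

Editing levels are ratios, not counts; they bypass count correction
and are only quantile-normalized.

Quantile normalization maps every sample (column) onto the reference
distribution formed by row means of the column-sorted matrix; tied
values receive the mean of the reference values their ranks span (the
common dialect of the routine).  Consequence: columns share the exact
reference multiset only where they are tie-free.  Normalization is
applied per feature family (counts vs EL) so percent-scale features
are not mapped onto the count distribution — whether the original
analysis normalized jointly or per family is not documented, and the
per-family choice keeps EL features interpretable as percentages.

PCA diagnostics (top-3 components, full SVD) verify that batch
structure dominates before correction and class structure after.

## DFL: Discrete Function Learning

Let Y be the class attribute and X a subset of discretized features.
DFL searches for the smallest X with

    H(Y) − I(X;Y) < ε·H(Y)

using plug-in entropies in bits.  If Y is an exact function of X then
I(X;Y) = H(Y); ε ∈ [0,1) tolerates label noise.  The search proceeds
by cardinality (1, 2, …, K); within a cardinality, candidates extend
already-evaluated parents ranked by descending I(parent;Y) (ties by
feature index), each parent extended by features ranked by descending
single-feature information.  The first satisfying subset is returned;
this is exactly the minimal-cardinality subset under the stated order,
and on ≤ 12-feature instances agrees with exhaustive enumeration (an
oracle test).  If nothing satisfies the criterion, the best-scoring
subset of size K is returned flagged `converged=False`.

The classifier merges duplicate training vectors into a function table
mapping each distinct x to its majority class (ties to the smallest
label) with the majority count.  Prediction is exact lookup, else
Hamming-nearest entry; equidistant entries are resolved by largest
count, remaining ties by lexicographically smallest key.  The count
totals per key sum to the training-set size.

Defaults, all recorded in every run manifest since the underlying
method literature leaves them open:

| parameter | default | rationale |
|---|---|---|
| ε | 0.3 | tolerates ≈ H₂(0.05) bits of residual label noise for a binary class — about a 5% error floor |
| K (max cardinality) | 5 | small subsets are the method's point; K=5 exceeds the 3-feature solutions the approach typically yields |
| B (bins) | 3 | equal-frequency tertiles; robust to monotone transforms, enough resolution for two classes |
| beam cap | none (API) / 20000 per cardinality (pipeline/CLI) | exhaustive scans are kept for oracle comparisons; on matrices with thousands of columns the ordered search reaches informative subsets long before the cap, which only bounds the worst case |

Discretization is per-feature equal-frequency binning with edges
learned on training data only; test values clip into the end bins.
Constant features collapse to one bin with a warning.

Note on ε and downstream accuracy: by construction a subset accepted
at ε = 0.3 may leave ≈5% of training labels unexplained, so the
function table alone plateaus near 95% accuracy; classifiers trained
on the *selected features'* continuous values (kNN here) recover the
remaining margin.  Evaluations therefore report the selected-subset
classifier accuracy as the primary figure.

## Model lab

* **Split**: stratified by class; the train side receives
  round(0.8·n) samples with per-class largest-remainder allocation
  (within one sample of exact proportionality).  A 395-sample cohort
  yields exactly 316/79.  Optional class×batch stratification.
* **kNN** (k = 6 default): Euclidean, majority vote; vote ties resolve
  by smaller mean neighbour distance, then smaller label.  The ROC
  score is the positive-class vote fraction.
* **LOOCV**: n folds, one held-out sample each.
* **CFS**: symmetrical-uncertainty correlations on equal-frequency
  bins; merit `m·r̄_cf / sqrt(m + m(m−1)·r̄_ff)`; best-first search
  stops after 5 consecutive non-improving expansions (the common
  dialect), greedy-stepwise stops at the first non-improving step.
* **Wrapper**: same searches scored by stratified k-fold CV accuracy
  of any classifier honoring the fit/predict contract.  On pure-noise
  data forward search may chain one or two chance improvements before
  stalling; it returns a small, near-chance subset rather than exactly
  one feature.
* **ROC/AUC**: score-threshold staircase with simultaneous steps on
  ties; trapezoid AUC equals the Mann–Whitney statistic / (n₁n₀),
  verified against an O(n²) pairwise oracle.
* External classifiers (random forest, SVM, etc.) plug in via
  `sklearn_spec`; only kNN and DFL are in-house reference
  implementations because their tie rules are part of the method.

## Synthetic cohorts

`simulate_feature_cohort` emulates a multi-study bulk small-RNA
cohort: two classes of 198 samples each across 5 batches (the scale of
the 395-sample case/control design the package targets), feature
families sized like the filtered analysis matrices (422 AOM, 957 AEM,
1221 EL).  Counts are negative-binomial with

    mu[s,f] = mu_f · 2^(effect_f · 1[case]) · libsize_s · exp(shift[b(s),f])

with `mu_f` log-uniform on [20, 500], NB size 2 (strong
overdispersion, typical of bulk small-RNA counts), per-sample
library-size factors LogNormal(0, 0.3) and per-(batch, feature) shifts
N(0, 0.5) on the natural-log scale — enough to dominate PCA before
correction, as in real multi-study data.  Editing levels are
per-sample Beta draws (concentration 30) around per-feature means from
Beta(1.2, 6) (mostly low-edited sites); planted EL effects shift the
case-class mean additively.

`simulate_pileup_cohort` emits SAM-lite reads covering the mature
window of random pre-miRNA references, negative-binomial depth per
(sample, pre-miRNA), planted editing events applied per read with the
configured probability, then uniform per-base errors at 10⁻³ (the Q30
Phred floor), each error choosing among the three alternative bases
uniformly.  A planted 3'-addition extends affected reads one base past
the mature end.  All generators draw from one seeded RNG stream, so a
configuration plus seed reproduces outputs byte-identically.

What the generators deliberately do **not** model: read-quality
profiles (FASTQ), adapter/UMI artifacts, multi-mapping and
cross-mapping between paralogous pre-miRNAs, batch-specific dispersion
changes (only location shifts), coverage-dependent EL missingness
correlated with expression, and correlation structure among features.
Passing tests therefore demonstrate correctness of the algorithms
under a clean generative model, not performance on real sequencing
data.

EL cohort features are simulated directly as Beta variables rather
than derived from simulated pileups, so the cohort generator and the
editing caller stay independent; the pileup → caller path is exercised
end-to-end separately.

## Problem sizes in tests and the acceptance script

Cohort-level checks run at reduced scale chosen for tight feedback
loops while keeping every estimator in its working regime: 380-sample
cohorts with ~540 features for DFL recovery (20 seeds), 200-sample
cohorts for the combined-vs-AOM comparison (20 seeds), 100 pre-miRNAs
× 22-nt windows (≈2200 positions) for null-call control, and
coverage-1000 pileups over 50 samples for level recovery.  The
acceptance script reuses these designs at 10 seeds per quantity.

## Known limitations

* The fallback batch corrector aligns only log-scale means; residual
  dispersion differences between batches survive it.
* Plug-in mutual information is biased upward on small samples; with
  hundreds of candidate features, weakly informative noise can inflate
  subset scores.  The ε default absorbs part of this; the beam cap
  bounds the cost of the induced extra search.
* The function-table classifier discards within-bin margin
  information; accuracy on noisy cohorts is bounded accordingly (see
  the ε note above).
* Group-mean filtering before splitting mildly leaks labels, kept for
  fidelity to the emulated workflow.
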