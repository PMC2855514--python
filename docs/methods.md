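# Methods

This note records the models, conventions and numerical choices behind
`progsig`, the assumptions of its synthetic-cohort generator, and the
limits of what its tests demonstrate.

## Cohort model

A cohort couples a genes × samples log-intensity matrix with a
per-sample phenotype record: outcome ∈ {lethal, indolent, excluded},
death-from-cancer flag, follow-up years, age at diagnosis, Gleason
category grouped 4–6 / 7 / 8–10, and ERG rearrangement status
{rearranged, negative, unknown}.  Expression values are consumed as
already log-scale and normalized; the package performs no normalization
or batch correction.  Missing expression entries are explicit (NaN);
operations that cannot tolerate missingness (t-tests, distances) drop
genes with any missing value and log the count.  Numeric Gleason scores
map onto the three groups (e.g. "9" → G8_10); unparsable optional
phenotype fields become the explicit `unknown` level with a warning
count, while malformed mandatory fields are errors.

**Extreme-case definitions.** `apply_extreme_definition` reassigns
outcomes under configurable stringency: lethal iff death from cancer
(optionally within `lethal_within_years`); indolent iff alive without
progression for at least `indolent_beyond_years` (default 10); all else
— other-cause deaths inside the window, short follow-up, cancer deaths
past a stringent bound — excluded.

## Synthetic-cohort generator

The generator operationalizes the structure an extreme-design watchful-
waiting study assumes.  Defaults are the study-design shape: 165 lethal
+ 116 indolent samples, 6100 genes.

* **Baseline + noise.** Per-gene baseline means ~ N(8, 1.5²) drawn once
  per cohort; i.i.d. Gaussian noise (sd `noise_sd`, default 1) added per
  entry.  Additive Gaussian on the log scale is the simplest model
  matching log-intensity data; no gene–gene correlation is simulated
  beyond the block structure below.
* **Outcome signal and heterogeneity.** `n_signal_genes` (default 100)
  split into K = `n_lethal_subtypes` disjoint blocks; each lethal sample
  is assigned one subtype uniformly and its block is shifted by
  `effect_size_delta`.  Class-level signal therefore dilutes as 1/K —
  the cleanest operationalization of clonally distinct lethal subtypes.
* **ERG subgroup.** Per-class ERG+ probabilities are solved analytically
  (bracketed root of the monotone marginal equation) so that the
  population odds ratio of lethality for ERG+ vs ERG− equals
  `erg_target_odds_ratio` (default 7.2) at the configured overall ERG
  fraction (default 0.16); infeasible targets are rejected with the
  feasible range.  ERG+ samples carry an `erg_effect_size` shift on a
  disjoint ERG-signature block (default 87 genes).  Note the *estimated*
  cross-product odds ratio of a single cohort is upward-biased when the
  smallest expected cell is ~5 samples; the generator's targeting is
  exact in the probabilities, and checks against the target use the
  median of Haldane–Anscombe-corrected estimates across seeds.
* **Stroma contamination.** A fraction of samples (default 17/281)
  receives a fixed per-cohort stroma *profile*: per-gene offsets drawn
  once from N(shift, shift²) over `n_stroma_genes` (default 47).  A
  patterned profile, not a constant shift, is essential: Pearson
  correlation is invariant to adding a constant to one sample's values,
  so a uniform shift would be undetectable under the default correlation
  distance — and real stroma admixture is itself a patterned signature.
  The profile's positive mean keeps flagged clusters identifiable by
  elevated mean signature expression.
* **Clinical covariates.** Gleason drawn from P(gleason | outcome); the
  default table — lethal (0.20, 0.45, 0.35), indolent (0.52, 0.45, 0.03)
  over G4_6/G7/G8_10 — was chosen analytically so the population
  Cramér's V at the default class sizes is ≈0.45, a strong association
  of the kind such cohorts show.  Age ~ N(74, 6²) truncated to [50, 95]
  (placeholder values, recorded in config).  Lethal death times are
  lognormal with median 5 years (log-sd 0.6); indolent follow-up uniform
  on [10, 25] years — only their ordering relative to the definition
  thresholds matters.
* **Determinism.** One master seed feeds named substreams (expression /
  phenotype / structure) via `SeedSequence.spawn`; identical config +
  seed gives a bit-identical cohort.

What the generator does **not** emulate: probe-level assay chemistry,
realistic gene–gene correlation, spatial tumor geometry, overlapping
subtype gene programs, measurement batch effects.  Tests passing on
these cohorts show the *pipeline* behaves correctly under the stated
statistical structure; they do not certify performance on real tumors.

## Evaluation protocol

* **Split.** Stratified Learning/Validation split; per-class Learning
  counts are round(fraction × class size).  The split fraction defaults
  to 0.5 and is configurable (no canonical value exists for it).
* **Folds.** Per repetition, each class is shuffled and dealt round-robin
  (with a class offset) to k folds, so test-fold class counts are within
  ±1 of proportionality and folds partition the Learning set.  Default
  10 folds × 100 repetitions; the acceptance-scale runs in this
  repository use 1–20 repetitions, sized so the whole suite stays
  comfortably testable on one CPU, and report the sizes used.
* **In-fold selection.** Threshold mode keeps genes with pooled-variance
  two-sided t-test p below 0.01 (or 0.001); stepwise mode sorts genes by
  p, scores prefixes by 5-fold inner CV (DLDA) on the training slice
  only, and returns the smallest prefix attaining the maximal inner AUC.
  The selection function receives only training identifiers — the
  leakage contract is structural, and a poisoning test (outcome-revealing
  constants written into held-out samples) verifies selection output is
  unchanged.
* **Pooled vs Welch.** The default per-gene test is the classic
  pooled-variance two-sample t (the era-typical microarray choice);
  Welch is a flag.
* **AUC.** Mann–Whitney form via midranks: (concordant pairs + half
  ties)/(n₁n₀); undefined with one class absent.
* **Aggregation and model choice.** Fold AUCs average per repetition,
  then across repetitions (grand mean).  The best model maximizes the
  grand mean; ties break toward fewer mean selected genes, then a fixed
  family order (dlda, logistic, ntp, knn, plugin).  Single-fold failures
  are recorded and skipped — thousand-partition runs must not abort on a
  degenerate fold.
* **Final validation.** Features reselected and the model refit on the
  full Learning set; validation AUC reported with (a) a stratified
  bootstrap percentile CI (default 2000 resamples) over validation
  samples and (b) the percentile interval of the repetition-level CV AUC
  distribution, both labeled.
* **Null calibration.** The null distribution of a *single* permuted
  cohort's CV grand mean scatters with sd ≈ 0.06: the permuted label
  vector's chance alignment with the data is common to every partition,
  so extra repetitions do not shrink it.  Calibration checks therefore
  average over label permutations (20 permutations × 10 folds), where
  the honest protocol centers on 0.5 within ±0.03 for every family while
  whole-set selection inflates the same quantity by ≈0.3–0.45.

## Classifiers

All families emit a continuous score oriented larger-is-lethal, and all
standardization statistics are computed on training data only and frozen
into the model.

* **DLDA**: per-class per-gene means, pooled per-gene variance
  (zero-variance genes dropped with a warning);
  score(x) = Σ_g [(x_g−μ_g,ind)² − (x_g−μ_g,leth)²]/s_g².
* **kNN**: Euclidean distance to memorized exemplars; score = lethal
  fraction among the k nearest (k odd, enforced); distance ties break
  toward the smaller training index via a stable sort.
* **NTP**: signed ±1 templates over the marker genes (sign of the
  training lethal-minus-indolent mean difference; zero differences
  default to +1), samples standardized per gene with training mean/sd,
  cosine distance to each template; score = d_indolent − d_lethal.  The
  original permutation-based confidence is omitted — only the ranking
  score feeds AUC here.
* **Logistic regression**: penalized maximum likelihood by IRLS
  (tolerance 1e−8 on the step, max 100 iterations); the intercept is
  never penalized; default ridge 1e−4.  Non-convergence at penalty 0
  (typically separation) is reported and the model refit with the
  default ridge, flagged in the parameter block.  Clinical encodings:
  age linear; Gleason and ERG as reference-coded indicators with
  references G4_6 and negative; unknown levels sit at the reference.
* **Plug-ins**: any external learner (SVM, neural network, …)
  participates through a train/score contract; no hyperparameter grids
  are shipped for them.

Trained models (except plug-ins) serialize to a versioned plain-text
format sufficient to reproduce scores exactly.

## Homogeneity analysis

* **Distances**: `one_minus_pearson` (default; the expression-profile
  standard) or Euclidean over a gene subset.  A zero-variance sample is
  an error under the correlation metric.  Note the correlation metric is
  blind to any constant offset of a sample's profile — a uniform
  class-wide shift separates classes under Euclidean but not correlation
  distance; both metrics are exposed and logged for this reason.
* **Silhouette widths**: s(i) = (b−a)/max(a,b) with self-excluded
  within-group mean a(i); singleton-group samples score 0 by convention;
  per-group plain means; structure bands >0.70 strong, (0.50, 0.70]
  reasonable, (0.25, 0.50] weak, ≤0.25 none (the classical silhouette
  interpretation convention).
* **Overfit signature**: per-gene pooled t-tests on *all* samples of
  both classes, Storey q-values, genes with q < 0.05 sorted by p.  This
  is intentionally biased toward the best class description and must
  never feed an unbiased performance claim.
* **Stroma flagging**: average-linkage hierarchical clustering on the
  signature-gene distance matrix, cut at 2 clusters; the cluster with
  higher mean signature expression is flagged.  The mean silhouette of
  the 2-cut is reported; below 0.25 the split is marked weak and the
  flags untrustworthy (a forced 2-cut always produces clusters, even on
  unstructured data).
* **Cross-dataset use**: any expression matrix + two-group labels +
  signature list runs through the same three operations; per-dataset
  gene-selection recipes are configuration, not code.

## Statistics

* **q-values**: Benjamini–Hochberg step-up, or Storey's procedure with
  π₀ estimated on the λ-grid 0.05…0.90 (step 0.05) smoothed by a cubic
  spline and read at the largest λ, clipped to [1/m, 1].  Families
  smaller than 100 tests always use π₀ = 1 — the estimate is too noisy
  to help there.
* **Fisher's exact test**: 2×2 exact (two-sided: total hypergeometric
  probability of tables no more likely than observed, with a 1e−9
  relative slack for floating-point ties); r×c by seeded Monte-Carlo
  over fixed-margin tables (≥1000 draws enforced, add-one p estimate,
  standard error reported).
* **Odds ratio**: cross-product with Woolf log-interval; zero cells get
  the 0.5 continuity correction with a warning; a zero margin is an
  error.
* **Cramér's V**: Pearson χ² without continuity correction; zero-margin
  rows/columns dropped with a warning.

## Known limitations

* The Gleason/age/survival distributions are plausible placeholders, not
  estimates from any cohort.
* Storey's π₀ spline uses a fixed λ-grid; very sparse or very dense
  alternative distributions may prefer other grids.
* The r×c exact test is Monte-Carlo, not network-algorithm enumeration;
  its p-values carry the reported standard error.
* Stepwise selection scores candidate prefixes with DLDA inner CV
  regardless of the outer family; this mirrors its role as a gene-count
  selector rather than a per-family optimizer.
* The GEO importer parses the series-matrix text dialect and maps
  characteristics by a configurable key table; deposited records vary,
  so the default mapping should be checked against a live record before
  real-data runs.
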