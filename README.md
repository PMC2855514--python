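# progsig

Expression-based outcome classification and molecular-homogeneity
analysis for extreme-design tumor cohorts.

## The problem

Watchful-waiting prostate cancer cohorts pose a sharp prognostic
question: at the time of diagnosis, can a tumor's gene-expression
profile tell the man who will die of his cancer from the man who will
live with it untreated for decades?  Studies of this design contrast two
*extreme* outcome classes — **lethal** (death from cancer during
follow-up) and **indolent** (≥10 years of survival without progression)
— profile a few thousand genes per tumor, and ask two things of the
data:

1. **Classification.** How well do gene-expression classifiers, clinical
   covariates (grouped Gleason score, age, ERG rearrangement status), or
   combinations of the two rank lethal above indolent cases — when the
   evaluation is kept scrupulously honest?
2. **Homogeneity.** If molecular classifiers disappoint, is it because
   each outcome class is molecularly heterogeneous — lethal tumors
   scattered across many expression subtypes rather than sharing one
   signature?

`progsig` implements both analyses as a tested, reusable library, plus a
seeded synthetic-cohort generator that reproduces the statistical
structure such studies assume (a minority of outcome-associated genes,
latent lethal subtypes, an ERG-rearranged subgroup enriched for
lethality, stroma-contaminated samples, clinical covariates with tunable
association to outcome), so every stage can be exercised and validated
without any data download.

## The methods at its core

**Honest evaluation protocol.** The cohort is split once into stratified
Learning and Validation halves.  Within the Learning set, stratified
k-fold cross-validation is repeated R times (default 10 folds × 100
repetitions = 1000 partitions).  In *every* training fold, genes are
re-selected by per-gene two-sided t-tests (threshold p < 0.01 or 0.001,
or a stepwise rule that keeps the smallest gene set achieving the best
inner-CV AUC); the held-out fold never influences selection.  Models are
compared by the grand-mean AUC over repetitions,

AUC = P(score(lethal) > score(indolent)) (Mann–Whitney form, ties count ½),

the best model is refit on the full Learning set and scored once on the
Validation set, with bootstrap and CV-distribution confidence intervals.
A deliberately *leaky* mode (selection once on the whole Learning set)
is included so the selection bias the protocol avoids can be measured.

**Classifier families** (all produce a continuous lethality score;
larger = more lethal): diagonal linear discriminant analysis (DLDA),
score(x) = Σ_g [(x_g−μ_g,ind)² − (x_g−μ_g,leth)²] / s_g²; k-nearest
neighbor; nearest-template prediction (cosine distance to signed ±1
marker templates); ridge-penalized logistic regression mixing genes with
reference-coded clinical covariates.  SVMs, neural networks or any other
learner plug in through a train/score contract.

**Homogeneity score.** For sample *i* with mean distance *a(i)* to its
own outcome class and *b(i)* to the other class, the silhouette width

s(i) = (b(i) − a(i)) / max(a(i), b(i)) ∈ [−1, 1]

is averaged per class and banded (>0.70 strong, 0.51–0.70 reasonable,
0.26–0.50 weak, ≤0.25 none).  Class descriptors are chosen by
*deliberately overfitting* the full cohort (per-gene t-tests, Storey
q < 0.05) — the most favorable possible description of the two classes,
so a low homogeneity score is a statement about the biology, not the
gene list.

**Association statistics.** Cramér's V and Fisher's exact test for the
Gleason × outcome table; odds ratio with Woolf CI and exact Fisher p for
ERG × outcome; Storey/BH q-values for gene-test families.

## Worked example

`python examples/classify_outcomes.py` — a 2000-gene cohort with a
20-gene planted signal (half a standard deviation shift), evaluated with
5 × 10-fold in-fold-selection CV:

```
cross-validated grand-mean AUC per model (Learning set):
  dlda         0.857 (sd 0.016, ~34 genes/fold)
  knn5         0.786 (sd 0.033, ~34 genes/fold)
  lr_clinical  0.627 (sd 0.020, ~0 genes/fold)

best model: dlda
validation AUC 0.816 (bootstrap 95% CI 0.735-0.882, 34 genes)
```

The grand means compare model families on identical partitions; the
validation AUC is the unbiased estimate for the chosen model on samples
no stage of training or selection ever saw.

`python examples/selection_bias_demo.py` shows why in-fold selection is
non-negotiable — on outcome-permuted data with *no* signal:

```
honest in-fold selection:   grand-mean AUC 0.436
leaky whole-set selection:  grand-mean AUC 0.820
optimism from leakage:      +0.384
```

`python examples/homogeneity_analysis.py` contrasts a uniform lethal
class (K=1) with one hiding four latent subtypes (K=4):

```
K=4 lethal subtype(s), 44-gene overfit signature:
  lethal    average homogeneity -0.125 (none structure)
  indolent  average homogeneity +0.165 (none structure)
```

A lethal average below zero means lethal tumors sit closer to indolent
profiles than to each other — the heterogeneity signature that defeats
single-signature classifiers.

The other examples cover cohort simulation (`simulate_cohort.py`),
clinical association tables (`clinical_associations.py`) and
stroma-contamination screening (`stroma_screening.py`).

## Command line

A thin CLI wraps the library for seeded end-to-end runs; each subcommand
writes its outputs plus a manifest (config echo, seeds, version,
timings) for bit-identical re-runs:

```bash
progsig simulate   --seed 1 --out runs/cohort
progsig evaluate   --expression runs/cohort/expression.tsv \
                   --phenotype runs/cohort/phenotype.tsv --seed 1 --out runs/eval
progsig homogeneity --expression ... --phenotype ... --out runs/homog
progsig associate  --phenotype ... --out runs/assoc
progsig geo-import --series-matrix series_matrix.txt --out runs/geo
```

`geo-import` reads the GEO series-matrix text dialect (optionally
gzipped), mapping sample characteristics onto phenotype fields through
an editable key mapping.

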