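# Methods

This note records the statistical model behind `prognae`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## Model and procedure

The pipeline treats subtype discovery as unsupervised structure-finding
in a survival-screened, autoencoder-compressed multi-omics space,
followed by supervised transfer of the discovered labels.

**Survival screening.** Features enter integration only if a univariate
Cox proportional-hazards model relates them to event-free (EFS) or
overall survival (OS) at p < 0.05. The p-value is the score test at
β = 0, which needs no iteration and, for a dichotomous covariate with
untied event times, coincides exactly with the Mantel–Haenszel log-rank
chi-square. The full fit (Newton–Raphson on the Breslow partial
likelihood, tolerance 1e-8, 50 iterations max) is used where the
coefficient itself is needed. Breslow tie handling is used throughout;
monotone likelihoods cap the coefficient at |β| = 20 with a warning.
No multiplicity correction is applied at this stage — screening is a
filter, not an inference; Benjamini–Hochberg FDR is applied only in the
differential-expression stage. Selection across the two endpoints is a
union (EFS *or* OS), so the expected null pass rate exceeds the nominal
α when the endpoints are independent and approaches α as they become
concordant.

**Autoencoder.** A fully connected d–500–100–500–d network, tanh on the
hidden layers. The reconstruction layer is **linear** by default:
inputs are z-scores and a tanh output cannot reconstruct |z| > 1; a
`tanh` output remains available as a configuration option. The loss is
the Pseudo-Huber function summed over input dimensions and averaged
over the minibatch — quadratic in small residuals, linear in large
ones, with scale δ = 1 (exposed in the config; the choice only sets the
crossover point between the two regimes, and z-scored inputs make 1 a
natural unit). L1 = 1e-4 and L2 = 1e-3 penalties apply to weights only,
not biases (the usual convention); the L1 subgradient at 0 is taken as
0. Initialisation is Glorot-uniform from a seeded generator; minibatch
order is drawn from a second stream derived from the same seed, so the
whole train→encode path is bit-reproducible.

Two training profiles exist. The `default` profile (10 epochs, batch 32,
learning rate 1e-6) reflects the historical configuration this design
derives from; at that step size Glorot-scale weights barely move, so
the bottleneck is essentially a random projection — informative (random
projections preserve separation) but not trained. The `adequate`
profile (learning rate 1e-3, 200 epochs, otherwise identical) actually
descends the loss and is the default for synthetic-recovery
experiments; the loss-decrease, factor-recovery and end-to-end tests
use it.

**Latent selection.** Each of the 100 bottleneck features is
dichotomised at its median and tested by two-group log-rank against
both endpoints (p < 0.05 for either selects it). A continuous Cox
score-test variant is provided (`method="cox"`); median dichotomisation
is the default because the downstream K-means step also treats the
latent space geometrically, and the split makes the test invariant to
monotone transforms of a latent feature. Constant features, or features
whose median split empties a group, are excluded with a warning.

**Cluster number and orientation.** For each k in 2..6 (K-means,
k-means++ seeding, best of 50 restarts by within-cluster sum of
squares), three criteria are computed: Harrell's C-index of the
cluster-derived risk ranking against EFS (and OS, reported), the mean
silhouette width, and the Calinski–Harabasz score. The chosen k is the
majority winner; when all three disagree the C-index criterion decides.
For k > 2 the risk ranking orders clusters by restricted-mean EFS
(worst cluster = highest risk); at k = 2 this reduces to coding
G1 = 1, G2 = 0. Orientation also uses restricted-mean survival (area
under the Kaplan–Meier curve up to the last observed time) rather than
the raw event rate, which is confounded by follow-up length; exact ties
fall back deterministically to the first cluster with a warning.

**Label transfer.** Linear-kernel SVM (C = 1), Gaussian naive Bayes and
logistic regression select features by ANOVA-F backward elimination:
starting from the top-100 F-ranked features, the lowest-ranked feature
is dropped one at a time and mean accuracy over 10-repeat stratified
10-fold CV is recorded at each size; the highest mean accuracy wins,
ties preferring fewer features. Stratified folds are used because at
n ≈ 190 plain folds can lose a class. XGBoost (100 rounds, depth 3,
learning rate 0.1) skips elimination; its selected features are those
with nonzero split importance, and the final model is refit on exactly
that set so the persisted estimator and feature list agree. Per omics
layer the candidate with the highest mean cross-validated AUC becomes
the transfer model (ties: higher CV accuracy, then the simpler
algorithm). Both layers are z-scored per gene before supervised
modelling so transfer is robust to scale differences between cohorts.
Transfer refuses to predict when any model feature is missing from the
cohort (the diagnostic reports coverage when it falls below 90%).

**Downstream.** Differential expression uses the equal-variance Student
t-test (two-sided) per gene with BH FDR at 0.05; genes with zero pooled
variance get p = 1 and a flag. Cross-cohort intersection requires
significance in both tables *and* the same direction. Overrepresentation
is the exact hypergeometric upper tail P(X ≥ overlap) with the gene set
intersected with the universe first; the default universe is the set of
genes tested for differential expression.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study *topology*: a training cohort with
paired layers (default n = 190), a CNA-only internal cohort (n = 190),
an expression-only external cohort (n = 176), two subtypes at 50%
prevalence, and right-censoring. Defaults: 2000 expression genes, 500
CNA genes (a subset of the same namespace, with half of the informative
CNA genes also informative in expression so cross-layer structure
exists), 5% informative features, a 3-SD mean shift in expression
(1.5 SD in CNA — the weaker copy-number signal mirrors the empirical
pattern that expression classifies better than copy number), an EFS/OS
hazard ratio of 4 for G1, exponential event times with a 1500-day
baseline median, and an independent exponential censoring time whose
rate is solved (Brent's method) so the expected censored fraction is
0.30 across the subtype mixture.

Deliberately **not** emulated: gene–gene covariance, chromosomal
arm-level events, segment length distributions (the SEG writer emits
one segment per gene, constructed so the gene-level reconstruction is
exact), correlated EFS/OS within patient (endpoints are drawn
independently given the subtype), non-proportional hazards, cohort
batch effects, and any specific oncogene biology. Passing the
end-to-end tests therefore demonstrates that the machinery recovers
planted low-dimensional structure with realistic sample sizes and
censoring — not that it would recover biology from any particular real
cohort.

## Numerical conventions

- Z-scoring uses the population SD (n denominator); constant rows
  become all-zero with a warning, and the choice is recorded in the
  matrix metadata.
- FPKM flooring computes both bounds from the data: L = min over
  samples of the per-sample smallest nonzero value, U = the max of
  those minima; values below U are set to L before log2.
- Harrell's C counts a pair as comparable iff the member with the
  smaller time has an event; tied risk scores earn 0.5; the reported
  standard error is the Noether approximation √(C(1−C)/N_pairs).
- SEG coordinates are 1-based inclusive; BED input is 0-based
  half-open and converted on read. Segment means are assumed to be on
  the log2(CN) − 1 scale unless `scale="absolute"` is given.
- Genes with no overlapping segment in a sample get 0 (diploid) rather
  than missing.
- Stage seeds are derived from the run seed by SHA-256 of
  `"{seed}:{stage}"` reduced mod 2³¹, so stages can be re-run in
  isolation and a manifest of artifact SHA-256 hashes makes runs
  byte-reproducible.

## Problem sizes used in automated checks

Replicated experiments use the default study scenario unscaled
(n = 190/190/176, 2000 + 500 genes). Replicate counts and the
supervised-model sweep are sized for a single-CPU workstation: 20
replicates for end-to-end recovery (10 in the acceptance script), the
expression SVM with a 50-feature elimination pool and 2 CV repeats, and
only the two transfer models (expression SVM, CNA XGBoost) rather than
all four candidates per layer. Library defaults remain the full
configuration (pool 100, 10×10 CV, four algorithms per layer).
Calibration checks use 1000 null log-rank simulations, 2000 null
screening features, 20 planted-DE replicates, and 200 Cox-recovery
replicates at n = 500.

## Known limitations

- The Cox implementation is univariate only (by design — it is a
  screening and validation primitive, not a modelling tool); no
  proportionality diagnostics are provided.
- The log-rank/score-test equivalence is exact only for untied event
  times; with heavy ties the hypergeometric variance and the Breslow
  information differ slightly.
- K-means with Euclidean geometry is sensitive to the scale of the
  latent features; the autoencoder's tanh bottleneck bounds them, which
  is part of why the latent space clusters well.
- `select_k`'s C-index criterion evaluates cluster-risk orderings on
  the same data used to form the clusters, so it is optimistically
  biased and tends to favour larger k; the majority vote with the two
  internal-geometry criteria compensates.
- With a single global censoring distribution, heavier censoring in the
  high-risk subtype than calibrated is not modelled.
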