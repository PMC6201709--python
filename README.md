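# prognae

Autoencoder-based multi-omics integration for prognostic subtyping of
high-risk tumour cohorts, with cross-cohort label transfer.

## The problem

High-risk neuroblastoma (and aggressive cancers generally) is clinically
heterogeneous: patients assigned to the same risk group can have very
different outcomes. Given a training cohort with paired gene-expression
and copy-number data plus survival endpoints, `prognae` discovers a
two-group prognostic stratification — an ultra-high-risk subtype **G1**
and a better-prognosis subtype **G2** — and transfers it to cohorts that
carry only one omics layer. It is a library for computational biologists
working with bulk expression matrices (microarray RMA or RNA-seq FPKM),
SEG-format segmented copy number, and right-censored survival tables.

## The method

1. **Normalisation.** Expression is z-scored per gene (FPKM input is
   first floored at the largest per-sample nonzero minimum and log2
   transformed). Copy number is summarised per gene as the
   overlap-length-weighted mean of segment means on the
   log2(CN) − 1 scale (0 = diploid).
2. **Survival screening.** Each feature is tested with a univariate Cox
   proportional-hazards score test against event-free survival (EFS) and
   overall survival (OS); features with *p* < 0.05 for either endpoint
   are kept, and the two screened layers are stacked.
3. **Integration.** A fully-connected autoencoder d–500–100–500–d with
   tanh hidden units is trained by minibatch gradient descent on the
   Pseudo-Huber reconstruction loss

   L(x, x′) = Σₖ δ² (√(1 + ((xₖ − x′ₖ)/δ)²) − 1),   δ = 1,

   with L1 (10⁻⁴) and L2 (10⁻³) weight penalties. The 100 bottleneck
   activations become integrated features; those associated with
   survival (median-split log-rank *p* < 0.05 for EFS or OS) are kept.
4. **Subtyping.** K-means clusters the selected latent features; the
   number of clusters is chosen over k = 2..6 by majority vote of
   Harrell's C-index (cluster-risk vs EFS), mean silhouette width, and
   the Calinski–Harabasz criterion. For k = 2 the cluster with the lower
   restricted-mean EFS is labelled G1.
5. **Label transfer.** Per-layer classifiers (linear SVM, Gaussian naive
   Bayes, logistic regression with ANOVA-F backward elimination under
   repeated stratified 10-fold CV; XGBoost with internal selection) are
   trained on the discovered labels; the best model by cross-validated
   AUC predicts subtypes in single-layer cohorts, validated by log-rank
   test and C-index.
6. **Characterisation.** Per-gene Student t-tests with Benjamini–
   Hochberg FDR, direction-consistent intersection across cohorts, and
   exact hypergeometric overrepresentation against GMT gene sets.

A synthetic-data module generates the full study topology (paired
training cohort, CNA-only internal and expression-only external
validation cohorts, planted subtypes with divergent exponential
survival), so the whole pipeline is testable without external downloads.

## Worked example

`examples/` contains one script per capability. Discovering and
validating subtypes on a synthetic study (`examples/03_autoencoder_subtypes.py`
and `examples/04_label_transfer.py`):

```
$ python examples/03_autoencoder_subtypes.py
k-selection metrics:
   c_index_efs  c_index_os  silhouette  calinski_harabasz
k
2        0.689       0.654       0.190             50.238
3        0.725       0.637       0.116             27.948
...
chosen k = 2

G1 size 92, G2 size 98
G1 vs G2 log-rank (EFS): chi2 = 69.4, p = 8.17e-17
agreement with planted subtypes: 1.000

$ python examples/04_label_transfer.py
expression -> external cohort: accuracy vs truth = 1.000, log-rank p = 7.72e-11
copy number -> internal cohort: accuracy vs truth = 1.000, log-rank p = 2.55e-12
```

Silhouette and Calinski–Harabasz both peak at k = 2, so two subtypes are
retained; the G1/G2 split separates survival (log-rank p ≈ 8 × 10⁻¹⁷)
and matches the planted subtypes exactly, and both transferred
stratifications remain strongly prognostic in cohorts the model never
saw.

The same flow is available from the shell:

```bash
prognae simulate --seed 3 --outdir sim/
prognae pipeline --config run.yaml --outdir run/   # full flow + manifest
prognae validate --kind seg sim/train_cna.seg
```

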