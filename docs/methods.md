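# Methods

## The separability score

For a gene with values a₁…aₙ over classes C₁…C_c, the score is

    d = min_j ( max_{k ∈ C_j} |a_k − mean(C_j)| ),

the minimum over classes of the maximum within-class absolute deviation.
It is computed per gene, independently of every other gene and of any
classifier — a pure filter statistic.  Useful identities: d ≥ 0;
d(αx) = |α|·d(x); adding a constant to all samples of one class leaves d
unchanged; any gene constant within every class has d = 0 (to within the
1-ulp rounding of a floating-point mean); permuting samples together with
their labels leaves d unchanged.  The vectorized implementation reduces
along the contiguous axis per class so its summation order matches a
naive per-column mean exactly, and the test suite holds it equal to an
independently written triple-loop implementation on hundreds of random
instances.

**What descending order measures.**  d is large when *every* class shows
large internal spread on the gene.  On raw intensity data where
discriminative genes have both shifted class means and larger within-class
variance than background probes, descending order ranks them first.  On
*unit-variance* (z-scored) data, every gene's total dispersion is 1 by
construction, so d then measures how much of that dispersion lies within
classes: informative genes (variance concentrated *between* classes) get
the *smallest* d.  Consequently:

- the pipeline scores genes on the raw training submatrix by default and
  applies z-scoring only to the selected panel before classification;
- `select_on_standardized=True` restores scoring-after-standardization
  for fidelity experiments, in which case the `ascending` direction is
  the informative one.

This interaction is easy to miss and was the single most consequential
design decision in the package; the default keeps the literal descending
rule effective on the data layout the generator (and raw microarray
intensities) present.

## Preprocessing

Per-gene z-scoring to mean 0, sd 1 (population convention, n in the
denominator; `sample` available).  Zero-variance genes map to all-zeros.
Scaling parameters are fit on training rows only and reused on test rows
(leakage-free default); `fit_on_training_only=False` fits on the full
matrix for fidelity runs.  An `abs_transform` flag takes |z| after
scoring; it is off by default because the only absolute value the method
itself needs is the |a_k − m_j| step inside the score, and applying |·|
to the data before computing class means would destroy the sign structure
those means depend on.  No quantile normalization, log transform or batch
correction is attempted.

## Selection and splitting

Default panel size k = 25, descending order, ties broken by ascending
gene index (stable, reproducible).  Selection is computed from training
rows only, so held-out rows never influence the panel; 60/40 stratified
splitting (per-class train counts within one sample of 0.6 × count) and
stratified k-fold (default 5) both derive from one global seed through
fixed per-stage offsets, so changing one stage's randomness never
perturbs another's.

## Classifiers

All five families satisfy one fit/predict contract; pipeline code never
branches on kind.  Defaults, all overridable:

| kind            | realization                           | defaults |
|-----------------|---------------------------------------|----------|
| `random_forest` | scikit-learn ensemble                  | 100 trees |
| `decision_tree` | scikit-learn CART                      | Gini criterion |
| `linear_onehot` | from scratch (this package)            | least-squares variant |
| `svm_pca`       | PCA → RBF SVC, one-vs-rest             | 95% variance, C = 1 |
| `lstm`          | from scratch, NumPy                    | hidden 64, 100 epochs, Adam 1e-3, batch 8 |

`linear_onehot` regresses the one-hot label matrix on the features by
ordinary least squares (intercept included, `numpy.linalg.lstsq`) and
predicts argmax_c xβ_c + β₀,c, ties to the lowest class code.  A
logistic-regression variant is available under
`hyperparameters={"variant": "logistic"}` for users who want a
calibrated linear classifier.  Known, documented behaviour: when three
or more class means are (near-)collinear — exactly the geometry the
synthetic generator uses — indicator regression suffers *masking* and
middle classes are never predicted, capping accuracy far below the other
families.  This is a property of the method, reproduced faithfully.

The LSTM is implemented directly in NumPy (no deep-learning framework is
a dependency): one recurrent layer with fused gate weights, softmax head,
cross-entropy loss, full backpropagation through time, Adam, gradient
clipping at global norm 5, Glorot input / orthogonal recurrent
initialisation with forget-gate bias 1.  The analytic gradient is held to
central finite differences in the tests.  Tabular vectors are fed as
sequences of length p with one input unit per timestep (the recurrence is
then non-degenerate); `sequence_mode="single_step"` feeds the whole
vector in one timestep instead.  Training is deterministic per seed.

PCA keeps the minimal number of components reaching the configured
explained-variance fraction; fraction 1.0 keeps the complete
min(n − 1, p) basis.  The projection is fit on training rows and reused
unchanged on test rows.  Multiclass SVM uses an explicit one-vs-rest
wrapper.  Class imbalance is left unweighted by default (matching the
study design this mirrors); the tree, forest and SVM kinds accept a
`class_weight` hyperparameter (e.g. `"balanced"`) for users who want
reweighting.

## Evaluation

Confusion matrix with rows = true, columns = predicted.  Per class,
TP/FP/FN/TN are read off the matrix; precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), specificity = TN/(TN+FP);
zero-denominator cases are defined as 0.  Aggregation is weighted by
class support by default (macro and micro available); for single-label
multiclass data, micro precision = micro recall = accuracy, an identity
the tests use as a cross-check, alongside agreement with scikit-learn's
metric functions.  Specificity is reported separately because some
published tables print the specificity formula under the heading
"precision"; reports carry a footnote naming which formula each field
uses.  Reports serialize to canonical JSON (sorted keys), and identical
resolved configurations produce byte-identical reports.

## The synthetic generator

Defaults: 5 classes sized 8/10/26/10/10 (n = 64), p = 2000 genes, 20
planted informative genes, background N(0, 0.1²), informative gene in
class j distributed N(j·Δ, 1²) with Δ = 5 intensity units.  The class
sizes mirror the motivating leukemia study; p = 2000 keeps the whole
suite fast while preserving p ≫ n (a full-scale 22 283-gene matrix is one
flag away).  Class means sit on the monotone ladder j·Δ so failures are
interpretable; the cost of that choice is the collinearity that exposes
`linear_onehot` masking, which we judged more instructive than a
random-directions design that would hide it.  Informative genes get
within-class sd 10× the background so that both selection (dispersion
ranking) and classification (mean shifts) have signal.

Not modelled: probe-level intensity distributions, gene–gene correlation,
batch effects, heavy tails, missingness.  Tests passing on this generator
demonstrate the pipeline's mechanics — recovery, leakage-freedom,
determinism, metric correctness — not performance on any real accession.

## Numerical and degenerate-input choices

- Standardization tolerance 1e-10 for idempotence; zero-variance → zeros.
- Loader rejects missing/non-numeric cells naming sample and gene; mean
  imputation is opt-in.  Values parse through NumPy's string conversion,
  which round-trips doubles exactly; writers print %.17g.
- Selection requires ≥ 2 classes, every class non-empty; k ≥ 1; k > m
  truncates to m.
- Stratified splitting refuses singleton classes by name; k-fold refuses
  classes smaller than the fold count.
- LSTM raises on non-finite loss rather than continuing silently.

## Problem sizes used in checks

Recovery and paired-comparison experiments run 20 seeded replicates of
the 64 × 2000 default; oracle-equivalence checks use 200 random instances
with n ≤ 20, m ≤ 50, c ≤ 4; the LSTM gradient check uses a hidden size of
3 over 5 timesteps.  These sizes make every property cheap to recompute
while keeping the p ≫ n geometry of the motivating data.

## Known limitations

- The descending/raw-data coupling above means the selector's ranking is
  scale-sensitive by design; users who pre-normalize their matrices
  should select with `direction="ascending"` or skip standardization
  before selection.
- The one-hot linear classifier inherits indicator-regression masking.
- The LSTM treats an arbitrary gene ordering as a sequence; the ordering
  carries no biology, and the model's strength here is capacity, not
  temporal structure.
- No ROC/AUC, significance testing between models, or batch-effect
  handling.
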