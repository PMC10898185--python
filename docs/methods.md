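# Methods

## Problem and data model

The package estimates sex (binary), age group (four classes) and continuous
age (years) from twelve CBCT-derived sinus measurements per subject: length,
width, height and volume of the frontal sinus and of the right and left
maxillary sinuses.  The canonical feature order is

    FSL FSW FSH FSV | RMSL RMSW RMSH RMSV | LMSL LMSW LMSH LMSV

and is fixed package-wide because the feature-selection chromosome indexes
into it.  All measurements must be strictly positive; sex is F/M; ages are
years with a cohort floor of 18.  Age groups are A [18, 25], B [26, 33],
C [34, 41], D [42, 50].  The printed bins are closed integer intervals; on
real-valued ages each bin extends to the next bin's lower bound so the
mapping is total and monotone.  Ages above 50 are clamped into group D with
a warning rather than rejected, since cohorts of this kind include subjects
up to ~52 years.

## Preprocessing

**SMOTE (balance to majority).**  Every class is oversampled to the size of
the largest class.  A synthetic row is `x + u (x_nn − x)` with `x` a real
class member, `x_nn` one of its `k = 5` nearest same-class neighbours
(Euclidean distance on raw, pre-scaling features — balancing precedes
normalization in the default order), and `u ~ U[0, 1]`.  Real rows are never
modified; synthetic rows carry a provenance flag.  If a class has fewer than
`k + 1` members, `k` is reduced to `size − 1` with a warning; singleton
classes are an error.  Ages of synthetic rows are interpolated with the same
`u`, which keeps them inside their (convex) age bin; sex is copied from the
seed point unless sex itself is the class label.

**Two pipeline orders.**  `paper` mode balances the whole cohort and splits
afterwards; `safe` mode splits first and balances only the training
partition.  `paper` is the default because it reproduces the published
procedure, but it leaks information two ways: synthetic neighbours of test
points end up in training, and synthetic rows themselves land in the test
partition, where they are interpolations of (mostly training) real rows.
On an effect-free n = 1000 cohort this inflates test sex accuracy to 0.588
(outside the 95% chance band of 0.500 ± 0.067 at n = 216), where the same
pipeline in `safe` mode stays at chance.  `safe` is the mode we recommend
for any real analysis, and it is the mode whose calibration the test suite
asserts.

**Scaling and encoding.**  Min–max scaling is always fitted on training rows
only — where the literal stage ordering (normalize before split) conflicts
with that rule, the rule wins, because fitting bounds on test rows is
leakage.  Test values may fall outside [0, 1] and are not clipped; a
constant training feature maps to 0.  Classification targets are one-hot
encoded; decoding is argmax with ties broken toward the lowest class index.

**Splitting.**  80/20, seeded, stratified by the task label for
classification; plain random for regression.  Strata of size 1 are an
error.

## The deep network

A fixed funnel of eight fully connected trunk layers (1024, 512, 256, 128,
64, 32, 16, 8 units) plus a task-sized linear head (2 sex / 4 age groups /
1 regression) — nine main layers in all, with the first layer taking the 12
inputs (or however many the feature mask leaves).  Each trunk layer is
linear → batch normalization → activation → dropout.  Activations are ReLU
for trunk layers 1–7 and softmax for trunk layer 8, taken literally: the
deepest 8-unit representation lives on a probability simplex, and the head
applies a plain linear map to it.  Batch normalization and dropout stop at
the trunk; applying them to the output layer would randomize or re-scale
the very predictions the loss is fit to, so the head is clean.

Training is plain SGD on mean squared error — against the one-hot matrix
for classification, against internally standardized targets for regression
(standardization keeps one learning rate usable for targets of any scale;
predictions are mapped back).  Cross-entropy and a softmax head are
available switches but are used nowhere by default.

**Hyperparameter defaults** (epochs 100, learning rate 0.05, batch 16,
dropout 0.1, batch-norm momentum 0.9, fan-in-scaled uniform init, float32
arithmetic): the epoch count is part of the protocol; the rest are this
package's choices, fixed by two capacity requirements we treat as
non-negotiable — the network must be able to memorize a 50-point
random-label problem within 500 epochs and must reach R² ≥ 0.95 on a
noiseless linear age signal.  Gentler settings (e.g. learning rate 0.01
with dropout 0.2) fail both: dropout noise biases the regression fit toward
the mean and the low rate underfits within the epoch budget.

Everything is seeded through one integer: weight init, batch shuffling and
dropout masks flow from `numpy.random.default_rng(seed)`, so the same data,
config and seed reproduce loss traces and predictions bit for bit.
Divergence (non-finite loss) raises immediately rather than propagating
NaNs.  Inference uses running batch-norm statistics and no dropout, so
prediction is deterministic.

## Genetic-algorithm feature selection

Chromosomes are 12-bit masks over the canonical feature order; all-zero
masks are repaired by setting one random bit.  The GA is deliberately
small and standard: tournament selection (size 2), single-point crossover
(p = 0.8), independent bit flips at rate 1/L, one elite per generation
(making best-so-far fitness non-decreasing), population 20 for 15
generations by default.  None of these values is a published setting; they
are desk-scale choices.

**Fitness** is the deep network's held-out performance on the masked
features: validation accuracy for classification, `1/(1 + RMSE)` for
regression (accuracy is undefined for a continuous target).  The validation
fold (20% of the training partition, stratified, seeded) is carved once and
shared by every mask, so comparisons are paired; each mask is trained with
one fixed seed, making fitness a deterministic, cacheable function of the
mask.  The fold never touches the test partition, so reported test metrics
are not selected on.

**The screening learner is deliberately constrained** (30 epochs, batch 64,
learning rate 0.02, dropout 0.2) relative to the final model.  This is a
property of wrapper selection, not a shortcut: a learner strong enough to
saturate validation accuracy scores every adequate mask identically and
leaves the search nothing to rank, whereas a constrained learner is
measurably hurt by irrelevant inputs.

**Final mask choice uses the one-standard-error rule.**  During evolution
the GA maximizes raw fitness (exact ties break toward the smaller mask);
but accuracy estimated on an n-row fold carries a binomial standard error
of sqrt(p(1−p)/n) — about 1–2 validation rows here — so the single
highest-scoring mask is partly an order statistic of fold noise.  Following
the standard practice from the model-selection literature (the 1-SE rule of
CART and glmnet), the mask returned by the full procedure is the most
parsimonious one, among all masks evaluated, whose fitness lies within one
standard error of the best; for the regression fitness, where no binomial
SE applies, only exact ties are eligible.  The chosen mask is then
retrained at the full epoch budget and scored once on the untouched test
partition.

## Baselines

Logistic regression, random forest and a 150-100-50 ReLU perceptron run
through the identical split/scale/evaluate path, always on the full
12-feature set.  Library implementations are used as-is; hyperparameters
beyond the printed ones are library defaults, echoed in the comparison
table for audit.  In the continuous-age scenario the "logistic regression"
slot is ordinary least-squares linear regression (logistic regression is
undefined for a continuous outcome; the original naming is kept only as a
row label).  Comparisons rank by accuracy (ties by macro F1) or by RMSE
(ties by R²).

## Synthetic cohorts

Real morphometry of this kind is private, so the simulator emulates the
published cohort shape: n = 240, 129 female / 111 male, ages uniform on
[18, 52].  The nine linear dimensions follow a linear Gaussian model

    x = μ + σ (δ_sex · 1[male] + β_age · (age − 35)/10 + ε)

with configurable standardized sex shifts (default 0.8σ on every dimension,
male larger — the direction reported across the craniofacial literature)
and age slopes (default 0.15σ per decade).  Right and left maxillary
homologues share a latent factor with loading √ρ (default ρ = 0.7).
Volumes are derived, not drawn: V = c·L·W·H·exp(ε_v) with c = 0.43 and
σ_v = 0.1, which makes volume columns largely redundant with their
dimensions — precisely the redundancy that makes wrapper feature selection
a meaningful exercise.  Baseline means and SDs are plausible adult sinus
magnitudes (maxillary length ≈ 38 mm, volume ≈ 15 000 mm³) chosen once for
readability; they claim nothing about any real cohort's distribution.
Measurements are truncated positive by resampling.  All rows are flagged
synthetic; the same config and seed give a byte-identical CSV.

The planted-relevance generator switches volume coupling and bilateral
correlation off so the twelve features are independent, puts a standardized
sex shift (2σ per feature by default) on a chosen subset and zero
elsewhere, and returns the ground-truth mask.  What passing tests on these
cohorts shows: the pipeline recovers planted structure and stays calibrated
under the null.  What they cannot show: anything about real sinus
measurement distributions, measurement error, or the published accuracy
numbers, which came from a private dataset.

## Problem sizes used in the test suite

Null-calibration runs use n = 1000 cohorts; signal-recovery and
planted-relevance runs use n = 500; the planted benchmark runs the full
select-and-retrain procedure ten times with a population of 10 for 5
generations and 30 screening epochs.  These sizes are the package's chosen
desk-scale study conditions; the selection machinery itself is
size-agnostic.

## Known limitations

- The softmax bottleneck at trunk layer 8 caps the representation entering
  the head at an 8-simplex; for regression this limits expressiveness, and
  the R² ceiling on hard nonlinear targets is below what an unconstrained
  head would reach.  It is kept because it is the defining architecture.
- MSE-on-one-hot is a weaker classification loss than cross-entropy; it is
  the default because it is part of the protocol being reproduced.
- `paper`-order SMOTE leaks synthetic neighbours of test rows into
  training (measured above); use `safe` for real analyses.
- Wrapper selection has an identifiability ceiling: when the planted
  per-feature effect is strong (2σ), every mask keeping ≥4 of 6 informative
  features has near-zero Bayes error, so held-out accuracy saturates and its
  binomial standard error on an 80-row fold exceeds the differences the
  search would need to rank masks.  Measured consequence: exact recovery of
  the planted mask (keep ≥5/6 informative and drop ≥4/6 noise) succeeds in
  only ~1–2 of 10 seeded runs under those conditions, under every selection
  rule we tried (raw argmax, exact-tie parsimony, 1-SE rule).  The
  corresponding acceptance test is expected to fail and is kept failing
  rather than weakened.  Reliable recovery would need weaker effects, larger
  validation folds, or fitness averaging over multiple seeds.
- Published per-table accuracy values are not reproduction targets: they
  were computed on a private cohort and are quoted nowhere in the test
  suite as assertions.
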