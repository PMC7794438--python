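# Methods

## Model

`gamnn` fits a generalized additive model whose univariate shape functions
are small neural networks (a GAM-NN) for binary risk prediction on tabular
clinical-style data. Writing x = (x_1, …, x_p) for the preprocessed feature
vector, the model is

    logit(x) = β0 + Σ_{j ∈ continuous} w_j · g_j(x_j) + Σ_{b ∈ binary} w_b · x_b
    P(y = 1 | x) = σ(logit(x))

Each continuous feature owns a subnetwork g_j: one to four fully connected
hidden layers (10–100 units, ReLU or tanh) followed by a single tanh unit,
so g_j(x_j) ∈ (−1, 1). Binary features skip the subnetworks and connect
directly to the final logistic layer. The interpretability claim is
structural, not post-hoc: the additive term w_j·g_j(x_j) (or w_b·x_b) *is*
feature j's contribution to the log-odds, and `contributions_table`
reconstructs every logit exactly as intercept plus the per-feature terms.
Feature interactions are deliberately not modelled — each shape function
sees one column only.

Assumptions: effects are additive on the logit scale; continuous effects
are bounded once multiplied by their logistic weight (|contribution| ≤
|w_j|, enforced by the tanh bottleneck); binary inputs are 0/1 so that a
binary contribution is either 0 or the weight itself.

## Preprocessing

Fixed order: impute → clip → standardize, with every data-driven parameter
fitted on training rows only.

- **Imputation** is per-feature by declared policy: `constant` (e.g. a
  severity score imputed with its modal class 3), `zero` (infusion-rate
  features where a missing value means the drug was never given), or
  `train_mean` (everything else; always the *training* mean, also when
  transforming test data).
- **Clipping** clamps each feature into schema-declared clinically
  plausible bounds. Bounds are domain constants, applied identically to
  every partition, so artifact values (unit errors, sensor spikes) cannot
  distort either the standardization statistics or the fitted shapes.
- **Standardization** rescales continuous features to mean 0, sd 1 using
  training statistics; the *population* (divide-by-n) standard deviation is
  used — either convention is defensible, this one is fixed and documented.
  Binary columns stay 0/1 by default: the binary contribution formula and
  patient reports presuppose raw indicators. `standardize_binary=True`
  restores the literal rescale-everything reading.

The train/test split draws |train| = round(0.8·n) rows from a seeded
permutation (59,985 rows split 47,988 / 11,997).

## Training

The loss is class-weighted cross-entropy: a positive sample costs
`w_pos · (−ln p)` with `w_pos = 100` by default, reflecting an outcome
prevalence below 1% where an unweighted fit collapses to the majority
class. Probabilities are clamped to [1e−7, 1−1e−7] inside the loss.
Optimization is mini-batch Adam (β1 = 0.9, β2 = 0.999, ε = 1e−8, lr 1e−3)
with batch size 256 for at most 100 epochs. The learning rate drops by a
factor of 10 (floor 1e−6) when the monitored loss fails to improve by more
than 1e−4 for five consecutive epochs; validation loss is monitored when a
validation split exists, otherwise the running training loss. There is no
early stopping by default — training runs to `max_epochs` with decay.
Dropout (p = 0.5 by default) applies to subnetwork hidden activations only,
never to inputs or to the bottleneck outputs; the L2 penalty (λ = 1e−4)
covers all weight matrices including the logistic weights, but no bias.

Three training-side choices deserve explanation because a naive setup
demonstrably fails on data with genuine non-monotone effects:

1. **1-d-aware initialization.** Fan-based (Glorot) initialization of a
   layer with a single input gives first-layer weights of order ±0.3, so
   every tanh unit is effectively linear across the standardized data range
   and the subnetwork starts monotone. Worse, the tanh bottleneck then
   saturates within the first couple of epochs (Adam moves every parameter
   at ≈ lr per step, and the bottleneck pre-activation sums ~50 of them),
   freezing the shape in its initial monotone form — on a cohort with a
   U-shaped effect this costs most of the attainable AUC. First-layer
   weights and biases are therefore drawn uniform on ±2.5 so the units'
   kinks and saturation points tile the standardized range, the bottleneck
   projection starts at zero (every shape function begins exactly flat),
   and the logistic weights start at 1 for continuous features (amplitude
   is available immediately, so the bottleneck need not saturate to move
   the logit) and at 0 for binary features.
2. **Intercept warm start.** The intercept is initialized at the
   class-weighted base log-odds log(w_pos·π/(1−π)). Otherwise the large
   global offset required by the weighted loss travels through every
   constant-capable channel (each subnetwork can emit a constant through
   its biases), leaving arbitrary per-feature constant offsets behind.
3. **Sum-to-zero centering.** Per-feature constants are not identified
   against the intercept — the classical GAM identifiability problem,
   solved in penalized-spline GAMs by centering every smooth. The training
   loss therefore includes μ·Σ_j (batch-mean g_j)² with μ = 1, which keeps
   each shape function centered and pushes offsets into β0 where they
   belong. Without it, null features carry constant contributions of ±0.2
   that swamp their true (zero) effect.

All randomness (initialization, epoch shuffling, dropout masks) derives
from `config.seed`; two runs with the same seed reproduce losses and
weights to floating-point identity on one platform.

## Hyperparameter selection

Exhaustive grid search over layers {1–4} × sizes {10, 40, 50, 90, 100} ×
activations {relu, tanh} × dropout {0.25, 0.5, 0.9} × L2 {1e−3, 1e−4}
(240 combinations), each scored by mean held-out AUC under stratified
5-fold cross-validation on the training partition. Stratification matters:
at sub-1% prevalence an unstratified fold can contain zero positives and
an undefined AUC. Ties break toward the earlier grid entry; the winner is
retrained on the full training partition. The library default configuration
is the selected one: 1 hidden layer, 50 tanh units, dropout 0.5, L2 1e−4.

## Evaluation

AUC ROC (Mann–Whitney, ties half) and average precision (non-interpolated
step sum) with 95% percentile-bootstrap intervals from 1000 paired
(label, score) resamples; single-class resamples are redrawn with a 10×
attempt cap. Both metrics are delegated to scikit-learn; the test suite
verifies them against O(n²) brute-force oracles to 1e−12. The reference
model is a logistic regression on the identical preprocessed matrix,
fitted by lbfgs with a very weak L2 (C = 1e6) so it remains defined under
perfect separation; its coefficients are reported on the standardized
scale the network itself consumes.

## Interpretability outputs

Shape curves plot each sample's raw (pre-standardization, post-clipping)
feature value against the per-sample GAM-NN contribution, with the LR
contribution (coefficient × standardized value — exactly linear) as the
reference on a secondary axis. Contributions stay on the logit scale; the
more negative, the less that value adds to predicted risk. Features rank
by mean contribution across samples, optionally excluding binary flags
(whose curves have only two x-values). Patient reports list the top-k
contributions for one sample in raw clinical units; at k = p they
reconstruct the patient's full logit. `binned_curve` (equal-count bin
means) exists for diagnostics such as locating a learned U-shape's argmin;
the primary artifact is the raw scatter.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, with
known ground truth. Continuous features are truncated normals; each
carries a declared shape on the generating z-scale: `linear` (scale·z),
`u_shaped` (a centered quadratic with a declared vertex — risk rising on
both sides of an optimum, the classic intraoperative mean-arterial-pressure
pattern), `threshold` (a hinge), or `flat` (an exact null, for
false-positive-shape tests). Binary flags are Bernoulli with a log-odds
weight. The logit is assembled additively, the intercept is solved by
Brent's method so the sampled sigmoid mean hits the target prevalence, and
labels are Bernoulli draws. Missing cells and out-of-range spikes are
injected only *after* label generation, so labels always reflect true
values and the tests isolate how imputation and clipping degrade recovery.

The ready-made template (`paper_template_spec`) has five continuous
features — U-shaped mean arterial pressure (vertex 65 mmHg, values
30–120), linear age, a hinge-threshold severity score with constant-value
imputation, a protective linear minimum diastolic pressure, and a null
pulse-oximetry feature — plus three binary device/procedure flags at
prevalences 18%, 5% and 2%, with a default outcome prevalence of 0.8%.
Effect scales put per-feature contributions on the order of ±1.5 logits.
What the template does *not* emulate: correlated features, interactions,
informative missingness, measurement error, non-Gaussian marginals, or
calibration drift — so passing recovery tests demonstrates that the
machinery works under the model's own assumptions, not that it will
recover shapes from any real registry.

## Problem sizes and numerical choices

Recovery suites run at n = 20,000 (shape recovery, outcome prevalence
lifted to 5% so fold/test positive counts are stable at desk scale),
n = 30,000 (linear-limit comparison; held-out AUC differences at smaller n
are dominated by binomial noise), and n = 3,000 (grid-search contract,
prevalence 15%). Additivity is asserted to 1e−6 absolute; metric oracles
to 1e−12; standardization self-consistency to 1e−10. Degenerate inputs
fail loudly: constant columns at standardization, single-class labels at
training and AUC, fully-missing train-mean features at imputation,
all-one-class synthetic cohorts at generation.

## Known limitations

- Contribution bounds couple amplitude to the logistic weight; an effect
  spanning many logits forces |w_j| large and the shape toward saturation.
- No interaction terms, by design; confounded pairs fold into whichever
  univariate shapes best absorb them.
- The centering penalty holds batch means near zero but is not an exact
  constraint; residual per-feature offsets of order 1e−2 remain.
- Bootstrap intervals are percentile, not BCa; for very rare outcomes and
  small test sets they can be optimistic.
- Training reproducibility is per-platform (BLAS reduction order).
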