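# Methods

## Problem setting

The package targets binary classification under extreme class imbalance
(positive prevalence on the order of 1–4%), the regime typical of rare-disease
screening from routine laboratory panels. Ordinary classifiers trained on such
data drift toward the majority class: overall accuracy stays high while
minority-class recall collapses. The usual remedies rebalance the *data*
(SMOTE-style interpolation, GAN-generated minority samples, undersampling);
this package instead implements a model-level alternative that leaves the data
untouched and works on the *representation*: each continuous feature is kept
in two forms — raw, and discretized into label-informed intervals — and each
form is routed to base learners suited to it, with a second-layer forest
fusing the base probabilities.

## Supervised CART discretization

For each flagged continuous feature j, a small CART classifier is grown on the
pairs (x_j, y) with Gini impurity, maximum depth D_j, leaf budget L_j, and
minimum leaf/split sizes. The split values at its internal nodes,
deduplicated and sorted, become the threshold vector
θ_j(1) < … < θ_j(K−1), which partitions ℝ into K right-closed intervals

    I_j(k) = { x : θ_j(k−1) < x ≤ θ_j(k) },   θ_j(0) = −∞,  θ_j(K) = +∞.

A value maps to the 1-based index of its interval; values outside the training
range are absorbed by the virtual ±∞ bounds, so transform never fails on new
data. The interval count obeys K ≤ min(2^D, L). Defaults are D = 3, L = 8,
min 5 samples per leaf, min 2 per split, i.e. at most 8 intervals per feature.

Numerical choices:

- Candidate cuts are midpoints between consecutive distinct sorted values
  (the CART convention), which makes the toy examples exact.
- Tree growth is best-first under the leaf budget (scikit-learn's behaviour
  whenever `max_leaf_nodes` is set), the conventional reading of a leaf
  budget.
- Thresholds are deduplicated by exact equality; no epsilon merging.
- **Exact Gini ties.** Distinct cuts can induce mathematically identical
  weighted impurities (e.g. x = [0,2,3,2,0,4,5,3], y = [1,1,0,1,0,1,1,1]:
  cuts at 1.0 and 3.5 tie). Which tied cut the underlying library selects is
  determined by its floating-point split-proxy arithmetic, not by a stated
  rule; the package documents the guarantee that the fitted split always
  *attains* the optimal Gini, verified against an exhaustive-search oracle,
  and leaves the tie representative library-determined. Fits remain
  deterministic for fixed data.
- A constant feature yields K = 1 (no thresholds), not an error; a
  single-class label vector is an error, since supervision is then vacuous.

Equal-width and equal-frequency binning are provided as unsupervised
baselines in the same threshold representation (equal-frequency collapses
duplicate quantiles, so K may shrink).

Discretization also acts as a robust transform: heavy-tailed laboratory
features (skewness ≫ 1) map to bounded integer indices whose skewness is far
smaller, which stabilises learners that are sensitive to extreme values.
`skewness_report` quantifies this per feature with the population-moment
Fisher–Pearson coefficient g1 = m3 / m2^{3/2} (no small-sample correction;
the corrected variant is available by flag). |g1| > 1 is flagged as highly
skewed.

## Base layer and routing

Two views of the same rows are built: ND (raw continuous columns) and FD
(interval indices of the flagged columns). Categorical columns have one
natural form and pass through to both views as ordinal codes. The default
four-slot plan is

| slot | learner | view | rationale |
|------|---------|------|-----------|
| 1 | XGBoost (100 trees, γ=0, λ=1) | ND | precise non-linear boundaries on raw values |
| 2 | LightGBM (100 trees, λ=1) | ND | histogram-based complement to slot 1 |
| 3 | ordered target encoding + XGBoost (100 rounds, lr 0.1, depth 6) | FD | ordered-statistics handling of interval levels |
| 4 | AdaBoost over depth-1 stumps (50 rounds, lr 1) | FD | stable stepwise boundaries, emphasis on hard cases |

Slot order is fixed once the plan is built; it defines the meta-feature
layout. Every slot exposes the same contract: fit on its routed view, report
a probability p = σ(s) and the raw score s = logit(p). Feeding a slot the
wrong view raises a view-tag mismatch error rather than silently cross-feeding.

Gradient-boosting internals are delegated to the xgboost and lightgbm
libraries behind this contract; they are standard published algorithms, not
this package's contribution. The LightGBM slot lowers `min_child_samples`
to 5 (library default 20) so the learner can still split at the row counts
the synthetic scenarios use. Slot 3 realises categorical-native boosting as
ordered target encoding followed by a boosted learner with the
configuration above; `fd_as="ordinal"` feeds the raw indices instead. A
`stub` slot kind (logistic regression) exercises the contract in tests
without any boosting library in the loop.

**Ordered target encoding.** A level's encoding is the smoothed running mean
of the label over strictly preceding samples of that level in a seeded
traversal permutation:

    TE(x_i) = (Σ_{k<i, x_k=x_i} y_k + a·p) / (#{k<i: x_k=x_i} + a),

so a sample's own label never leaks into its encoding. Defaults: a = 1,
p = training prevalence (the natural prior when none is given). One
permutation per fit, shared across columns; dataset-order traversal is
available (`order_seed=None`). At transform time the full training statistics
are used; unseen levels encode to the prior. With a = 0 a first occurrence is
0/0; the encoder returns the prior and warns.

**AdaBoost.** Discrete AdaBoost in the ±1 formulation: weighted error
ε_t = Σ w_i·1[h_t(x_i) ≠ y_i], learner weight α_t = ½·log((1−ε_t)/ε_t),
weights reweighted by exp(−α_t·ỹ·h̃) and renormalised to the simplex each
round. ε ≥ 0.5 discards the round and stops; ε = 0 diverges in α, so α is
clipped at ½·log((1−ε_min)/ε_min) with ε_min = 1e−10, preserving ordering.
The ensemble score Σ_t α_t·h̃_t(x) maps to a probability via the sigmoid.

## Meta-ensemble

The four slot probabilities form the meta-feature vector v = [p1, p2, p3, p4].
A random forest (default 100 trees, bootstrap resampling, √-feature
subsetting per split, unlimited depth, default leaf sizes) is fitted on these
vectors. The final label is the majority vote of the per-tree argmax
predictions; a label of 1 requires strictly more than T/2 positive votes, so
an exact tie on an even tree count resolves to the negative class — in the
clinical framing a tie carries no positive evidence. The continuous score
used for ROC/PR curves is the forest's mean leaf probability of class 1 (the
standard forest probability); majority voting alone yields only labels, so a
curve requires this companion score, and any monotone rescaling of it leaves
the ROC unchanged.

**Meta-feature assembly.** Fitting the base learners on all rows and feeding
the meta-model their in-sample probabilities (`meta_mode="direct"`) is the
literal composition of the training algorithms, but lets the meta-model
learn the base layer's training optimism. The default is therefore
out-of-fold assembly (`meta_mode="out_of_fold"`, k = 5): a stratified k-fold
supplies row i's vector from learners that never saw fold(i), after which the
deployed learners are refitted on all rows. Both modes are recorded in the
model archive; a test demonstrates that out-of-fold assembly removes the
memorisation a flexible learner exhibits on label-shuffled data.

All randomness flows from a single integer seed: component seeds (slots,
fold shuffling, meta forest) are derived through a `SeedSequence`, so the
full pipeline output is a pure function of (data, configuration, seed).

## Evaluation

Reports carry sensitivity (minority recall), specificity, precision, F1,
G-mean = sqrt(sensitivity × specificity), AUROC and AUPRC, plus the
confusion counts and the threshold used (default 0.5 for probability-style
scores). Conventions: zero predicted positives give precision and F1 of 0
with an explicit flag; a single-class truth vector flags AUROC/AUPRC as
undefined (NaN) rather than silently reporting 0. Curve points group tied
scores. AUROC is validated in tests against the independent Mann–Whitney
probability-of-correct-ranking estimator.

## Synthetic data generator

The generator emulates the statistical shape of a rare-disease laboratory
cohort, not any particular hospital's data: exact positive counts
(`round(n × prevalence)` — prevalence carries no sampling noise), and a
panel of class-conditional features. One seed governs everything through
stream splitting (labels from the first child stream, feature j from child
j+1), so adding a feature never perturbs the labels.

The `clinical_like` panel (defaults, negative-class parameters):

| feature | family | negative class | positive-class shift |
|---|---|---|---|
| crp_like | lognormal | μ=3.0, σ=1.0 | ×12 |
| alt_like | lognormal | μ=3.4, σ=1.2 | ×7 |
| ast_like | lognormal | μ=3.8, σ=1.5 | ×4 |
| wbc_like | normal | 10.8 (SD 5.9) | +11.8 (+2.0 SD) |
| hgb_like | normal | 12.0 (SD 1.8) | −2.7 (−1.5 SD) |
| plt_like | normal | 294 (SD 125) | +187.5 (+1.5 SD) |
| hct_like | normal | 35.6 (SD 4.9) | −5.9 (−1.2 SD) |
| urine_flag | bernoulli | rate 0.07 | +0.78 |
| noise | normal | 0 (SD 1) | none |

Families, directions and negative-class locations mirror published
descriptive statistics of febrile-cohort laboratory panels (heavily
right-skewed liver/inflammation markers, near-normal hematology, a binary
pyuria-style flag). The shift magnitudes are deliberately larger than those
descriptive tables suggest feature-by-feature: a desk-scale panel has ~9
features and a few thousand rows where a real cohort has dozens of features
and tens of thousands of rows, so per-feature effects were calibrated once so
that the scenario reproduces the *operating regime* the method is built for —
a majority-vote ensemble reaching >90% held-out recall at ~2% prevalence —
rather than any table of real-data statistics. With these frozen values the
default pipeline averages ≈ 0.92 recall and ≈ 0.96 G-mean over ten seeds
(n = 5000, 2% prevalence, 80:20 stratified split). What passing tests show is
that the pipeline exploits class-conditional structure of this kind under
extreme imbalance; they do not certify performance on real clinical data,
which has correlated features, measurement artifacts, missingness and
cross-institution shift that the generator does not model.

Other scenarios: `separable` (two features with effects large enough that
classes barely overlap — used for exact recall/specificity oracles), `null`
(the clinical panel with all effects removed — any classifier's expected
AUROC is 0.5, and the pipeline's held-out G-mean collapses), and
`threshold_step` / `known_threshold_dataset` (a single uniform feature with a
step in P(y=1) at a known cut c, used to verify the discretizer recovers c;
labels here are Bernoulli in x by construction, so the exact-count rule
applies to the class-conditional scenarios only). Threshold recovery is
unreliable below a few hundred rows and is documented as out of contract
there.

## Problem sizes and determinism

Test and acceptance workloads are sized for a single CPU: discretizer sweeps
use 200–2000 small datasets, algebra checks 10,000 randomized cases, and the
end-to-end scenario n = 5000 over 10 seeds (the acceptance script uses 5
derived seeds). Two runs with identical data, configuration and seed produce
identical predictions and model manifests; the model archive stores all
native-learner state as JSON/text (the meta forest as a joblib blob) with a
format version checked at load.

## Known limitations

- Binary labels only; no multi-class, no missing-value handling (missing
  data are rejected at load, since silent imputation would change the
  method).
- The categorical-native boosting slot is realised as ordered target
  encoding + gradient boosting; it is not the CatBoost library.
- No hyperparameter search; the documented defaults are package defaults,
  overridable via configuration.
- The generator draws features independently given the class; real panels
  are correlated, which typically makes the problem easier per-feature
  count than independence suggests — another reason the calibrated shifts
  are not comparable to real-data effect sizes.
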