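# Methods

## Model and procedure

Ensemble Integration treats each data modality as its own learning problem.
A *local model* is a binary classifier trained on one modality's feature
table; the ensemble layer then operates purely on local-model scores, never
on raw features. The separation is enforced by nested cross-validation:
outer folds (default 5) define where ensembles are trained and evaluated,
and inner folds (default 5, chosen to match the outer granularity since the
inner count is a free parameter) within each outer-training set define
where local models are trained. Every base prediction consumed downstream
is out-of-fold, and the package ships an exhaustive audit
(`audit_out_of_fold`) that walks the provenance of every (entity, column)
score and fails on any breach.

Outer-test base predictions are the mean of the `k_inner` inner models'
scores rather than the output of a model retrained on the whole
outer-training set. This keeps train- and test-side base scores on the same
distributional footing (both are averages of models trained on ~4/5 of the
outer-training data); retraining would hand the meta-layer test inputs from
a systematically stronger model than the one that generated its training
inputs.

Class imbalance is handled by random undersampling of the majority class,
applied **inside each training fold only** (test folds keep the natural
class ratio; balancing them would inflate the precision entering Fmax). The
balanced subset is shared across the algorithms of a modality within a
fold, so roster changes do not perturb the training sets of unrelated
columns. Undersampling before fold splitting is leakage-prone and is not
offered as a default; the flag can be turned off entirely.

### Ensemble variants

* **Mean aggregation** needs no fitting.
* **CES** (forward selection with replacement) optimizes Fmax on the
  outer-training base predictions. Design choices: strict improvement (no
  epsilon) as the stopping rule, ties broken toward the lowest column
  index, at most 100 iterations, no internal validation split — the
  out-of-fold contract already decouples selection data from local-model
  training. The selection metric is configurable (AUPRC available). The
  bagged variant of the original ensemble-selection literature is out of
  scope.
* **Stacking** fits one meta-classifier per roster entry on the
  out-of-fold base predictions. Meta-models that fail to fit are recorded
  as failed and the variant is dropped with a warning rather than aborting
  the run.

Reported performance pools outer-test scores across folds before computing
Fmax/AUPRC/AUROC (per-fold reports are also emitted); pooling yields a
single operating curve per variant and is how a deployment would consume
the model.

### Classifier registry

The ten local families and nine meta families are scikit-learn estimators
plus XGBoost, used with library defaults except: the local linear SVM uses
C = 0.001 and logistic regression caps iterations at 100 (both to bound
convergence time), and the stacking SVM uses a linear kernel. Two families
have no exact scikit-learn counterpart: the rule-induction slot is filled
by an entropy-criterion decision tree (the closest native relative of
partial-tree rule lists) and the perceptron-family slot by the standard
perceptron with its margin squashed through a logistic at score time.
Estimators without `predict_proba` are scored via
`sigmoid(decision_function)`, so every column of the base prediction matrix
lies in [0, 1]. Stochastic learners receive per-model seeds derived from
the global seed by a stable blake2 hash of (seed, component path), so runs
are bit-reproducible and components are independently seeded.

## Interpretation

Local feature ranks (LFRs) use *held-out retraining*: the importance of
feature f for a local model is the drop in stratified-CV AUPRC (5 folds on
the model's own training entities) when the model is retrained without f.
Score-time zeroing was rejected because "holding out" a feature most
plausibly means excluding it from training, and zeroing measures
sensitivity to an arbitrary imputation point instead. AUPRC is the default
importance metric; the interface accepts alternatives.

Local model ranks (LMRs) are variant-dispatched: uniform for mean
aggregation — every column receives the average percentile (n+1)/(2n),
which keeps RPS magnitudes comparable across variants while leaving
within-ensemble feature ordering untouched; CES inclusion counts, with
never-selected columns tied at the worst rank so that every feature retains
a defined RPS; and permutation importance for stacking — the mean AUPRC
drop over 100 random permutations of a column, **re-scoring** the fitted
meta-model rather than retraining it (the standard permutation-importance
routine; retraining would measure a different, far costlier quantity).

Percentile ranks use the mean-rank tie convention and span 1/n to 1. Rank
product scores average LMR x LFR over the local models covering a feature
and are reported ascending. Because percentile ranks are relative to
modality size, the scheme is mildly biased toward large modalities; this
bias is left uncorrected by default to keep the baseline procedure intact,
and a size-normalized mode is a natural extension.

Whole-dataset interpretation (`interpret_ei`) retrains the grid of local
models on all entities, fits the chosen ensemble on stratified-CV base
predictions over all entities, and combines the resulting ranks.

## Evaluation machinery

Fmax sweeps thresholds over the unique score values (predict positive at
score >= t), defines F = 0 where precision + recall = 0, and breaks ties
toward the higher threshold (the more conservative operating point). AUPRC
is the step-interpolated area (sum of precision x recall increments, the
average-precision dialect); AUROC is the trapezoidal / Mann-Whitney area
with half credit for ties. Both are oracle-tested against exhaustive
recomputation and direct U-statistic counting.

Method-over-tasks comparisons use the tie-corrected Friedman chi-square on
within-task ranks followed by Nemenyi pairwise p-values from the
studentized range distribution, Benjamini-Hochberg-adjusted across pairs.
Feature-list overlaps use the two-sided Fisher exact test; the odds ratio
is reported as the conditional MLE of the noncentral hypergeometric
likelihood (the sample cross-product ratio is reported alongside, but the
conditional MLE is the estimate that matches exact-test inference).

## Preprocessing defaults

* Missingness filter: keep features with missing fraction strictly below
  0.3 ("fewer than 30%"), so a feature missing in exactly 30% of rows is
  dropped.
* KNN imputation: K = 5; distances are Euclidean over mutually observed
  features scaled by sqrt(n_features / n_usable); donors must observe the
  imputed feature; distance ties break by entity order. Observed cells are
  never altered.
* z-scores use the population SD (divisor n); zero-variance features map
  to 0. Statistics are fitted on training rows only.
* Adjacency-vector modalities: the symmetric weighted adjacency row over a
  fixed node universe; entities without edges (or absent from a network
  entirely, after alignment) get all-zero rows flagged as *data*, not
  missingness — absence of associations is informative. Edges outside the
  universe are dropped with a log message so the feature space stays
  predictable.
* Entity alignment reindexes every modality to the labeled entities in
  lexicographic order (reproducible regardless of input file order).
  Labeled entities present in no modality are retained zero-filled with a
  warning.

## Synthetic data: what it does and does not emulate

The generator produces class-conditional Gaussian features with equal
covariance: informative features shift the positive-class mean by
`effect_size` SD units; within-modality correlation comes from one shared
factor per modality. The *complementary* scenario partitions the positives
into disjoint subsets, one per informative modality — the simplest
structure in which concatenation and late fusion genuinely differ, and the
regime late integration is designed for. The *redundant* scenario shifts
all positives in every informative modality; *noise* plants nothing.
Missingness is MCAR only, and every feature keeps at least one observed
value.

Passing tests on these data demonstrate correct mechanics and the expected
qualitative orderings (integration benefit under complementarity,
planted-feature recovery). They do not certify behavior under real-data
phenomena the generator omits: non-Gaussian and heavy-tailed features,
informative missingness, label noise, temporal structure, or
network-topology effects beyond random weighted graphs.

## Study sizes used by the automated checks

The acceptance checks run at desk scale: the default-roster run uses 300
entities x 3 modalities x 10 features; recovery and integration-benefit
experiments use 600 entities, prevalence 0.25, effect size 2.0, ten seeded
replicates, and a reduced roster (logistic regression, naive Bayes,
decision tree locally; logistic-regression stacking) — fast, deterministic
families that keep the ten-replicate experiments quick while exercising the
full pipeline.

## Known limitations

* CES with strict-improvement greedy selection can include a noise column
  whose addition nudges the training metric by one step; with inclusion-
  count LMRs such a column then ties with genuinely informative
  single-inclusion columns. The validation-split CES mode and the bagged
  selection of the wider literature mitigate this but are outside the
  default configuration.
* Hyperparameter search and probability calibration are deliberately out
  of scope; the rosters mirror algorithm families, not any particular
  toolkit's tuned defaults.
* The interpretation cost grows as (features per modality) x (local
  models) x (CV folds) retrainings; for wide modalities use a reduced
  roster or coarser CV.
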