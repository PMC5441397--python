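# Methods

## The problem

Clinical prediction studies built on smartphone and wearable-sensor data
almost always collect many records per subject: feature vectors computed from
sensing windows, visits, or encounters.  When such a dataset is
cross-validated *record-wise* — folds drawn over records regardless of which
subject they came from — records of the same subject end up on both sides of
the train/test boundary.  A classifier can then recognise the *subject*
(whose label it already saw in training) instead of the *disease*, and the
estimated accuracy no longer predicts performance on new patients.
*Subject-wise* cross-validation, which assigns whole subjects to folds,
matches the diagnosis use-case: the test fold behaves like a newly recruited
patient.  This package quantifies the gap between the two estimates and
benchmarks both against a true-error oracle.

## Generative model (`cvleak.cohort`)

Each of S subjects carries a latent class β_s ∈ {+1 (diseased), −1 (healthy)}
and contributes R records of N features:

    y[s,r,n] = a·β_s + b·u[s,n] + c·v[s,r,n] + d·ε[n]

with u, v, ε independent standard normal draws.  The terms and their roles:

| term | drawn | role |
|------|-------|------|
| a·β_s | fixed | disease (fixed) effect; expected class-mean difference 2a |
| b·u[s,n] | once per (subject, feature) | cross-subject random effect: stable personal signature |
| c·v[s,r,n] | once per record-feature | within-subject record noise |
| d·ε[n] | once per feature per cohort | population-level per-feature offset shared by everyone |

The ε index carries no subject or record subscript, so it is implemented as
one draw per feature per cohort, shared across all subjects and records; it
shifts both classes equally and cancels out of class contrasts.  Simulation
defaults follow the simulated-clinical-prediction design: a = 0.5 (effect
size (1−(−1))·0.5 = 1), d = 0.1, N = 10, R = 100, b and c swept over 0..2.

Design choices where the design was genuinely open:

- **Class assignment.** ⌊S/2⌋ subjects are diseased; for odd S the extra
  subject is healthy.  Class counts never differ by more than 1.
- **Seed streams.** One master seed spawns independent sub-streams for u, v,
  ε and the holdout (numpy `SeedSequence`), so changing R does not perturb
  the u draws and holdout generation never consumes training-cohort
  randomness.  Identical seeds give bit-identical cohorts.
- **Holdout ε.** The 10-subject holdout used as the true-error oracle
  redraws ε by default — it is a genuinely new dataset, the situation a
  deployed model faces.  `share_eps=True` reuses the training cohort's
  offsets for the stricter same-population reading.  Each repetition of an
  experiment redraws the full cohort, ε included.
- **Latents** (u, v, ε, β) are retained on the cohort object so tests can
  verify the variance decomposition (within-(subject,feature) variance → c²,
  variance of per-subject record-means within class → b², class-mean
  difference → 2a) directly rather than only through Monte-Carlo proxies.

## Splitting (`cvleak.splitting`)

Record-wise k-fold deals shuffled records into folds (sizes differ by ≤ 1);
subject-wise k-fold deals whole subjects (subject counts per fold differ by
≤ 1).  Balancing is by subject count, not record count: records per subject
are equal in simulation, and on real data per-fold record counts may differ.
Ties (odd counts) give the extra unit to the lower-indexed fold.  The 50/50
half-split used by the simulation puts the extra record/subject on the
training side (fold 0); its subject-wise variant stratifies subjects by
class, which is what keeps S = 4 designs from producing single-class
training halves.  Subject-wise k-fold does not stratify by default (a
`stratify` flag deals each class cyclically with a continuing counter when
degenerate training sets are a risk).  `verify_no_subject_leakage` audits
any assignment; for record-wise folds a failure is diagnostic, not an error.

## Evaluation (`cvleak.evaluation`)

Three classifier families:

- **random_forest** — scikit-learn `RandomForestClassifier`, 50 trees (the
  tree count used in both experiments); all other settings are the library
  defaults, recorded in run metadata.  The tree count is treated as fixed,
  not tuned.
- **midpoint_threshold** — the population-trend rule of the walking-speed
  example: predict diseased iff the single feature is *strictly* below the
  midpoint of the training class means.  Strictness resolves the degenerate
  fold whose class means coincide (training means 0.4/0.4 when the fastest
  subject is held out) in favour of the healthy call, which is the verdict
  the worked example requires.
- **nearest_record** — 1-NN over records, Euclidean distance, ties broken by
  the lowest training record index; the memorizing learner that record-wise
  CV rewards.

Errors are misclassification fractions; the CV mean error is record-weighted
(total misclassified over total tested), hence invariant to fold relabeling.
Repetition intervals are distribution-free percentile intervals (2.5th and
97.5th percentiles of repetition mean errors); with few repetitions they are
sample ranges, which is the honest width.  `true_error` scores the fold
models on the holdout and averages across models.

## The grid experiment (`cvleak.bias_grid`)

For every (b, c, S) cell and repetition: generate a cohort, half-split it
both ways, train on the training half, and record the test-half error (what
CV reports) and the holdout error (the truth).  True error per cell uses the
single model trained on the training half, matching the half-split design.
The cohort seed depends on (master_seed, b, c, S, repetition) only, so both
schemes judge the same data draw; the scheme enters only the split and
classifier streams.  Cells are seeded independently, making results
independent of execution order and the sweep embarrassingly parallel.
Defaults are the full design (21×21 b,c grid, S = 4..32, 10 repetitions);
tests and examples run coarse sub-grids (5×5, S ∈ {4, 12, 32}, 5
repetitions), which preserve every qualitative contrast at a few minutes of
compute.

## Activity-recognition protocol (`cvleak.har`)

The protocol consumes data in the public smartphone activity corpus layout
(three aligned whitespace-delimited files: 561-feature matrix, activity code
per line, subject id per line; 30 subjects, 6 activities).  Feature
engineering belongs to the upstream corpus and is out of scope.  Because the
corpus is an external download, a fixture generator emits files in the
identical layout: per-class Gaussian means (scale `class_separation`) plus
per-subject offsets (scale `subject_signature_strength`) plus unit noise.
The subject offset is the leakable signal; at strength 0 the two CV schemes
estimate the same quantity, and the gap grows with strength.  Fixture
defaults mirror the real corpus's scale (30 subjects, 561 features, ~57
records per subject per activity); tests use smaller shapes.

The sweep runs both schemes over subject counts and fold counts in
{2, 10, 30}, resampling the subject subset and the folds in every
repetition.  Subject-wise cells with k > S cannot be formed and are reported
as skipped, never silently dropped.  Multi-class error is the fraction of
misclassified records (micro-average).  Real-data error levels (errors of a
few percent record-wise versus tens of percent subject-wise at small S) are
properties of the real corpus and are not asserted on fixtures; fixtures
establish the direction and flatness contrasts only.

## Review statistics (`cvleak.review`)

The computable part of the systematic review.  CV-type classification fires
two rule groups over per-paper annotations — subject-wise evidence
(terminology, stated unseen-subject testing, no id overlap) versus
record-wise evidence (folds > subjects, random whole-dataset split, id
overlap found).  Both groups firing yields an explicit `conflict` outcome
for human adjudication rather than an automatic resolution; neither yields
`unknown`.  Accuracy normalization: single accuracy → itself; multiple
per-condition accuracies → mean; multiple per-classifier accuracies → max;
sensitivity/specificity within 2 points → mean; F1 (reported or 2PR/(P+R))
substitutes when no accuracy exists; RMSE-only papers are missing.  Each
normalized value carries the rule that produced it, so the accuracy/F1
mixture is auditable.  Because the source fields do not distinguish
per-condition from per-classifier multiplicity, records carry an
`accuracy_multiplicity` annotation; the scale (fraction vs percent) is
likewise declared per record, never guessed from magnitude.

Group medians of classification error (1 − accuracy) are computed over
papers with extractable accuracy, with group sizes reported alongside.  The
two-tailed rank-sum test uses exact enumeration for combined n ≤ 20 without
ties and the normal approximation with tie and continuity corrections
otherwise (scipy's Mann-Whitney implementation, cross-checked in the test
suite against an exhaustive enumeration oracle); two identical constant
samples return p = 1.

The bundled fixture is synthetic: 62 papers whose annotations classify 28
record-wise / 34 subject-wise, accuracy extractable for 47 (25 + 22), errors
drawn log-normally around medians of 13% (subject-wise) and 5.6%
(record-wise), citations Poisson around 10.5 and 9.  It exercises every
normalization rule and reproduces the qualitative review finding (about
twice the reported accuracy under the leaky scheme, rank-sum p ≪ 0.01), but
it is a stand-in with the same schema as a review export, not bibliographic
data.

## What the simulations do and do not show

The generator produces Gaussian, feature-independent, exchangeable records:
no feature correlations, no non-Gaussian tails, no longitudinal ordering, no
site effects.  Passing tests therefore demonstrate the *mechanism* of
subject leakage and the direction and rough magnitude of its bias under a
clean random-effects structure — not error levels for any particular real
dataset, where correlated features and temporal autocorrelation can make
record-wise optimism worse.  One subtlety worth flagging: label-permutation
nulls are only chance-level under record-wise CV when subjects carry no
identifiable signature (b = 0).  With b > 0, permuted labels are still
constant within subject, so the leaky scheme beats chance even on pure
noise — the test suite asserts this below-chance behaviour explicitly
rather than pretending the null holds there.  Time-based (prognosis) splits
are conceptually adjacent but not implemented.  Hyperparameter tuning and nested CV are out
of scope; the random forest's tree count is fixed at 50 throughout.

## Numerical conventions

Misclassification fractions live in [0, 1]; printed percentages are 100×.
All randomness flows from explicit seeds; derived seeds come from
`SeedSequence` streams and stay below 2³¹.  Degenerate inputs fail loudly:
single-class training sets raise (the caller should stratify), infeasible
fold counts name the limiting count, malformed layout files name the
offending line.
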