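# cvleak

**Record-wise vs subject-wise cross-validation for sensor-based clinical
prediction: leakage simulation, true-error benchmarking, and review
statistics.**

Clinical machine-learning studies on smartphone and wearable data collect
many records per subject.  If cross-validation folds are drawn over
*records* (record-wise CV), records of the same subject appear in both
training and test sets, the classifier can recognise the subject instead of
the disease, and the reported accuracy does not transfer to new patients.
Drawing folds over *subjects* (subject-wise CV) mirrors the diagnosis
use-case.  `cvleak` is a library for measuring that difference: it is aimed
at methodologists and reviewers who want to demonstrate, quantify, or audit
subject leakage in evaluation pipelines.

## The model

Simulated cohorts follow a random-effects generative model.  For subject
s ∈ {1..S} with disease state β_s ∈ {+1, −1}, record r ∈ {1..R}, feature
n ∈ {1..N}:

```
y[s,r,n] = a·β_s + b·u[s,n] + c·v[s,r,n] + d·ε[n],   u, v, ε ~ N(0, 1) iid
```

`a` is the disease effect (class means differ by 2a), `b` scales the
cross-subject random effect (each subject's stable personal signature — the
leakable signal), `c` the within-subject record noise, and `d` a per-feature
offset shared by the whole cohort.  Both CV schemes are benchmarked against
the **true error**: the same trained models scored on an independently
generated holdout cohort never touched by CV.

## Worked example

```python
from cvleak import (GenerativeParams, generate_cohort, generate_holdout,
                    CVScheme, make_half_split, ClassifierSpec,
                    cross_validate, true_error)

params = GenerativeParams(a=0.5, b=1.0, c=1.0, d=0.1,
                          n_features=10, n_records_per_subject=100,
                          n_subjects=12, seed=5)
cohort = generate_cohort(params)
holdout = generate_holdout(params, 10)

for mode in ("record_wise", "subject_wise"):
    split = make_half_split(cohort, CVScheme(mode, "half_split", seed=2))
    est, models = cross_validate(cohort, split, ClassifierSpec(n_trees=50),
                                 return_models=True)
    print(f"{mode:13s} CV error {est.per_fold_errors[1]:.3f}   "
          f"true error {true_error(models[0], holdout):.3f}")
```

prints

```
record_wise   CV error 0.077   true error 0.310
subject_wise  CV error 0.250   true error 0.303
```

Record-wise CV claims ~8% error while the model's true error on new
subjects is ~31%; the subject-wise estimate (~25%, noisy with only 6
training subjects but unbiased in direction) tracks the truth.
The `examples/` directory has one narrative script per capability:

- `01_walking_speed_toy.py` — the deterministic four-subject walking-speed
  example (50% honest accuracy vs 100% under leakage, fold by fold);
- `02_simulated_bias.py` — the (b, c, S) error-surface experiment against
  the true-error holdout;
- `03_activity_recognition.py` — the fold/subject sweep on a synthetic
  activity-recognition fixture (readers for the real corpus layout
  included);
- `04_review_statistics.py` — CV-type rules, accuracy normalization, group
  medians, and the rank-sum comparison on a synthetic review table.

A thin CLI wraps the same functions: `cvleak toy`, `cvleak bias-grid
[--coarse]`, `cvleak har-sweep [--har-dir DIR]`, `cvleak fixture`, `cvleak
review [--table CSV]`.  Every run writes a `run_metadata.json` with resolved
parameters and seeds; reruns with the same seed are byte-identical.

See `docs/methods.md` for model assumptions, parameter meanings and
defaults, seeding, and what the synthetic generators do and do not emulate.

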