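"""Classifier training and error estimation under a fold assignment.

Three classifier families are supported:

``random_forest``
    scikit-learn ``RandomForestClassifier`` with 50 trees by default (the
    tree count used throughout the experiments); all other settings are the
    library defaults and are recorded in run metadata.
``midpoint_threshold``
    A population-trend rule for a single feature: compute the training class
    means and predict "diseased" iff the value is strictly below their
    midpoint (the slower-walkers-are-sick rule of the walking-speed example).
``nearest_record``
    1-nearest-neighbour over records (Euclidean distance, ties broken by the
    lowest training record index) — the memorizing learner that turns
    subject identification into apparent diagnosis under record-wise CV.

Errors are misclassification fractions.  ``cross_validate`` rotates over
folds (train on all but one, test on the held-out fold); ``repeat_cv`` runs
many repetitions with fresh folds (and fresh cohorts when given a generator)
and summarizes them with a 95% percentile interval; ``true_error`` scores
trained models on an independent holdout cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .cohort import DISEASED
from .errors import ConsistencyError, DegenerateTrainingError, ParameterError
from .splitting import CVScheme, FoldAssignment, make_folds

RANDOM_FOREST = "random_forest"
MIDPOINT_THRESHOLD = "midpoint_threshold"
NEAREST_RECORD = "nearest_record"

__all__ = [
    "RANDOM_FOREST",
    "MIDPOINT_THRESHOLD",
    "NEAREST_RECORD",
    "ClassifierSpec",
    "ErrorEstimate",
    "build_classifier",
    "cross_validate",
    "repeat_cv",
    "train_and_test",
    "true_error",
]


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = RANDOM_FOREST
    n_trees: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in (RANDOM_FOREST, MIDPOINT_THRESHOLD, NEAREST_RECORD):
            raise ParameterError(f"unknown classifier family {self.family!r}")
        if self.n_trees < 1:
            raise ParameterError(f"n_trees must be >= 1, got {self.n_trees}")

    def metadata(self) -> dict:
        meta = {"family": self.family, "seed": self.seed}
        if self.family == RANDOM_FOREST:
            meta["n_trees"] = self.n_trees
            meta["other_settings"] = "scikit-learn RandomForestClassifier defaults"
        return meta


@dataclass
class ErrorEstimate:
    """Misclassification summary.

    ``mean_error`` is the record-weighted mean of ``per_fold_errors`` (total
    misclassified over total tested).  After repeated runs,
    ``repetition_errors`` holds each repetition's mean error and ``ci95`` the
    2.5th/97.5th percentiles across repetitions.
    """

    per_fold_errors: list[float]
    mean_error: float
    ci95: tuple[float, float] | None = None
    repetition_errors: list[float] | None = None


class MidpointThreshold:
    """Single-feature rule: diseased iff value strictly below the class-mean midpoint."""

    def __init__(self, diseased_label=DISEASED):
        self.diseased_label = diseased_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] != 1:
            raise ParameterError("midpoint_threshold handles exactly one feature")
        labels = np.unique(y)
        if len(labels) != 2 or self.diseased_label not in labels:
            raise DegenerateTrainingError("midpoint_threshold needs both classes in training")
        self.n_features_in_ = 1
        self.healthy_label_ = labels[labels != self.diseased_label][0]
        self.midpoint_ = 0.5 * (
            X[y == self.diseased_label, 0].mean() + X[y == self.healthy_label_, 0].mean()
        )
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)[:, 0]
        # strict inequality: an exactly-midpoint value is called healthy
        return np.where(x < self.midpoint_, self.diseased_label, self.healthy_label_)


class NearestRecord:
    """1-NN over training records; distance ties go to the lowest record index."""

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y)
        self.n_features_in_ = self.X_.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        return self.y_[np.argmin(d2, axis=1)]  # argmin picks the first minimum


def build_classifier(spec: ClassifierSpec, seed: int | None = None):
    if spec.family == RANDOM_FOREST:
        rs = spec.seed if seed is None else seed
        return RandomForestClassifier(n_estimators=spec.n_trees, random_state=int(rs) % (2**31))
    if spec.family == MIDPOINT_THRESHOLD:
        return MidpointThreshold()
    return NearestRecord()


def _fit_model(spec: ClassifierSpec, X, y, seed: int | None = None):
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError(
            "training set contains a single class; re-stratify the folds")
    return build_classifier(spec, seed=seed).fit(X, y)


def _misclassification(model, X, y) -> float:
    return float(np.mean(model.predict(X) != np.asarray(y)))


def train_and_test(cohort, train_idx, test_idx, spec: ClassifierSpec, seed: int | None = None):
    """Fit one model on the given records and return (model, test error)."""
    model = _fit_model(spec, cohort.features[train_idx], cohort.labels[train_idx], seed=seed)
    return model, _misclassification(model, cohort.features[test_idx], cohort.labels[test_idx])


def cross_validate(cohort, assignment: FoldAssignment, spec: ClassifierSpec,
                   *, return_models: bool = False):
    """Train on all but one fold and test on the held-out fold, for every fold.

    ``mean_error`` aggregates over all test records (record-weighted), so it
    is invariant to fold relabeling.  With ``return_models=True`` also
    returns the per-fold fitted models for later holdout scoring.
    """
    if len(assignment.fold_of_record) != cohort.n_records:
        raise ConsistencyError(
            f"assignment covers {len(assignment.fold_of_record)} records, "
            f"cohort has {cohort.n_records}")
    per_fold, models = [], []
    n_wrong = 0
    for f in range(assignment.n_folds):
        test_idx = assignment.test_indices(f)
        train_idx = assignment.train_indices(f)
        fold_seed = int(np.random.SeedSequence((spec.seed, f)).generate_state(1)[0] >> 1)
        model, err = train_and_test(cohort, train_idx, test_idx, spec, seed=fold_seed)
        per_fold.append(err)
        n_wrong += err * len(test_idx)
        if return_models:
            models.append(model)
    estimate = ErrorEstimate(per_fold_errors=per_fold,
                             mean_error=float(n_wrong / cohort.n_records))
    return (estimate, models) if return_models else estimate


def repeat_cv(cohort_or_generator, scheme: CVScheme, spec: ClassifierSpec,
              n_repetitions: int, master_seed: int = 0) -> ErrorEstimate:
    """Repeat cross-validation with fresh fold assignments (and fresh cohorts
    when given a generator ``f(seed) -> cohort``).

    Returns the repetition mean errors, their overall mean, and the 95%
    percentile interval (2.5th/97.5th percentiles) across repetitions.
    """
    if n_repetitions < 2:
        raise ParameterError(f"n_repetitions must be >= 2, got {n_repetitions}")
    rep_errors = []
    for rep in range(n_repetitions):
        ss = np.random.SeedSequence((master_seed, rep))
        cohort_seed, fold_seed, clf_seed = (int(s) >> 1 for s in ss.generate_state(3))
        cohort = (cohort_or_generator(cohort_seed) if callable(cohort_or_generator)
                  else cohort_or_generator)
        rep_scheme = replace(scheme, seed=fold_seed)
        assignment = make_folds(cohort, rep_scheme)
        est = cross_validate(cohort, assignment, replace(spec, seed=clf_seed))
        rep_errors.append(est.mean_error)
    lo, hi = np.percentile(rep_errors, [2.5, 97.5])
    return ErrorEstimate(per_fold_errors=[], mean_error=float(np.mean(rep_errors)),
                         ci95=(float(lo), float(hi)), repetition_errors=rep_errors)


def true_error(models, holdout) -> float:
    """Mean misclassification of trained model(s) on an independent holdout cohort.

    When a CV run yields several fold-models, their holdout errors are
    averaged.  The holdout must be subject-disjoint from the training cohort
    (enforced upstream by construction) and feature-compatible.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    if not models:
        raise ParameterError("no trained models supplied")
    errs = []
    for model in models:
        expected = getattr(model, "n_features_in_", None)
        if expected is None and hasattr(model, "X_"):
            expected = model.X_.shape[1]
        if expected is not None and expected != holdout.n_features:
            raise ConsistencyError(
                f"model expects {expected} features, holdout has {holdout.n_features}")
        errs.append(_misclassification(model, holdout.features, holdout.labels))
    return float(np.mean(errs))
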