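"""Record-wise and subject-wise fold construction.

Record-wise folds are drawn over records irrespective of subject, so records
of the same subject can land in both training and test sets (subject-identity
leakage).  Subject-wise folds assign whole subjects, mirroring diagnosis of
previously unseen patients.  Both k-fold partitions and the 50/50 half-split
used by the simulation experiment are provided, along with a leakage auditor.

Conventions: fold sizes (records for record-wise, subjects for subject-wise)
differ by at most one, with any extra unit going to the lower-indexed fold.
For half-splits, fold 0 is the training half and fold 1 the test half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InfeasibleSplitError, ParameterError

RECORD_WISE = "record_wise"
SUBJECT_WISE = "subject_wise"
HALF_SPLIT = "half_split"

TRAIN_FOLD = 0
TEST_FOLD = 1

__all__ = [
    "RECORD_WISE",
    "SUBJECT_WISE",
    "HALF_SPLIT",
    "TRAIN_FOLD",
    "TEST_FOLD",
    "CVScheme",
    "FoldAssignment",
    "LeakageReport",
    "make_folds",
    "make_half_split",
    "verify_no_subject_leakage",
]


@dataclass(frozen=True)
class CVScheme:
    """How to partition a cohort.

    ``k_folds`` is an integer fold count or the token ``"half_split"`` for
    the 50/50 train/test design.  ``stratify`` applies to subject-wise
    k-folds only (half-splits always stratify subjects by class so that
    small designs keep both classes on each side).
    """

    mode: str
    k_folds: int | str = HALF_SPLIT
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if self.mode not in (RECORD_WISE, SUBJECT_WISE):
            raise ParameterError(f"mode must be {RECORD_WISE!r} or {SUBJECT_WISE!r}, got {self.mode!r}")
        if self.k_folds != HALF_SPLIT:
            if not isinstance(self.k_folds, (int, np.integer)) or self.k_folds < 2:
                raise ParameterError(f"k_folds must be >= 2 or {HALF_SPLIT!r}, got {self.k_folds!r}")


@dataclass
class FoldAssignment:
    """Mapping record index -> fold index in 0..k-1."""

    fold_of_record: np.ndarray
    scheme: CVScheme
    n_folds: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_record == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_record != fold)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of_record, minlength=self.n_folds)

    def to_frame(self, subject_ids: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "record_index": np.arange(len(self.fold_of_record)),
            "fold": self.fold_of_record,
        })
        if subject_ids is not None:
            df.insert(1, "subject_id", subject_ids)
        return df

    def to_csv(self, path: str | Path, subject_ids: np.ndarray | None = None) -> None:
        self.to_frame(subject_ids).to_csv(path, index=False)


@dataclass
class LeakageReport:
    ok: bool
    offending_subjects: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _deal(units: np.ndarray, k: int, rng: np.random.Generator) -> dict:
    """Shuffle units and deal them round-robin into k folds (extra to fold 0)."""
    order = rng.permutation(units)
    return {int(unit): i % k for i, unit in enumerate(order)}


def make_folds(cohort, scheme: CVScheme) -> FoldAssignment:
    """Build a k-fold assignment for ``cohort`` under ``scheme``.

    Record-wise: records are randomly dealt to folds (sizes differ by <= 1).
    Subject-wise: whole subjects are dealt, so no subject spans two folds;
    with ``scheme.stratify`` the deal interleaves classes so each fold's
    class mix stays as even as possible.
    """
    if scheme.k_folds == HALF_SPLIT:
        return make_half_split(cohort, scheme)
    k = int(scheme.k_folds)
    subject_ids = np.asarray(cohort.subject_ids)
    n_records = len(subject_ids)
    rng = np.random.default_rng(scheme.seed)

    if scheme.mode == RECORD_WISE:
        if k > n_records:
            raise InfeasibleSplitError(
                f"record_wise k={k} exceeds the {n_records} available records")
        order = rng.permutation(n_records)
        fold = np.empty(n_records, dtype=int)
        fold[order] = np.arange(n_records) % k
        return FoldAssignment(fold, scheme, k)

    subjects = cohort.subjects
    if k > len(subjects):
        raise InfeasibleSplitError(
            f"subject_wise k={k} exceeds the {len(subjects)} available subjects")
    if scheme.stratify:
        # deal each class's shuffled subjects cyclically, continuing the fold
        # counter across classes: every fold gets an even share of each class
        labels = np.array([cohort.subject_label(s) for s in subjects])
        fold_of_subject = {}
        counter = 0
        for lab in np.unique(labels):
            for s in rng.permutation(subjects[labels == lab]):
                fold_of_subject[int(s)] = counter % k
                counter += 1
    else:
        fold_of_subject = _deal(subjects, k, rng)
    fold = np.array([fold_of_subject[int(s)] for s in subject_ids])
    return FoldAssignment(fold, scheme, k)


def make_half_split(cohort, scheme: CVScheme) -> FoldAssignment:
    """50/50 split into fold 0 (train) and fold 1 (test).

    Record-wise splits record counts equal +-1 regardless of subject ids.
    Subject-wise splits subject counts equal +-1, stratified by class label
    so that class balance is preserved as closely as possible on each side.
    """
    subject_ids = np.asarray(cohort.subject_ids)
    n_records = len(subject_ids)
    rng = np.random.default_rng(scheme.seed)

    if scheme.mode == RECORD_WISE:
        if n_records < 2:
            raise InfeasibleSplitError(f"need >= 2 records to half-split, got {n_records}")
        order = rng.permutation(n_records)
        fold = np.ones(n_records, dtype=int)
        fold[order[: (n_records + 1) // 2]] = TRAIN_FOLD
        return FoldAssignment(fold, scheme, 2)

    subjects = cohort.subjects
    if len(subjects) < 2:
        raise InfeasibleSplitError(
            f"subject_wise half-split needs >= 2 subjects, got {len(subjects)}")
    labels = np.array([cohort.subject_label(s) for s in subjects])
    train_subjects: set[int] = set()
    # stratified: split each class's subjects in half, extra unit to the train side
    for lab in np.unique(labels):
        members = rng.permutation(subjects[labels == lab])
        train_subjects.update(int(s) for s in members[: (len(members) + 1) // 2])
    fold = np.where(np.isin(subject_ids, list(train_subjects)), TRAIN_FOLD, TEST_FOLD)
    return FoldAssignment(fold.astype(int), scheme, 2)


def verify_no_subject_leakage(assignment: FoldAssignment, cohort) -> LeakageReport:
    """Check whether any subject's records span more than one fold.

    Always true for subject-wise assignments by construction; for
    record-wise assignments this is a diagnostic of leakage, not an error.
    """
    subject_ids = np.asarray(cohort.subject_ids)
    if len(subject_ids) != len(assignment.fold_of_record):
        raise ConsistencyError(
            f"assignment covers {len(assignment.fold_of_record)} records "
            f"but cohort has {len(subject_ids)}")
    offenders = []
    for s in cohort.subjects:
        folds = np.unique(assignment.fold_of_record[subject_ids == s])
        if len(folds) > 1:
            offenders.append(int(s))
    return LeakageReport(ok=not offenders, offending_subjects=offenders)
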