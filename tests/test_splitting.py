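"""Fold-construction tests: partition invariants, leakage semantics, balance."""

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvleak.cohort import GenerativeParams, generate_cohort
from cvleak.errors import ConsistencyError, InfeasibleSplitError, ParameterError
from cvleak.splitting import (HALF_SPLIT, RECORD_WISE, SUBJECT_WISE, TEST_FOLD,
                              TRAIN_FOLD, CVScheme, FoldAssignment, make_folds,
                              make_half_split, verify_no_subject_leakage)


@dataclass
class FakeCohort:
    """Bare-bones record collection: just subject ids (and optional labels)."""

    subject_ids: np.ndarray
    subject_labels: dict | None = None

    @property
    def subjects(self):
        _, idx = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(idx)]

    def subject_label(self, s):
        return self.subject_labels[int(s)]


def make_fake(records_per_subject):
    """records_per_subject: list of record counts, one entry per subject."""
    ids = np.concatenate([np.full(r, s) for s, r in enumerate(records_per_subject)])
    return FakeCohort(subject_ids=ids)


class TestMakeFolds:
    def test_leave_one_subject_out_by_pigeonhole(self, small_cohort):
        k = len(small_cohort.subjects)
        a = make_folds(small_cohort, CVScheme(SUBJECT_WISE, k, seed=4))
        for f in range(k):
            assert len(np.unique(small_cohort.subject_ids[a.test_indices(f)])) == 1

    @pytest.mark.parametrize("mode", [RECORD_WISE, SUBJECT_WISE])
    @pytest.mark.parametrize("k", [2, 10, 30])
    def test_many_seeds_all_valid_on_thirty_subjects(self, mode, k):
        cohort = make_fake([3] * 30)
        n = len(cohort.subject_ids)
        seen = set()
        for seed in range(100):
            a = make_folds(cohort, CVScheme(mode, k, seed=seed))
            seen.add(tuple(a.fold_of_record))
            assert a.fold_sizes().sum() == n
            if mode == RECORD_WISE:
                sizes = a.fold_sizes()
            else:
                subj_fold = {int(s): a.fold_of_record[cohort.subject_ids == s][0]
                             for s in cohort.subjects}
                sizes = np.bincount(list(subj_fold.values()), minlength=k)
                assert verify_no_subject_leakage(a, cohort).ok
            assert sizes.max() - sizes.min() <= 1
        assert len(seen) == 100  # different seeds give distinct assignments

    def test_record_wise_two_folds_of_ten_records(self):
        a = make_folds(make_fake([5, 5]), CVScheme(RECORD_WISE, 2, seed=0))
        assert sorted(a.fold_sizes()) == [5, 5]

    @pytest.mark.parametrize("mode,k,records,match", [
        (RECORD_WISE, 11, [5, 5], "10 available records"),
        (SUBJECT_WISE, 3, [5, 5], "2 available subjects"),
    ])
    def test_infeasible_split_names_limit(self, mode, k, records, match):
        with pytest.raises(InfeasibleSplitError, match=match):
            make_folds(make_fake(records), CVScheme(mode, k, seed=0))

    def test_stratified_subject_wise_balances_classes_per_fold(self, small_cohort):
        # 8 subjects, 4 per class: every stratified 2-fold split must put
        # 2 subjects of each class in each fold
        for seed in range(20):
            a = make_folds(small_cohort, CVScheme(SUBJECT_WISE, 2, seed=seed,
                                                  stratify=True))
            for f in range(2):
                subs = np.unique(small_cohort.subject_ids[a.test_indices(f)])
                labs = [small_cohort.subject_label(s) for s in subs]
                assert sorted(labs) == [-1, -1, 1, 1]

    def test_deterministic_under_fixed_seed(self, small_cohort):
        scheme = CVScheme(RECORD_WISE, 4, seed=9)
        a, b = make_folds(small_cohort, scheme), make_folds(small_cohort, scheme)
        assert np.array_equal(a.fold_of_record, b.fold_of_record)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        records=st.lists(st.integers(1, 6), min_size=2, max_size=12),
        k=st.integers(2, 6),
        mode=st.sampled_from([RECORD_WISE, SUBJECT_WISE]),
        seed=st.integers(0, 2**16),
    )
    def test_partition_invariants(self, records, k, mode, seed):
        cohort = make_fake(records)
        n = len(cohort.subject_ids)
        limit = n if mode == RECORD_WISE else len(records)
        if k > limit:
            with pytest.raises(InfeasibleSplitError):
                make_folds(cohort, CVScheme(mode, k, seed=seed))
            return
        a = make_folds(cohort, CVScheme(mode, k, seed=seed))
        # union of folds covers every record exactly once
        assert len(a.fold_of_record) == n
        assert set(np.unique(a.fold_of_record)) <= set(range(k))
        assert a.fold_sizes().sum() == n
        if mode == SUBJECT_WISE:
            assert verify_no_subject_leakage(a, cohort).ok


class TestHalfSplit:
    def test_four_subjects_two_per_class_stratified(self, rng):
        cohort = FakeCohort(
            subject_ids=np.repeat([0, 1, 2, 3], 5),
            subject_labels={0: 1, 1: 1, 2: -1, 3: -1},
        )
        for seed in range(20):
            a = make_half_split(cohort, CVScheme(SUBJECT_WISE, HALF_SPLIT, seed=seed))
            for fold in (TRAIN_FOLD, TEST_FOLD):
                subs = np.unique(cohort.subject_ids[a.test_indices(fold)])
                assert len(subs) == 2
                assert sorted(cohort.subject_label(s) for s in subs) == [-1, 1]

    def test_two_records_one_each_side(self):
        a = make_half_split(make_fake([1, 1]), CVScheme(RECORD_WISE, HALF_SPLIT, seed=0))
        assert sorted(a.fold_sizes()) == [1, 1]

    def test_record_counts_equal_within_one(self):
        a = make_half_split(make_fake([3, 4]), CVScheme(RECORD_WISE, HALF_SPLIT, seed=1))
        sizes = a.fold_sizes()
        assert abs(sizes[0] - sizes[1]) <= 1
        assert sizes[TRAIN_FOLD] >= sizes[TEST_FOLD]  # extra record to the train side

    def test_each_subject_on_each_side_half_the_time(self, small_params):
        # Monte-Carlo uniformity: over many seeds each subject should appear
        # in the training half about 50% of the time
        cohort = generate_cohort(GenerativeParams(n_subjects=12, n_records_per_subject=2,
                                                  n_features=1, seed=0))
        n_seeds = 1000
        train_counts = np.zeros(12)
        for seed in range(n_seeds):
            a = make_half_split(cohort, CVScheme(SUBJECT_WISE, HALF_SPLIT, seed=seed))
            train_subjects = np.unique(cohort.subject_ids[a.test_indices(TRAIN_FOLD)])
            train_counts[train_subjects] += 1
        np.testing.assert_allclose(train_counts / n_seeds, 0.5, atol=0.06)


class TestLeakageReport:
    def test_subject_wise_never_leaks(self, small_cohort):
        a = make_folds(small_cohort, CVScheme(SUBJECT_WISE, 4, seed=3))
        report = verify_no_subject_leakage(a, small_cohort)
        assert report.ok and not report.offending_subjects

    def test_record_wise_on_two_subjects_leaks_both(self):
        # with 5 records per subject and a 2-fold record-wise split, the odds
        # that either subject's records all land on one side are ~2^-9
        cohort = make_fake([5, 5])
        a = make_folds(cohort, CVScheme(RECORD_WISE, 2, seed=0))
        report = verify_no_subject_leakage(a, cohort)
        assert not report.ok
        assert report.offending_subjects == [0, 1]

    def test_single_record_per_subject_cannot_leak(self):
        cohort = make_fake([1] * 8)
        a = make_folds(cohort, CVScheme(RECORD_WISE, 2, seed=0))
        assert verify_no_subject_leakage(a, cohort).ok

    def test_mismatched_record_counts_rejected(self, small_cohort):
        a = make_folds(small_cohort, CVScheme(RECORD_WISE, 2, seed=0))
        with pytest.raises(ConsistencyError):
            verify_no_subject_leakage(a, make_fake([2, 2]))


def test_scheme_validation():
    with pytest.raises(ParameterError):
        CVScheme("sideways", 2)
    with pytest.raises(ParameterError):
        CVScheme(RECORD_WISE, 1)


def test_assignment_csv(tmp_path, small_cohort):
    a = make_folds(small_cohort, CVScheme(RECORD_WISE, 4, seed=0))
    path = tmp_path / "folds.csv"
    a.to_csv(path, subject_ids=small_cohort.subject_ids)
    import pandas as pd
    df = pd.read_csv(path)
    assert list(df.columns) == ["record_index", "subject_id", "fold"]
    assert np.array_equal(df["fold"].to_numpy(), a.fold_of_record)
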