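"""Review-statistics tests: rule sets, normalization, medians, and the
rank-sum test against an exhaustive enumeration oracle."""

import itertools

import numpy as np
import pytest

from cvleak.errors import ParameterError
from cvleak.review import (CONFLICT, RECORD_WISE, SUBJECT_WISE, UNKNOWN,
                           ReviewRecord, ReviewTable, classify_cv_type,
                           make_review_fixture, normalize_reported_accuracy,
                           rank_sum_test, read_review_csv, summarize_review,
                           table_to_csv)


def rec(**kwargs):
    return ReviewRecord(paper_id="p", **kwargs)


class TestClassifyCvType:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(n_folds=100, n_subjects=20), RECORD_WISE),
        (dict(n_folds=10, n_subjects=20), UNKNOWN),      # folds <= subjects alone proves nothing
        (dict(uses_term_subject_wise_or_loso=True), SUBJECT_WISE),
        (dict(states_tested_on_unseen_subjects=True), SUBJECT_WISE),
        (dict(train_test_id_overlap="no"), SUBJECT_WISE),
        (dict(train_test_id_overlap="yes"), RECORD_WISE),
        (dict(states_random_record_split=True), RECORD_WISE),
        (dict(), UNKNOWN),
        (dict(uses_term_subject_wise_or_loso=True,
              states_random_record_split=True), CONFLICT),
        (dict(train_test_id_overlap="yes", n_folds=100, n_subjects=20,
              states_tested_on_unseen_subjects=True), CONFLICT),
    ])
    def test_rule_groups(self, kwargs, expected):
        assert classify_cv_type(rec(**kwargs)) == expected

    def test_total_over_flag_combinations(self):
        # the classifier must return a label for every boolean annotation combo
        for flags in itertools.product([False, True], repeat=3):
            for overlap in ("yes", "no", "unknown"):
                label = classify_cv_type(rec(
                    uses_term_subject_wise_or_loso=flags[0],
                    states_tested_on_unseen_subjects=flags[1],
                    states_random_record_split=flags[2],
                    train_test_id_overlap=overlap))
                assert label in (SUBJECT_WISE, RECORD_WISE, UNKNOWN, CONFLICT)


class TestNormalizeAccuracy:
    def test_single_accuracy_used_directly(self):
        assert normalize_reported_accuracy(rec(accuracy_values=(0.8,))).value == 0.8

    def test_mean_over_conditions(self):
        n = normalize_reported_accuracy(rec(accuracy_values=(0.8, 0.9),
                                            accuracy_multiplicity="conditions"))
        assert n.value == pytest.approx(0.85)
        assert n.rule == "mean_over_conditions"

    def test_max_over_classifiers(self):
        n = normalize_reported_accuracy(rec(accuracy_values=(0.8, 0.9),
                                            accuracy_multiplicity="classifiers"))
        assert n.value == 0.9

    def test_close_sensitivity_specificity_averaged(self):
        n = normalize_reported_accuracy(rec(sensitivity=0.90, specificity=0.91))
        assert n.value == pytest.approx(0.905)
        assert n.rule == "sensitivity_specificity_mean"

    def test_divergent_sensitivity_specificity_missing_with_reason(self):
        n = normalize_reported_accuracy(rec(sensitivity=0.70, specificity=0.95))
        assert n.missing
        assert "differ" in n.reason

    def test_f1_from_precision_recall(self):
        n = normalize_reported_accuracy(rec(precision=0.5, recall=0.5))
        assert n.value == pytest.approx(0.5)
        assert n.rule == "f1_substitute"

    def test_rmse_only_is_missing(self):
        assert normalize_reported_accuracy(rec(rmse_only=True)).missing

    def test_percent_and_fraction_dialects_agree(self):
        # the scale is declared, never guessed from magnitude
        as_pct = rec(accuracy_values=(92.5,), units="percent")
        as_frac = rec(accuracy_values=(0.925,), units="fraction")
        assert (normalize_reported_accuracy(as_pct).value
                == pytest.approx(normalize_reported_accuracy(as_frac).value))
        pct_pair = rec(sensitivity=90.0, specificity=91.0, units="percent")
        assert normalize_reported_accuracy(pct_pair).value == pytest.approx(0.905)

    def test_multiple_accuracies_need_declared_multiplicity(self):
        with pytest.raises(ParameterError):
            normalize_reported_accuracy(rec(accuracy_values=(0.8, 0.9)))

    def test_out_of_range_accuracy_rejected(self):
        with pytest.raises(ParameterError):
            normalize_reported_accuracy(rec(accuracy_values=(1.2,)))


class TestSummarize:
    def test_single_paper_median_is_its_value(self):
        table = ReviewTable([rec(uses_term_subject_wise_or_loso=True,
                                 accuracy_values=(0.9,), citations=4)])
        s = summarize_review(table)
        assert s.median_error[SUBJECT_WISE] == pytest.approx(0.1)
        assert s.median_citations[SUBJECT_WISE] == 4
        assert s.median_error[RECORD_WISE] is None

    def test_fixture_counts_and_proportion(self):
        s = summarize_review(make_review_fixture(seed=0))
        assert s.counts[RECORD_WISE] == 28
        assert s.counts[SUBJECT_WISE] == 34
        assert s.prop_record_wise == pytest.approx(28 / 62, abs=1e-9)
        assert s.group_sizes_with_accuracy == {SUBJECT_WISE: 25, RECORD_WISE: 22}

    def test_medians_match_sort_based_oracle(self):
        table = make_review_fixture(seed=1)
        s = summarize_review(table)
        df = table.derive().dropna(subset=["error"])
        for group in (SUBJECT_WISE, RECORD_WISE):
            vals = sorted(df[df.cv_type == group]["error"])
            n = len(vals)
            oracle = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
            assert s.median_error[group] == pytest.approx(oracle)

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            summarize_review(ReviewTable([]))


def enumerate_rank_sum_p(a, b):
    """Exhaustive two-tailed p: distribution of the Mann-Whitney U statistic
    over every assignment of the pooled values to the two groups."""
    pooled = np.array(list(a) + list(b))
    na = len(a)
    mid = na * len(b) / 2.0

    def u_stat(x, y):
        return sum(int(xi > yi) + 0.5 * int(xi == yi) for xi in x for yi in y)

    observed = abs(u_stat(a, b) - mid)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        total += 1
        if abs(u_stat(pooled[mask], pooled[~mask]) - mid) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_textbook_exact_case(self):
        # {1,2} vs {3,4}: only 2 of the 6 assignments are as extreme
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_constant_samples_give_p_one(self):
        assert rank_sum_test([0.5, 0.5], [0.5, 0.5, 0.5]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            rank_sum_test([], [1.0])

    def test_matches_enumeration_for_all_small_sizes(self, rng):
        # exhaustive check across every (n_a, n_b) with combined n <= 8,
        # distinct values (the exact-distribution regime)
        for na in range(1, 8):
            for nb in range(1, 9 - na):
                vals = rng.permutation(np.arange(1.0, na + nb + 1.0))
                a, b = vals[:na], vals[na:]
                assert rank_sum_test(a, b) == pytest.approx(
                    enumerate_rank_sum_p(a, b)), (na, nb)

    def test_large_sample_approximation_is_sane(self, rng):
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(1.5, 1.0, 40)
        assert rank_sum_test(a, b) < 1e-6
        same = rng.normal(0.0, 1.0, 40)
        assert rank_sum_test(a, same) > 0.01


class TestFixtureAndIO:
    def test_fixture_deterministic(self):
        t1, t2 = make_review_fixture(seed=3), make_review_fixture(seed=3)
        assert t1.records == t2.records

    def test_fixture_exercises_every_rule(self):
        rules = {normalize_reported_accuracy(r).rule
                 for r in make_review_fixture(seed=0).records}
        assert {"single_accuracy", "mean_over_conditions", "max_over_classifiers",
                "sensitivity_specificity_mean", "f1_substitute",
                "rmse_only"} <= rules

    def test_csv_round_trip(self, tmp_path):
        table = make_review_fixture(seed=0)
        path = tmp_path / "review.csv"
        table_to_csv(table, path)
        back = read_review_csv(path)
        assert summarize_review(back).median_error == summarize_review(table).median_error
        assert [r.paper_id for r in back.records] == [r.paper_id for r in table.records]

    def test_column_mapping(self, tmp_path):
        import pandas as pd
        pd.DataFrame({
            "id": ["a", "b"],
            "loso": [True, False],
            "rand_split": [False, True],
            "acc": ["0.9", "0.8"],
            "cites": [3, 1],
        }).to_csv(tmp_path / "t.csv", index=False)
        table = read_review_csv(tmp_path / "t.csv", column_map={
            "paper_id": "id",
            "uses_term_subject_wise_or_loso": "loso",
            "states_random_record_split": "rand_split",
            "accuracy_values": "acc",
            "citations": "cites",
        })
        s = summarize_review(table)
        assert s.counts == {SUBJECT_WISE: 1, RECORD_WISE: 1}
        assert s.median_error[RECORD_WISE] == pytest.approx(0.2)
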