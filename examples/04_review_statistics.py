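"""Systematic-review statistics on the bundled synthetic table.

Applies the computable review rules — CV-type classification from
annotations, accuracy normalization, group medians, and the two-tailed
Wilcoxon rank-sum comparison — to a synthetic 62-paper table shaped like a
real review export.  Swap in a real CSV with cvleak.review.read_review_csv.
"""

from cvleak.review import (RECORD_WISE, SUBJECT_WISE, make_review_fixture,
                           rank_sum_test, summarize_review)

table = make_review_fixture(seed=0)
summary = summarize_review(table)

print(f"papers: {summary.n_papers}")
print(f"counts by CV type: {summary.counts}")
print(f"proportion record-wise: {summary.prop_record_wise:.1%}")
for group in (SUBJECT_WISE, RECORD_WISE):
    print(f"{group}: median error {summary.median_error[group]:.1%} "
          f"(over {summary.group_sizes_with_accuracy[group]} papers with "
          f"extractable accuracy), median citations "
          f"{summary.median_citations[group]}")

df = table.derive().dropna(subset=["error"])
p = rank_sum_test(df[df.cv_type == SUBJECT_WISE]["error"],
                  df[df.cv_type == RECORD_WISE]["error"])
print(f"two-tailed rank-sum p: {p:.2g}")

print("""
The record-wise group's median reported error is roughly half the
subject-wise group's — papers using the leaky scheme look about twice as
accurate — and the difference is strongly significant.  These numbers come
from a synthetic fixture, not from real publications; the pipeline applies
identically to a real review export.
""")
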