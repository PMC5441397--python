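"""Error surfaces over cross- and within-subject variability.

For each grid cell (b, c, S) a fresh cohort is generated (a=0.5, d=0.1,
N=10, R=100 by default), split 50/50 both record-wise and subject-wise, a
classifier trained on the training half, and two numbers recorded per
scheme: the test-half error (what CV would report) and the error on an
independent 10-subject holdout cohort (the true error).  Averaging over
repetitions yields the bias surfaces: record-wise CV reports errors well
below both the subject-wise estimate and the truth, most severely at small
subject counts.

Per-cell seeds are derived from (master_seed, b, c, S, repetition), with the
scheme mixed in only for the split/classifier stream, so both schemes judge
the same cohort draw and results are independent of execution order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GenerativeParams, generate_cohort, generate_holdout
from .errors import InfeasibleSplitError, ParameterError
from .evaluation import ClassifierSpec, train_and_test, true_error
from .splitting import (HALF_SPLIT, RECORD_WISE, SUBJECT_WISE, TEST_FOLD,
                        TRAIN_FOLD, CVScheme, make_half_split)

__all__ = ["GridSpec", "BiasGridResult", "run_grid", "summarize_by_subjects"]

_SCHEME_CODE = {RECORD_WISE: 0, SUBJECT_WISE: 1}


def _default_b_values() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 2.0001, 0.1), 10))


@dataclass(frozen=True)
class GridSpec:
    """Configuration of the variability sweep.

    Defaults reproduce the full design: b, c in 0..2 step 0.1, subject
    counts 4..32, 10 repetitions per cell, a 10-subject holdout, a random
    forest with 50 trees.  Coarser grids are obtained by overriding the
    value lists.
    """

    b_values: tuple[float, ...] = field(default_factory=_default_b_values)
    c_values: tuple[float, ...] = field(default_factory=_default_b_values)
    subject_counts: tuple[int, ...] = (4, 8, 12, 16, 20, 24, 28, 32)
    n_repetitions: int = 10
    holdout_subjects: int = 10
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    master_seed: int = 0
    a: float = 0.5
    d: float = 0.1
    n_features: int = 10
    n_records_per_subject: int = 100

    def __post_init__(self) -> None:
        if any(v < 0 for v in (*self.b_values, *self.c_values)):
            raise ParameterError("b and c values must be >= 0")
        if self.n_repetitions < 1:
            raise ParameterError("n_repetitions must be >= 1")


@dataclass
class BiasGridResult:
    """Tidy per-repetition table plus a record of any skipped cells.

    ``table`` columns: b, c, n_subjects, scheme, repetition, cv_error,
    true_error.  ``skipped`` lists cells whose split was infeasible, with
    the reason — they are recorded, never silently dropped.
    """

    table: pd.DataFrame
    skipped: list[dict]
    spec: GridSpec

    def cell_means(self) -> pd.DataFrame:
        return (self.table
                .groupby(["b", "c", "n_subjects", "scheme"], as_index=False)
                [["cv_error", "true_error"]].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cell_seed(*entropy: int) -> int:
    return int(np.random.SeedSequence(entropy).generate_state(1)[0]) >> 1


def run_grid(spec: GridSpec) -> BiasGridResult:
    """Run the full (b, c, S, scheme, repetition) sweep."""
    rows, skipped = [], []
    for b, c, s in itertools.product(spec.b_values, spec.c_values, spec.subject_counts):
        bi, ci = int(round(b * 10)), int(round(c * 10))
        for rep in range(spec.n_repetitions):
            params = GenerativeParams(
                a=spec.a, b=float(b), c=float(c), d=spec.d,
                n_features=spec.n_features,
                n_records_per_subject=spec.n_records_per_subject,
                n_subjects=int(s),
                seed=_cell_seed(spec.master_seed, bi, ci, s, rep),
            )
            cohort = generate_cohort(params)
            holdout = generate_holdout(params, spec.holdout_subjects)
            for scheme_mode in (RECORD_WISE, SUBJECT_WISE):
                run_seed = _cell_seed(spec.master_seed, bi, ci, s, rep,
                                      _SCHEME_CODE[scheme_mode])
                scheme = CVScheme(mode=scheme_mode, k_folds=HALF_SPLIT, seed=run_seed)
                try:
                    assignment = make_half_split(cohort, scheme)
                except InfeasibleSplitError as exc:
                    skipped.append({"b": float(b), "c": float(c), "n_subjects": int(s),
                                    "scheme": scheme_mode, "repetition": rep,
                                    "reason": str(exc)})
                    continue
                model, cv_err = train_and_test(
                    cohort,
                    assignment.test_indices(TRAIN_FOLD),
                    assignment.test_indices(TEST_FOLD),
                    spec.classifier, seed=run_seed)
                rows.append({
                    "b": float(b), "c": float(c), "n_subjects": int(s),
                    "scheme": scheme_mode, "repetition": rep,
                    "cv_error": cv_err,
                    "true_error": true_error(model, holdout),
                })
    return BiasGridResult(table=pd.DataFrame(rows), skipped=skipped, spec=spec)


def summarize_by_subjects(result: BiasGridResult) -> pd.DataFrame:
    """Mean and standard deviation of error across the (b, c) grid, per
    subject count and scheme, with the record-wise-minus-subject-wise gap.

    Cell values are first averaged over repetitions; the mean/sd are then
    taken across (b, c) cells, matching a surface-level summary.
    """
    if result.table.empty:
        raise ParameterError("empty grid result")
    cells = result.cell_means()
    agg = (cells.groupby(["n_subjects", "scheme"])
           .agg(cv_error_mean=("cv_error", "mean"),
                cv_error_sd=("cv_error", "std"),
                true_error_mean=("true_error", "mean"),
                true_error_sd=("true_error", "std"))
           .reset_index())
    agg[["cv_error_sd", "true_error_sd"]] = agg[["cv_error_sd", "true_error_sd"]].fillna(0.0)
    wide = agg.pivot(index="n_subjects", columns="scheme", values="cv_error_mean")
    gap = (wide[RECORD_WISE] - wide[SUBJECT_WISE]).rename("record_minus_subject_gap")
    return agg.merge(gap.reset_index(), on="n_subjects")


def plot_error_surfaces(result: BiasGridResult, path=None):
    """Heat maps of mean CV error over (b, c), one panel per (S, scheme).

    Dark = 0, light = 1, mirroring the error-surface figure layout.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = result.cell_means()
    s_values = sorted(cells["n_subjects"].unique())
    fig, axes = plt.subplots(2, len(s_values),
                             figsize=(3 * len(s_values), 6), squeeze=False)
    for j, s in enumerate(s_values):
        for i, scheme in enumerate((RECORD_WISE, SUBJECT_WISE)):
            sub = cells[(cells.n_subjects == s) & (cells.scheme == scheme)]
            grid = sub.pivot(index="c", columns="b", values="cv_error")
            ax = axes[i][j]
            extent = None
            if grid.shape[0] > 1 and grid.shape[1] > 1:
                extent = [grid.columns.min(), grid.columns.max(),
                          grid.index.min(), grid.index.max()]
            ax.imshow(grid.to_numpy(), origin="lower", cmap="gray",
                      vmin=0, vmax=1, aspect="auto", extent=extent)
            ax.set_title(f"{scheme}, S={s}")
            ax.set_xlabel("b (cross-subject)")
            ax.set_ylabel("c (within-subject)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
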