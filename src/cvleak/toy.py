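"""The four-subject walking-speed thought experiment.

Two healthy subjects walk at constant 1.0 and 0.4 m/s; two Parkinson's
disease (PD) patients at 0.6 and 0.2 m/s; each contributes 10 identical
records of the scalar speed.  Disease and speed are confounded with subject
identity: a population-trend rule ("slower means PD") evaluated subject-wise
gets the slow healthy subject and the fast patient wrong (about 50%
accuracy), while record-wise leave-one-out lets a memorizing learner match
every record to its own subject's other records and score 100%.

The full 2x2 design (two splitting modes x two classifier families) is run
so the dependence of each headline number on its learner is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DISEASED, HEALTHY, SyntheticCohort
from .errors import ParameterError
from .evaluation import (MIDPOINT_THRESHOLD, NEAREST_RECORD, ClassifierSpec,
                         MidpointThreshold, cross_validate)
from .splitting import RECORD_WISE, SUBJECT_WISE, CVScheme, make_folds

SUBJECT_WISE_LOSO = "subject_wise_loso"
RECORD_WISE_LOO = "record_wise_loo"

# (speed m/s, class); healthy = -1, PD (diseased) = +1
TOY_SUBJECTS = ((1.0, HEALTHY), (0.4, HEALTHY), (0.6, DISEASED), (0.2, DISEASED))
RECORDS_PER_SUBJECT = 10

__all__ = [
    "SUBJECT_WISE_LOSO",
    "RECORD_WISE_LOO",
    "TOY_SUBJECTS",
    "ToyFoldOutcome",
    "build_toy_cohort",
    "run_toy",
    "toy_fold_outcomes",
    "toy_table",
]


def build_toy_cohort() -> SyntheticCohort:
    """40 records: 10 copies of each subject's constant walking speed."""
    speeds = np.repeat([s for s, _ in TOY_SUBJECTS], RECORDS_PER_SUBJECT)
    labels = np.repeat([lab for _, lab in TOY_SUBJECTS], RECORDS_PER_SUBJECT)
    return SyntheticCohort(
        subject_ids=np.repeat(np.arange(4), RECORDS_PER_SUBJECT),
        labels=labels.astype(int),
        features=speeds.reshape(-1, 1),
    )


def _scheme_for(scheme_mode: str) -> CVScheme:
    if scheme_mode == SUBJECT_WISE_LOSO:
        return CVScheme(mode=SUBJECT_WISE, k_folds=4, seed=0)
    if scheme_mode == RECORD_WISE_LOO:
        return CVScheme(mode=RECORD_WISE, k_folds=40, seed=0)
    raise ParameterError(f"scheme_mode must be {SUBJECT_WISE_LOSO!r} or {RECORD_WISE_LOO!r}")


def run_toy(scheme_mode: str, classifier_family: str) -> float:
    """Overall accuracy of one (splitting mode, classifier) cell.

    ``subject_wise_loso`` holds out each subject's 10 records in turn;
    ``record_wise_loo`` holds out each of the 40 records in turn.  The toy
    contains no randomness: every cell is a deterministic fraction.
    """
    if classifier_family not in (MIDPOINT_THRESHOLD, NEAREST_RECORD):
        raise ParameterError(f"classifier_family must be {MIDPOINT_THRESHOLD!r} or "
                             f"{NEAREST_RECORD!r}, got {classifier_family!r}")
    cohort = build_toy_cohort()
    assignment = make_folds(cohort, _scheme_for(scheme_mode))
    est = cross_validate(cohort, assignment, ClassifierSpec(family=classifier_family))
    return 1.0 - est.mean_error


@dataclass(frozen=True)
class ToyFoldOutcome:
    held_out_speed: float
    true_label: int
    predicted_label: int

    @property
    def correct(self) -> bool:
        return self.true_label == self.predicted_label


def toy_fold_outcomes() -> list[ToyFoldOutcome]:
    """Per-fold verdicts of subject-wise leave-one-subject-out with the
    midpoint-threshold rule, in subject order (1.0, 0.4, 0.6, 0.2 m/s)."""
    cohort = build_toy_cohort()
    outcomes = []
    for held_out in range(4):
        train = cohort.subject_ids != held_out
        model = MidpointThreshold().fit(cohort.features[train], cohort.labels[train])
        speed, true_label = TOY_SUBJECTS[held_out]
        pred = int(model.predict(np.array([[speed]]))[0])
        outcomes.append(ToyFoldOutcome(speed, true_label, pred))
    return outcomes


def toy_table() -> pd.DataFrame:
    """Accuracies of the full 2x2 design, as a (scheme x classifier) table."""
    rows = {}
    for mode in (SUBJECT_WISE_LOSO, RECORD_WISE_LOO):
        rows[mode] = {fam: run_toy(mode, fam)
                      for fam in (MIDPOINT_THRESHOLD, NEAREST_RECORD)}
    return pd.DataFrame(rows).T
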