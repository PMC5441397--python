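"""Generative model for subject-structured clinical cohorts.

Simulated datasets mimic the structure of wearable-sensor studies: each of S
subjects carries a binary disease state and contributes R records (feature
vectors of length N).  Feature values decompose into a disease (fixed) effect,
a cross-subject random effect, within-subject record noise, and a shared
population-level per-feature offset:

    y[s, r, n] = a * beta[s] + b * u[s, n] + c * v[s, r, n] + d * eps[n]

with beta[s] = +1 for diseased and -1 for healthy subjects, and u, v, eps
independent standard normal draws.  ``b`` and ``c`` set the proportions of
cross- and within-subject variability; ``d`` scales a per-feature offset drawn
once per cohort and shared by every subject and record.

The same model generates an independent holdout cohort that serves as the
true-error oracle when comparing cross-validation schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

DISEASED = 1
HEALTHY = -1

__all__ = [
    "DISEASED",
    "HEALTHY",
    "GenerativeParams",
    "SyntheticCohort",
    "generate_cohort",
    "generate_holdout",
    "subject_class_labels",
]


@dataclass(frozen=True)
class GenerativeParams:
    """Coefficients and counts of the generative model.

    Parameters
    ----------
    a : float
        Fixed (disease) effect size; the expected class-mean feature
        difference is ``2 * a``.
    b : float
        Cross-subject variability coefficient.
    c : float
        Within-subject variability coefficient.
    d : float
        Scale of the population-level per-feature offset.
    n_features, n_records_per_subject, n_subjects : int
        N, R, and S of the design.
    seed : int
        Master seed; independent sub-streams are spawned for u, v, eps and
        the holdout so that e.g. changing R does not perturb the u draws.
    """

    a: float = 0.5
    b: float = 1.0
    c: float = 1.0
    d: float = 0.1
    n_features: int = 10
    n_records_per_subject: int = 100
    n_subjects: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ParameterError(f"coefficient {name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_features", "n_records_per_subject", "n_subjects"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ParameterError(f"{name} must be a positive integer, got {value!r}")


@dataclass
class SyntheticCohort:
    """Long-format record set: one row per (subject, record).

    ``features`` has shape (S*R, N); rows are ordered subject-major.  All
    records of a subject share its class label.  ``latents`` retains the
    u, v, eps draws for testing the variance decomposition.
    """

    subject_ids: np.ndarray
    labels: np.ndarray
    features: np.ndarray
    params: GenerativeParams | None = None
    latents: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        """Distinct subject ids in order of first appearance."""
        _, idx = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(idx)]

    def subject_label(self, subject: int) -> int:
        return int(self.labels[self.subject_ids == subject][0])

    def subset(self, record_indices: np.ndarray) -> "SyntheticCohort":
        idx = np.asarray(record_indices)
        return SyntheticCohort(
            subject_ids=self.subject_ids[idx],
            labels=self.labels[idx],
            features=self.features[idx],
            params=self.params,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"f{i + 1}": self.features[:, i] for i in range(self.n_features)}
        return pd.DataFrame({"subject_id": self.subject_ids, "label": self.labels, **cols})

    def to_csv(self, path: str | Path) -> None:
        """Serialize records (not latents/params) losslessly to CSV."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SyntheticCohort":
        df = pd.read_csv(path, float_precision="round_trip")
        feat_cols = [c for c in df.columns if c.startswith("f")]
        return cls(
            subject_ids=df["subject_id"].to_numpy(dtype=int),
            labels=df["label"].to_numpy(dtype=int),
            features=df[feat_cols].to_numpy(dtype=float),
        )


def subject_class_labels(n_subjects: int) -> np.ndarray:
    """Per-subject class labels: floor(S/2) diseased (+1), the rest healthy (-1).

    For odd S the extra subject goes to the healthy class.
    """
    n_diseased = n_subjects // 2
    return np.concatenate(
        [np.full(n_diseased, DISEASED), np.full(n_subjects - n_diseased, HEALTHY)]
    ).astype(int)


def _assemble(params: GenerativeParams, beta: np.ndarray, seed_seq: np.random.SeedSequence,
              eps: np.ndarray | None, subject_offset: int = 0) -> SyntheticCohort:
    s, r, n = params.n_subjects, params.n_records_per_subject, params.n_features
    u_ss, v_ss, e_ss = seed_seq.spawn(3)
    u = np.random.default_rng(u_ss).standard_normal((s, n))
    v = np.random.default_rng(v_ss).standard_normal((s, r, n))
    if eps is None:
        eps = np.random.default_rng(e_ss).standard_normal(n)
    else:
        eps = np.asarray(eps, dtype=float)
        if eps.shape != (n,):
            raise ParameterError(f"shared eps must have shape ({n},), got {eps.shape}")

    y = (
        params.a * beta[:, None, None]
        + params.b * u[:, None, :]
        + params.c * v
        + params.d * eps[None, None, :]
    )
    return SyntheticCohort(
        subject_ids=np.repeat(np.arange(subject_offset, subject_offset + s), r),
        labels=np.repeat(beta, r),
        features=y.reshape(s * r, n),
        params=params,
        latents={"u": u, "v": v, "eps": eps, "beta": beta},
    )


def generate_cohort(params: GenerativeParams) -> SyntheticCohort:
    """Draw a cohort from the generative model.

    eps is drawn once per feature and shared by all subjects and records;
    u once per (subject, feature); v once per (subject, record, feature).
    Identical seeds give bit-identical cohorts.
    """
    master = np.random.SeedSequence(params.seed)
    cohort_ss, _holdout_ss = master.spawn(2)
    beta = subject_class_labels(params.n_subjects)
    return _assemble(params, beta, cohort_ss, eps=None)


def generate_holdout(
    params: GenerativeParams,
    n_holdout_subjects: int,
    *,
    share_eps: bool = False,
) -> SyntheticCohort:
    """Generate an independent cohort never touched by cross-validation.

    Same coefficients as the training cohort, fresh latent draws from a
    dedicated seed stream.  By default eps is also redrawn (the holdout is a
    genuinely new dataset); ``share_eps=True`` reuses the training cohort's
    per-feature offsets instead.  Holdout subject ids start above the
    training cohort's so the two are disjoint.
    """
    if n_holdout_subjects < 2:
        raise ParameterError(f"n_holdout_subjects must be >= 2, got {n_holdout_subjects}")
    master = np.random.SeedSequence(params.seed)
    _cohort_ss, holdout_ss = master.spawn(2)
    hold_params = replace(params, n_subjects=int(n_holdout_subjects))
    beta = subject_class_labels(n_holdout_subjects)
    eps = generate_cohort(params).latents["eps"] if share_eps else None
    return _assemble(hold_params, beta, holdout_ss, eps=eps,
                     subject_offset=params.n_subjects)
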