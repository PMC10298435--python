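"""Per-patient polypharmacy risk scores.

Two integer scores are computed from a patient's standardised active drug
set:

* **WARS** (Weighted Anticholinergic Risk Score) — the sum over the patient's
  drugs of their anticholinergic-burden class score,

  ``WARS = n_c1*1 + n_c2*2 + n_c3*3``,

  where ``n_ck`` counts the patient's drugs in ACB class *k*.  Drugs without
  an ACB listing contribute 0.

* **WIRS** (Weighted Interaction Risk Score) — the severity-weighted count of
  interacting unordered drug pairs,

  ``WIRS = n_mild*1 + n_moderate*2 + n_severe*3``,

  equivalently half the sum of the patient's symmetric interaction matrix
  (halving undoes the double count of each unordered pair).

The two scores are deliberately never combined into one number: they measure
different things (absolute anticholinergic burden vs relative pairwise
interaction risk) and are kept as separate clustering features.  All
arithmetic is integer and exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .knowledge import AcbTable, InteractionTable, canonical


@dataclass(frozen=True)
class PatientRecord:
    """One patient's standardised, deduplicated drug set."""

    patient_id: str
    drugs: frozenset[str]
    active: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(canonical(d) for d in self.drugs))


@dataclass(frozen=True)
class RiskProfile:
    """A patient's (WARS, WIRS) pair — the clustering features."""

    patient_id: str
    wars: int
    wirs: int

    def __post_init__(self) -> None:
        if self.wars < 0 or self.wirs < 0:
            raise ValueError("risk scores are non-negative")


class MatrixInvariantError(ValueError):
    """An interaction matrix is asymmetric or has a non-zero diagonal."""


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric per-patient interaction-severity matrix.

    Row/column order follows ``drugs``; cell (i, j) holds the severity of the
    (drug_i, drug_j) interaction, or 0 when none is listed.  The diagonal is
    zero — a drug does not interact with itself.
    """

    drugs: tuple[str, ...]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        object.__setattr__(self, "cells", cells)
        n = len(self.drugs)
        if cells.shape != (n, n):
            raise MatrixInvariantError(f"matrix shape {cells.shape} does not match {n} drugs")
        self.validate()

    def validate(self) -> None:
        if not np.array_equal(self.cells, self.cells.T):
            raise MatrixInvariantError("interaction matrix must be symmetric")
        if np.any(np.diag(self.cells) != 0):
            raise MatrixInvariantError("interaction matrix must have a zero diagonal")
        if not np.isin(self.cells, (0, 1, 2, 3)).all():
            raise MatrixInvariantError("severities must be in {0,1,2,3}")

    def nonzero_pairs(self) -> list[tuple[str, str, int]]:
        """Unordered interacting pairs, upper triangle only."""
        i_idx, j_idx = np.nonzero(np.triu(self.cells))
        return [(self.drugs[i], self.drugs[j], int(self.cells[i, j])) for i, j in zip(i_idx, j_idx)]


def compute_wars(record: PatientRecord, acb: AcbTable) -> int:
    """Weighted anticholinergic risk score for one patient."""
    return sum(acb.score(drug) for drug in record.drugs)


def build_interaction_matrix(record: PatientRecord, interactions: InteractionTable) -> InteractionMatrix:
    """Build the patient's symmetric interaction matrix over their drug set.

    Drug order is sorted for determinism.  A single-drug patient yields the
    1x1 zero matrix.
    """
    drugs = tuple(sorted(record.drugs))
    n = len(drugs)
    cells = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            severity = interactions.severity(drugs[i], drugs[j])
            cells[i, j] = cells[j, i] = severity
    return InteractionMatrix(drugs, cells)


def compute_wirs(matrix: InteractionMatrix) -> int:
    """Weighted interaction risk score: half the matrix sum.

    Computed both ways — half the full matrix sum, and the severity-weighted
    count of unordered pairs — and asserted equal; they must agree whenever
    the matrix invariants hold.
    """
    matrix.validate()
    half_sum = int(matrix.cells.sum()) // 2
    upper = np.triu(matrix.cells)
    weighted_pairs = sum(int(s) * int((upper == s).sum()) for s in (1, 2, 3))
    if half_sum != weighted_pairs:
        raise MatrixInvariantError(
            f"half-matrix-sum ({half_sum}) disagrees with weighted pair count ({weighted_pairs})"
        )
    return half_sum


def score_patient(record: PatientRecord, acb: AcbTable, interactions: InteractionTable) -> RiskProfile:
    wars = compute_wars(record, acb)
    wirs = compute_wirs(build_interaction_matrix(record, interactions))
    return RiskProfile(record.patient_id, wars, wirs)


def score_population(
    records: Iterable[PatientRecord],
    acb: AcbTable,
    interactions: InteractionTable,
) -> list[RiskProfile]:
    """Score every patient; order-preserving and deterministic."""
    return [score_patient(record, acb, interactions) for record in records]


def profiles_to_rows(profiles: Sequence[RiskProfile]) -> list[tuple[str, int, int]]:
    """Flatten profiles for delimited-text output (patient_id, wars, wirs)."""
    return [(p.patient_id, p.wars, p.wirs) for p in profiles]
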