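"""Patient × gene copy-number alteration matrices and coverage-driven panel selection.

The substrate is a binary matrix: entry (patient, gene) is 1 when the tumor
carries a copy-number alteration (amplification or deletion, collapsed — the
coverage criterion never uses direction) of that miRNA gene.  A candidate
diagnostic panel is scored by *patient coverage*: the fraction of patients
altered in at least one panel member, i.e. a weighted set-cover objective.

Panel optimization enumerates all k-subsets when the subset count is small
enough and otherwise falls back to greedy set cover (which carries the
classical (1 − 1/e) approximation guarantee).  Ties are always broken by
lexicographic gene symbol so results are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnknownStageError, UnknownSymbolError, ValidationError

STAGES = ("I", "II", "III", "IV")
UNKNOWN_STAGE = "unknown"
VALID_STAGE_LABELS = STAGES + (UNKNOWN_STAGE,)


@dataclass(frozen=True)
class AlterationMatrix:
    """Binary patients × genes alteration indicator with per-patient stage labels.

    ``data`` is indexed by patient id with one 0/1 column per gene symbol;
    ``stage`` maps each patient to a label in {I, II, III, IV, unknown}.
    """

    data: pd.DataFrame
    stage: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate patient ids in alteration matrix")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate gene symbols in alteration matrix")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValidationError("alteration matrix entries must be 0 or 1")
        if not self.stage.index.equals(self.data.index):
            raise ValidationError("stage labels must be indexed by the same patients")
        bad = set(self.stage.unique()) - set(VALID_STAGE_LABELS)
        if bad:
            raise ValidationError(
                f"invalid stage labels {sorted(bad)!r}; allowed: {VALID_STAGE_LABELS}"
            )
        data = self.data.astype(np.int8)
        data.index.name = "patient_id"
        stage = self.stage.copy()
        stage.index.name = "patient_id"
        stage.name = "stage"
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "stage", stage)

    @classmethod
    def from_arrays(
        cls,
        patient_ids: Sequence[str],
        gene_symbols: Sequence[str],
        altered: np.ndarray,
        stage: Sequence[str],
    ) -> "AlterationMatrix":
        data = pd.DataFrame(
            np.asarray(altered), index=list(patient_ids), columns=list(gene_symbols)
        )
        return cls(data=data, stage=pd.Series(list(stage), index=list(patient_ids)))

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data.index)


@dataclass(frozen=True)
class PanelEvaluation:
    """A gene panel together with its patient-coverage statistics."""

    panel: tuple[str, ...]
    n_covered: int
    n_patients: int

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_patients

    def to_json(self) -> dict:
        return {
            "panel": list(self.panel),
            "n_covered": self.n_covered,
            "n_patients": self.n_patients,
            "coverage": self.coverage,
        }


@dataclass(frozen=True)
class StageSets:
    """Per-tumor-stage sets of panel genes altered in at least one patient."""

    sets: dict[str, frozenset[str]]
    n_patients: dict[str, int]

    def to_json(self) -> dict:
        return {
            "n_patients": dict(self.n_patients),
            "sets": {stage: sorted(genes) for stage, genes in self.sets.items()},
        }


def _require_genes(matrix: AlterationMatrix, genes: Iterable[str]) -> list[str]:
    genes = list(genes)
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValidationError(f"duplicate gene symbols in panel: {dupes}")
    missing = [g for g in genes if g not in matrix.data.columns]
    if missing:
        raise UnknownSymbolError(f"genes absent from matrix: {missing}")
    return genes


def alteration_frequency(matrix: AlterationMatrix, gene: str) -> float:
    """Fraction of patients with an alteration of ``gene``."""
    if matrix.n_patients == 0:
        raise ValidationError("alteration matrix has no patients")
    if gene not in matrix.data.columns:
        raise UnknownSymbolError(f"gene {gene!r} absent from matrix")
    return float(matrix.data[gene].sum()) / matrix.n_patients


def filter_genes_by_frequency(
    matrix: AlterationMatrix, min_fraction: float = 0.10
) -> list[str]:
    """Genes altered in at least ``min_fraction`` of patients (inclusive), in column order."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValidationError(f"min_fraction must be in [0, 1], got {min_fraction}")
    if matrix.n_patients == 0:
        raise ValidationError("alteration matrix has no patients")
    freqs = matrix.data.sum(axis=0) / matrix.n_patients
    return list(matrix.data.columns[freqs >= min_fraction])


def panel_coverage(matrix: AlterationMatrix, panel: Sequence[str]) -> PanelEvaluation:
    """Evaluate a panel: a patient is covered iff altered in ≥1 panel gene."""
    if matrix.n_patients == 0:
        raise ValidationError("alteration matrix has no patients")
    genes = _require_genes(matrix, panel)
    if not genes:
        n_covered = 0
    else:
        n_covered = int(
            matrix.data[genes].to_numpy().any(axis=1).sum()
        )
    return PanelEvaluation(
        panel=tuple(genes), n_covered=n_covered, n_patients=matrix.n_patients
    )


def select_panel(
    matrix: AlterationMatrix,
    k: int,
    candidates: Sequence[str],
    exhaustive_limit: int = 100_000,
) -> PanelEvaluation:
    """Choose a k-gene panel from ``candidates`` maximizing patient coverage.

    If the number of k-subsets is at most ``exhaustive_limit``, every subset
    is enumerated and a maximal-coverage one is returned (the lexicographically
    smallest subset among ties).  Above the limit a greedy set cover is used:
    each step adds the gene covering the most still-uncovered patients, ties
    broken by lexicographic symbol; the greedy panel is returned in selection
    order.  ``k ≥ len(candidates)`` returns all candidates.
    """
    if not isinstance(k, int) or k < 1:
        raise ValidationError(f"panel size k must be a positive integer, got {k!r}")
    cand = _require_genes(matrix, candidates)
    if not cand:
        raise ValidationError("candidate gene list is empty")
    if k >= len(cand):
        return panel_coverage(matrix, cand)

    cols = {g: matrix.data[g].to_numpy(dtype=bool) for g in cand}
    if math.comb(len(cand), k) <= exhaustive_limit:
        best: tuple[str, ...] | None = None
        best_covered = -1
        for combo in combinations(sorted(cand), k):
            covered = int(np.logical_or.reduce([cols[g] for g in combo]).sum())
            if covered > best_covered:
                best, best_covered = combo, covered
        assert best is not None
        return panel_coverage(matrix, list(best))

    uncovered = np.ones(matrix.n_patients, dtype=bool)
    remaining = sorted(cand)
    chosen: list[str] = []
    for _ in range(k):
        best_gene, best_gain = None, -1
        for g in remaining:
            gain = int((cols[g] & uncovered).sum())
            if gain > best_gain:
                best_gene, best_gain = g, gain
        assert best_gene is not None
        chosen.append(best_gene)
        remaining.remove(best_gene)
        uncovered &= ~cols[best_gene]
    return panel_coverage(matrix, chosen)


def stage_alteration_sets(
    matrix: AlterationMatrix, panel: Sequence[str]
) -> StageSets:
    """For each tumor stage, the panel genes altered in ≥1 patient of that stage.

    Patients labelled ``unknown`` contribute to no stage set.  Every canonical
    stage appears in the result; a stage with zero patients maps to the empty
    set.
    """
    genes = _require_genes(matrix, panel)
    sets: dict[str, frozenset[str]] = {}
    counts: dict[str, int] = {}
    for stage in STAGES:
        patients = matrix.stage.index[matrix.stage == stage]
        counts[stage] = len(patients)
        if len(patients) == 0 or not genes:
            sets[stage] = frozenset()
            continue
        sub = matrix.data.loc[patients, genes]
        sets[stage] = frozenset(sub.columns[(sub != 0).any(axis=0)])
    return StageSets(sets=sets, n_patients=counts)


def stage_overlap(sets: StageSets, stage_a: str, stage_b: str) -> frozenset[str]:
    """Exact intersection of two stages' alteration sets."""
    for stage in (stage_a, stage_b):
        if stage not in sets.sets:
            raise UnknownStageError(
                f"stage {stage!r} not present; known stages: {sorted(sets.sets)}"
            )
    return sets.sets[stage_a] & sets.sets[stage_b]
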