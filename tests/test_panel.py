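import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exomir import (
    AlterationMatrix,
    UnknownStageError,
    UnknownSymbolError,
    ValidationError,
    alteration_frequency,
    filter_genes_by_frequency,
    panel_coverage,
    select_panel,
    stage_alteration_sets,
    stage_overlap,
)


def matrix_with_counts(counts: dict[str, int], n_patients: int = 109) -> AlterationMatrix:
    genes = list(counts)
    altered = np.zeros((n_patients, len(genes)), dtype=int)
    for j, gene in enumerate(genes):
        altered[: counts[gene], j] = 1
    return AlterationMatrix.from_arrays(
        [f"p{i}" for i in range(n_patients)], genes, altered, ["unknown"] * n_patients
    )


class TestAlterationFrequency:
    @pytest.mark.parametrize(
        "count,expected", [(0, 0.0), (109, 1.0), (11, 11 / 109)]
    )
    def test_direct_fraction(self, count, expected):
        matrix = matrix_with_counts({"gA": count})
        assert alteration_frequency(matrix, "gA") == pytest.approx(expected)

    def test_unknown_gene_and_empty_matrix_are_explicit_errors(self, toy_matrix):
        with pytest.raises(UnknownSymbolError):
            alteration_frequency(toy_matrix, "gX")
        empty = AlterationMatrix.from_arrays([], ["g1"], np.zeros((0, 1)), [])
        with pytest.raises(ValidationError):
            alteration_frequency(empty, "g1")


class TestFrequencyFilter:
    def test_ten_percent_threshold_is_inclusive(self):
        matrix = matrix_with_counts({"gKeep": 11, "gDrop": 10})
        assert filter_genes_by_frequency(matrix, 0.10) == ["gKeep"]

    def test_zero_threshold_keeps_all_in_column_order(self, toy_matrix):
        assert filter_genes_by_frequency(toy_matrix, 0.0) == ["g1", "g2", "g3"]

    def test_invalid_threshold(self, toy_matrix):
        with pytest.raises(ValidationError):
            filter_genes_by_frequency(toy_matrix, 1.5)


class TestPanelCoverage:
    def test_toy_unions(self, toy_matrix):
        assert panel_coverage(toy_matrix, []).coverage == 0.0
        single = panel_coverage(toy_matrix, ["g3"])
        assert (single.n_covered, single.coverage) == (2, 0.5)
        full = panel_coverage(toy_matrix, ["g1", "g2"])
        assert (full.n_covered, full.coverage) == (4, 1.0)

    def test_duplicates_and_missing_genes_rejected(self, toy_matrix):
        with pytest.raises(ValidationError):
            panel_coverage(toy_matrix, ["g1", "g1"])
        with pytest.raises(UnknownSymbolError, match="gX"):
            panel_coverage(toy_matrix, ["g1", "gX"])

    def test_single_gene_coverage_equals_frequency(self, toy_matrix):
        for gene in toy_matrix.gene_symbols:
            assert panel_coverage(toy_matrix, [gene]).coverage == pytest.approx(
                alteration_frequency(toy_matrix, gene)
            )

    def test_json_serialization(self, toy_matrix):
        payload = json.dumps(panel_coverage(toy_matrix, ["g1"]).to_json())
        assert json.loads(payload)["n_covered"] == 2


class TestSelectPanel:
    def test_exhaustive_finds_exact_cover(self, toy_matrix):
        best = select_panel(toy_matrix, 2, toy_matrix.gene_symbols)
        assert set(best.panel) == {"g1", "g2"} and best.coverage == 1.0

    def test_lexicographic_tie_break(self, toy_matrix):
        # g1, g2, g3 all cover 2 patients; the smallest symbol wins
        assert select_panel(toy_matrix, 1, toy_matrix.gene_symbols).panel == ("g1",)

    def test_k_at_least_candidates_returns_all(self, toy_matrix):
        assert select_panel(toy_matrix, 3, ["g2", "g1"]).panel == ("g2", "g1")

    def test_invalid_inputs(self, toy_matrix):
        with pytest.raises(ValidationError):
            select_panel(toy_matrix, 0, ["g1"])
        with pytest.raises(ValidationError):
            select_panel(toy_matrix, 1, [])

    def test_greedy_path_is_deterministic(self, toy_matrix):
        a = select_panel(toy_matrix, 2, toy_matrix.gene_symbols, exhaustive_limit=0)
        b = select_panel(toy_matrix, 2, toy_matrix.gene_symbols, exhaustive_limit=0)
        assert a == b


class TestStageSets:
    def test_unknown_stage_patients_are_excluded(self, toy_matrix):
        sets = stage_alteration_sets(toy_matrix, toy_matrix.gene_symbols)
        # p4 (g2-altered, unknown stage) contributes nowhere
        assert sets.sets["I"] == {"g1"}
        assert sets.sets["II"] == {"g1", "g2", "g3"}
        assert sets.sets["III"] == frozenset() and sets.n_patients["III"] == 0

    def test_overlap_and_idempotence(self, toy_matrix):
        sets = stage_alteration_sets(toy_matrix, toy_matrix.gene_symbols)
        assert stage_overlap(sets, "I", "II") == {"g1"}
        assert stage_overlap(sets, "II", "II") == sets.sets["II"]
        with pytest.raises(UnknownStageError):
            stage_overlap(sets, "I", "V")

    def test_union_of_stage_sets_is_subset_of_altered_genes(self, toy_matrix):
        sets = stage_alteration_sets(toy_matrix, toy_matrix.gene_symbols)
        union = frozenset().union(*sets.sets.values())
        altered = {
            g for g in toy_matrix.gene_symbols if alteration_frequency(toy_matrix, g) > 0
        }
        assert union <= altered


@st.composite
def random_matrix_and_panels(draw):
    n_patients = draw(st.integers(2, 12))
    n_genes = draw(st.integers(1, 6))
    bits = draw(
        st.lists(
            st.lists(st.integers(0, 1), min_size=n_genes, max_size=n_genes),
            min_size=n_patients,
            max_size=n_patients,
        )
    )
    genes = [f"g{j}" for j in range(n_genes)]
    matrix = AlterationMatrix.from_arrays(
        [f"p{i}" for i in range(n_patients)],
        genes,
        np.array(bits),
        ["unknown"] * n_patients,
    )
    small = draw(st.sets(st.sampled_from(genes)))
    extra = draw(st.sets(st.sampled_from(genes)))
    return matrix, sorted(small), sorted(small | extra)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_matrix_and_panels())
def test_coverage_is_monotone_in_panel_inclusion(case):
    matrix, small, large = case
    assert (
        panel_coverage(matrix, small).coverage <= panel_coverage(matrix, large).coverage
    )
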