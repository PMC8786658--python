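"""Truncal/branch/private classification, ITH index, Jaccard, relatedness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from imaclone.clonality import (
    JaccardMatrix,
    PresenceMatrix,
    RelatednessConfig,
    assess_relatedness,
    build_presence_matrix,
    classify_mutations,
    cohort_ith_median,
    jaccard_matrix,
)
from imaclone.rounding import round_half_even
from imaclone.variants import AnnotatedVariant, RegionCallset, VariantKey


def callset(patient, label, names):
    # symbolic variant names map to distinct positions deterministically
    variants = [
        AnnotatedVariant("chr1", 1000 + hash_name(name), "C", "T",
                         alt_count=20, depth=100, vaf=0.2)
        for name in names
    ]
    return RegionCallset(patient, label, variants, callable_mb=40.0)


def hash_name(name: str) -> int:
    return sum((i + 1) * ord(c) for i, c in enumerate(name)) % 100_000


def matrix_from(cells, patient="P", labels=None):
    cells = np.asarray(cells, dtype=np.uint8)
    r, v = cells.shape
    return PresenceMatrix(
        patient_id=patient,
        region_labels=labels or [f"R{i}" for i in range(r)],
        variant_keys=[VariantKey("chr1", 1000 + j, "C", "T") for j in range(v)],
        cells=cells,
    )


class TestPresenceMatrix:
    def test_union_and_column_sums(self):
        pm = build_presence_matrix([callset("P", "A", ["a", "b"]), callset("P", "B", ["b", "c"])])
        assert pm.cells.shape == (2, 3)
        assert sorted(pm.cells.sum(axis=0)) == [1, 1, 2]

    def test_identical_regions_all_ones(self):
        pm = build_presence_matrix([callset("P", "A", ["a", "b"]), callset("P", "B", ["a", "b"])])
        assert pm.cells.all()

    def test_single_region_rejected(self):
        with pytest.raises(ValueError, match="two regions"):
            build_presence_matrix([callset("P", "A", ["a"])])

    def test_mixed_patients_rejected(self):
        with pytest.raises(ValueError, match="patients"):
            build_presence_matrix([callset("P", "A", ["a"]), callset("Q", "B", ["a"])])

    def test_matches_simulator_truth(self, sim_loaded):
        cohort, truth = sim_loaded
        for pid, callsets in cohort.items():
            pm = build_presence_matrix(callsets)
            emitted = {t.key for t in truth.patients[pid].variants}
            assert set(pm.variant_keys) == emitted


class TestClassification:
    def test_definition(self):
        pm = matrix_from([[1, 1, 0], [1, 0, 1], [1, 0, 1]])
        table = classify_mutations(pm)
        keys = pm.variant_keys
        assert table.classes[keys[0]] == "truncal"
        assert table.classes[keys[1]] == "private"
        assert table.classes[keys[2]] == "branch"

    def test_ith_percent(self):
        # 24 truncal + 112 branch/private across 3 regions
        cells = np.zeros((3, 136), dtype=np.uint8)
        cells[:, :24] = 1
        cells[0, 24:80] = 1
        cells[1, 80:136] = 1
        table = classify_mutations(matrix_from(cells))
        assert (table.n_truncal, table.n_branch + table.n_private) == (24, 112)
        assert table.ith_percent == pytest.approx(100 * 112 / 136)
        assert table.ith_percent_reported == 82.4

    def test_ith_undefined_without_truncal(self):
        table = classify_mutations(matrix_from([[1, 0], [0, 1]]))
        assert table.n_truncal == 0
        assert table.ith_percent is None and table.ith_percent_reported is None


class TestJaccard:
    def test_hand_example(self):
        # A={a,b,c}, B={b,c,d} -> 2/4
        jac = jaccard_matrix(matrix_from([[1, 1, 1, 0], [0, 1, 1, 1]]))
        assert jac.pair("R0", "R1") == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        assert jaccard_matrix(matrix_from([[1, 1], [1, 1]])).pair("R0", "R1") == 1.0
        assert jaccard_matrix(matrix_from([[1, 0], [0, 1]])).pair("R0", "R1") == 0.0

    def test_empty_region_pair_flagged(self):
        pm = matrix_from([[1, 1], [0, 0], [0, 0]])
        jac = jaccard_matrix(pm)
        # an empty region against a non-empty one is 0, not undefined
        assert jac.pair("R0", "R1") == 0.0
        # two empty regions have an empty union: undefined and flagged
        assert math.isnan(jac.pair("R1", "R2"))
        assert ("R1", "R2") in jac.undefined_pairs
        assert math.isnan(jac.values[1, 1])  # empty region has no defined self-similarity

    def test_median_even_count_half_even(self):
        jm = JaccardMatrix(
            "P", ["A", "B", "C", "D"],
            values=np.array(
                [
                    [1.00, 0.49, 0.52, 0.01],
                    [0.49, 1.00, 0.60, 0.55],
                    [0.52, 0.60, 1.00, 0.58],
                    [0.01, 0.55, 0.58, 1.00],
                ]
            ),
        )
        # six pairs: 0.01 0.49 0.52 0.55 0.58 0.60 -> median 0.535
        assert jm.median == pytest.approx(0.535)
        assert jm.median_reported == 0.54

    def test_round_half_even_on_decimal_literal(self):
        assert round_half_even(0.505, 2) == 0.50
        assert round_half_even(0.295, 2) == 0.30
        assert round_half_even(0.515, 2) == 0.52


class TestCohortMedian:
    def test_study_values(self):
        assert cohort_ith_median([50, 49.1, 82.3, 65.4, 75.7, 70.7]) == 68.1

    def test_single_and_even(self):
        assert cohort_ith_median([50]) == 50
        assert cohort_ith_median([40, 60]) == 50

    def test_undefined_excluded(self):
        t_def = classify_mutations(matrix_from([[1, 1], [1, 0]]))
        t_undef = classify_mutations(matrix_from([[1, 0], [0, 1]]))
        assert cohort_ith_median([t_def, t_undef]) == t_def.ith_percent_reported
        with pytest.raises(ValueError):
            cohort_ith_median([t_undef])


class TestRelatedness:
    def _setup(self, cells):
        pm = matrix_from(cells)
        return pm, jaccard_matrix(pm)

    def test_low_jaccard_no_driver_unrelated(self):
        cells = np.zeros((2, 100), dtype=np.uint8)
        cells[0, :50] = 1
        cells[1, 50:] = 1
        cells[:, 0] = 1  # one shared non-driver variant -> J = 1/99
        pm, jac = self._setup(cells)
        verdict = assess_relatedness(pm, jac)
        assert verdict.pair("R0", "R1") == "unrelated"

    def test_shared_driver_related_despite_low_jaccard(self):
        cells = np.zeros((2, 100), dtype=np.uint8)
        cells[0, :50] = 1
        cells[1, 50:] = 1
        cells[:, 0] = 1
        pm, jac = self._setup(cells)
        gene_map = {pm.variant_keys[0]: "KRAS"}
        verdict = assess_relatedness(pm, jac, gene_map=gene_map)
        assert verdict.pair("R0", "R1") == "related"
        assert verdict.evidence[("R0", "R1")][1] == [pm.variant_keys[0]]

    def test_intermediate_jaccard_indeterminate(self):
        cells = np.zeros((2, 20), dtype=np.uint8)
        cells[0, :11] = 1
        cells[1, 9:] = 1  # intersection 2, union 20 -> J = 0.10
        pm, jac = self._setup(cells)
        assert jac.pair("R0", "R1") == pytest.approx(0.10)
        assert assess_relatedness(pm, jac).pair("R0", "R1") == "indeterminate"

    def test_high_jaccard_related(self):
        pm, jac = self._setup([[1, 1, 1, 0], [0, 1, 1, 1]])
        assert assess_relatedness(pm, jac).pair("R0", "R1") == "related"


@st.composite
def presence_cells(draw):
    r = draw(st.integers(2, 5))
    v = draw(st.integers(1, 20))
    cells = draw(
        arrays(np.uint8, (r, v), elements=st.integers(0, 1)).filter(
            lambda a: (a.sum(axis=0) > 0).all()
        )
    )
    return cells


@given(cells=presence_cells())
@settings(max_examples=60, deadline=None)
def test_jaccard_axioms_and_ith_complement(cells):
    pm = matrix_from(cells)
    jac = jaccard_matrix(pm)
    vals = jac.values
    assert np.allclose(vals, vals.T, equal_nan=True)
    finite = vals[~np.isnan(vals)]
    assert ((finite >= 0) & (finite <= 1)).all()
    for i in range(pm.n_regions):
        if cells[i].any():
            assert vals[i, i] == 1.0
    table = classify_mutations(pm)
    if table.ith_percent is not None:
        assert table.ith_percent + 100 * table.n_truncal / table.n_total == pytest.approx(100)
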