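"""Trunk/branch classification, ITH index and subtype comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrith import (Clonality, ITHResult, RegionObservation,
                   build_mutation_matrix, classify_trunk_branch,
                   compare_ithi_by_subtype, compute_ithi,
                   gene_frequency_table, Subtype, cohort_from_frame)

from conftest import matrix, patient
from oracles import mannwhitney_two_sided


def obs(key, region, alt_reads=10):
    return RegionObservation(key, region, alt_reads=alt_reads, depth=100)


class TestBuildMutationMatrix:
    def test_presence_rows(self):
        p = patient(n_regions=3)
        observations = [obs("A", r) for r in ("R1", "R2", "R3")] + [obs("B", "R2")]
        m = build_mutation_matrix(p, observations)
        assert m.variant_keys == ["A", "B"]
        assert m.presence.tolist() == [[1, 1, 1], [0, 1, 0]]

    def test_zero_alt_reads_not_present(self):
        p = patient(n_regions=2)
        m = build_mutation_matrix(p, [obs("A", "R1"), obs("A", "R2", alt_reads=0)])
        assert m.presence.tolist() == [[1, 0]]

    def test_variant_absent_everywhere_dropped(self):
        p = patient(n_regions=2)
        m = build_mutation_matrix(p, [obs("A", "R1"),
                                      obs("B", "R1", alt_reads=0)])
        assert m.variant_keys == ["A"]

    def test_observation_order_invariance(self):
        p = patient(n_regions=3)
        observations = [obs("A", "R1"), obs("B", "R2"), obs("A", "R3")]
        for perm in itertools.permutations(observations):
            m = build_mutation_matrix(p, list(perm))
            assert m.presence.tolist() == [[1, 0, 1], [0, 1, 0]]

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            build_mutation_matrix(patient(n_regions=2), [obs("A", "R9")])

    def test_countless_observation_counts_as_present(self):
        p = patient(n_regions=2)
        m = build_mutation_matrix(p, [RegionObservation("EGFR:CNV:AMP", "R2")])
        assert m.presence.tolist() == [[0, 1]]


class TestClassifyTrunkBranch:
    def test_all_regions_rule(self):
        labels = classify_trunk_branch(matrix([[1, 1, 1, 1], [1, 1, 0, 1]]))
        assert labels["m0"] is Clonality.TRUNK
        assert labels["m1"] is Clonality.BRANCH

    def test_single_region_all_trunk(self):
        labels = classify_trunk_branch(matrix([[1], [1], [1]]))
        assert set(labels.values()) == {Clonality.TRUNK}

    def test_exhaustive_small_matrices_match_literal_rule(self):
        # every binary matrix with <= 3 mutations x <= 3 regions
        for n_regions in (1, 2, 3):
            patterns = [p for p in itertools.product((0, 1), repeat=n_regions)
                        if any(p)]
            for n_mut in (1, 2, 3):
                for rows in itertools.product(patterns, repeat=n_mut):
                    labels = classify_trunk_branch(matrix(list(rows)))
                    for key, row in zip(labels, rows):
                        expected = (Clonality.TRUNK if all(row)
                                    else Clonality.BRANCH)
                        assert labels[key] is expected


class TestComputeIthi:
    @pytest.mark.parametrize("n_trunk,n_branch,expected",
                             [(10, 0, 0.0), (0, 5, 1.0), (6, 4, 0.4)])
    def test_branch_fraction(self, n_trunk, n_branch, expected):
        labels = {f"t{i}": Clonality.TRUNK for i in range(n_trunk)}
        labels |= {f"b{i}": Clonality.BRANCH for i in range(n_branch)}
        assert compute_ithi(labels).ithi == pytest.approx(expected)

    def test_zero_mutations_undefined(self):
        with pytest.raises(ValueError, match="zero mutations"):
            compute_ithi({})

    @given(st.lists(st.lists(st.integers(0, 1), min_size=2, max_size=4),
                    min_size=1, max_size=6).filter(
                        lambda rows: len({len(r) for r in rows}) == 1
                        and all(any(r) for r in rows)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_invariant_under_mutation_and_region_reordering(self, rows):
        m = matrix(rows)
        base = compute_ithi(classify_trunk_branch(m)).ithi
        rng = np.random.default_rng(0)
        perm_rows = rng.permutation(len(rows))
        perm_cols = rng.permutation(len(rows[0]))
        shuffled = [[rows[i][j] for j in perm_cols] for i in perm_rows]
        assert compute_ithi(classify_trunk_branch(matrix(shuffled))).ithi == base

    def test_adding_region_monotonicity(self):
        rows = [[1, 1, 0], [1, 1, 1]]
        base = classify_trunk_branch(matrix(rows))
        # a region carrying every mutation changes nothing
        extended = classify_trunk_branch(matrix([r + [1] for r in rows]))
        assert extended == base
        # a region carrying none turns every trunk into branch
        empty = classify_trunk_branch(matrix([r + [0] for r in rows]))
        assert set(empty.values()) == {Clonality.BRANCH}


def _groups(values_a, values_b):
    """Build ITHResult/PatientRecord dicts realizing the given ITHi values
    (all values must be multiples of 0.05)."""
    results, patients = {}, {}
    for g, (values, subtype) in enumerate(
            [(values_a, Subtype.EGFR_LUAD), (values_b, Subtype.LUSC)]):
        for i, v in enumerate(values):
            pid = f"G{g}P{i}"
            n_branch = round(v * 20)
            results[pid] = ITHResult(pid, 20 - n_branch, n_branch)
            patients[pid] = patient(pid, 3, subtype)
    return results, patients


class TestCompareIthiBySubtype:
    def test_identical_groups_p_one(self):
        results, patients = _groups([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        cmp = compare_ithi_by_subtype(results, patients,
                                      {Subtype.EGFR_LUAD}, {Subtype.LUSC})
        assert cmp.pvalue == pytest.approx(1.0)

    def test_worked_exact_example(self):
        results, patients = _groups([0.9, 0.8, 0.7], [0.1, 0.2])
        cmp = compare_ithi_by_subtype(results, patients,
                                      {Subtype.EGFR_LUAD}, {Subtype.LUSC})
        assert cmp.pvalue == pytest.approx(0.2)
        assert cmp.median_a == pytest.approx(0.8)
        assert (cmp.n_a, cmp.n_b) == (3, 2)

    def test_minimal_attainable_p_six_vs_six(self):
        from math import comb
        results, patients = _groups([1.0, 0.9, 0.8, 0.7, 0.6, 0.55],
                                    [0.5, 0.4, 0.3, 0.2, 0.1, 0.0])
        cmp = compare_ithi_by_subtype(results, patients,
                                      {Subtype.EGFR_LUAD}, {Subtype.LUSC})
        assert cmp.pvalue == pytest.approx(2 / comb(12, 6))

    def test_exact_matches_enumeration_for_small_n(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            n1 = int(rng.integers(1, n))
            values = rng.choice(np.arange(0, 11), size=n, replace=False) / 10
            results, patients = _groups(values[:n1], values[n1:])
            cmp = compare_ithi_by_subtype(results, patients,
                                          {Subtype.EGFR_LUAD}, {Subtype.LUSC})
            oracle = mannwhitney_two_sided(list(values[:n1]), list(values[n1:]))
            assert cmp.pvalue == pytest.approx(oracle)

    def test_empty_group_rejected(self):
        results, patients = _groups([0.5], [])
        with pytest.raises(ValueError, match="non-empty"):
            compare_ithi_by_subtype(results, patients,
                                    {Subtype.EGFR_LUAD}, {Subtype.LUSC})

    def test_single_region_patients_excluded(self):
        results, patients = _groups([0.9, 0.8], [0.1, 0.2])
        patients["G0P0"] = patient("G0P0", 1, Subtype.EGFR_LUAD)
        cmp = compare_ithi_by_subtype(results, patients,
                                      {Subtype.EGFR_LUAD}, {Subtype.LUSC})
        assert cmp.n_a == 1


class TestGeneFrequency:
    def _cohort(self, assignments):
        """assignments: list of (patient, region, gene) tuples."""
        import pandas as pd

        rows = [dict(patient_id=p, region_id=r, subtype="WT_LUAD", chrom="chr1",
                     pos=i + 1, ref="A", alt="T", gene=g, vclass="SNV",
                     vaf=0.2, alt_reads=40, depth=200)
                for i, (p, r, g) in enumerate(assignments)]
        return cohort_from_frame(pd.DataFrame(rows))

    def test_strict_threshold_boundary(self):
        assignments = [(f"P{i}", "R1", "OTHER") for i in range(10)]
        assignments.append(("P0", "R1", "KEAP1"))
        df = gene_frequency_table(self._cohort(assignments))
        row = df[df.gene == "KEAP1"].iloc[0]
        assert row.fraction == pytest.approx(0.10)
        assert not row.recurrent

    def test_patient_counts_once_across_regions(self):
        assignments = [("P1", "R1", "TP53"), ("P1", "R2", "TP53"),
                       ("P2", "R1", "OTHER")]
        df = gene_frequency_table(self._cohort(assignments))
        assert df[df.gene == "TP53"].n_patients.iloc[0] == 1

    def test_two_of_five_included(self):
        assignments = [(f"P{i}", "R1", "OTHER") for i in range(5)]
        assignments += [("P0", "R1", "STK11"), ("P1", "R1", "STK11")]
        df = gene_frequency_table(self._cohort(assignments))
        row = df[df.gene == "STK11"].iloc[0]
        assert row.fraction == pytest.approx(0.4)
        assert row.recurrent
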