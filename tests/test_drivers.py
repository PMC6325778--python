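"""Driver annotation, composition tests and the dominance score."""

import pandas as pd
import pytest

from mrith import (Clonality, DriverCatalog, Subtype, annotate_mutations,
                   cohort_from_frame, composition_table, compute_dominance,
                   SimulationConfig, simulate_cohort,
                   build_mutation_matrix, classify_trunk_branch)
from mrith.drivers import MutationAnnotation
from mrith.io import DriverRole

from conftest import patient
from oracles import binomial_two_sided


CATALOG = DriverCatalog({"EGFR": DriverRole.ONCOGENE, "TP53": DriverRole.TSG})


def _cohort(gene_rows):
    """gene_rows: (patient, region, gene[, pos]) tuples -> one SNV row each;
    rows sharing a position are the same variant seen in several regions."""
    rows = [dict(patient_id=t[0], region_id=t[1], subtype="WT_LUAD",
                 chrom="chr1", pos=t[3] if len(t) > 3 else i + 1,
                 ref="A", alt="T", gene=t[2], vclass="SNV",
                 vaf=0.2, alt_reads=40, depth=200)
            for i, t in enumerate(gene_rows)]
    return cohort_from_frame(pd.DataFrame(rows))


def ann(pid, key, gene, role, clonality):
    return MutationAnnotation(pid, key, gene,
                              role is not DriverRole.PASSENGER, role, clonality)


class TestAnnotate:
    def _labels(self, cohort):
        return {pid: classify_trunk_branch(build_mutation_matrix(
                    cohort.patients[pid], cohort.observations[pid]))
                for pid in cohort.patients}

    def test_catalog_roles_and_clonality_copied(self):
        cohort = _cohort([("P1", "R1", "EGFR", 500), ("P1", "R2", "EGFR", 500),
                          ("P1", "R1", "NOVEL")])
        annotations = annotate_mutations(cohort, CATALOG, self._labels(cohort))
        by_gene = {a.gene: a for a in annotations}
        assert by_gene["EGFR"].role is DriverRole.ONCOGENE
        assert by_gene["EGFR"].clonality is Clonality.TRUNK
        assert by_gene["NOVEL"].role is DriverRole.PASSENGER
        assert not by_gene["NOVEL"].is_driver
        assert by_gene["NOVEL"].clonality is Clonality.BRANCH

    def test_empty_catalog_all_passenger(self):
        cohort = _cohort([("P1", "R1", "EGFR")])
        annotations = annotate_mutations(cohort, DriverCatalog(),
                                         self._labels(cohort))
        assert all(not a.is_driver for a in annotations)


class TestComposition:
    def _patients(self, pids, subtype=Subtype.WT_LUAD):
        return {pid: patient(pid, 3, subtype) for pid in pids}

    def test_exact_binomial_worked_example(self):
        annotations = (
            [ann("P1", f"d{i}", "EGFR", DriverRole.ONCOGENE, Clonality.TRUNK)
             for i in range(8)]
            + [ann("P1", f"p{i}", "X", DriverRole.PASSENGER, Clonality.TRUNK)
               for i in range(2)])
        df = composition_table(annotations, self._patients(["P1"]))
        row = df[(df.group == "ALL") & (df.compartment == "trunk")].iloc[0]
        assert row.pct_driver == pytest.approx(80.0)
        assert row.p_binomial == pytest.approx(0.109375)
        assert row.p_binomial == pytest.approx(binomial_two_sided(8, 10))

    def test_even_split_p_one(self):
        annotations = (
            [ann("P1", f"d{i}", "EGFR", DriverRole.ONCOGENE, Clonality.BRANCH)
             for i in range(5)]
            + [ann("P1", f"p{i}", "X", DriverRole.PASSENGER, Clonality.BRANCH)
               for i in range(5)])
        df = composition_table(annotations, self._patients(["P1"]))
        row = df[(df.group == "ALL") & (df.compartment == "branch")].iloc[0]
        assert row.p_binomial == pytest.approx(1.0)

    def test_empty_compartment_absent(self):
        annotations = [ann("P1", "k", "EGFR", DriverRole.ONCOGENE,
                           Clonality.BRANCH)]
        df = composition_table(annotations, self._patients(["P1"]))
        assert "trunk" not in set(df.compartment)

    def test_proportions_sum_to_one_and_order_invariant(self):
        annotations = (
            [ann("P1", f"d{i}", "TP53", DriverRole.TSG, Clonality.TRUNK)
             for i in range(3)]
            + [ann("P2", f"p{i}", "Y", DriverRole.PASSENGER, Clonality.TRUNK)
               for i in range(4)])
        patients = self._patients(["P1", "P2"])
        df1 = composition_table(annotations, patients)
        df2 = composition_table(annotations[::-1], patients)
        row = df1[(df1.group == "ALL")].iloc[0]
        assert row.n_driver + row.n_passenger == 7
        pd.testing.assert_frame_equal(df1, df2)

    def test_oncogene_tsg_split_among_drivers(self):
        annotations = (
            [ann("P1", f"o{i}", "EGFR", DriverRole.ONCOGENE, Clonality.TRUNK)
             for i in range(3)]
            + [ann("P1", "t0", "TP53", DriverRole.TSG, Clonality.TRUNK)])
        df = composition_table(annotations, self._patients(["P1"]))
        row = df[df.group == "ALL"].iloc[0]
        assert row.n_oncogene == 3 and row.n_tsg == 1
        assert row.pct_oncogene == pytest.approx(75.0)
        assert row.p_binomial_role == pytest.approx(binomial_two_sided(3, 4))


class TestDominance:
    def _annotations(self, patient_driver_genes):
        out = []
        for pid, genes in patient_driver_genes.items():
            for i, g in enumerate(genes):
                role = (DriverRole.ONCOGENE if g in ("EGFR", "KRAS")
                        else DriverRole.TSG)
                out.append(ann(pid, f"{pid}k{i}", g, role, Clonality.TRUNK))
        return out

    def test_sole_driver_scores_one(self):
        anns = self._annotations({f"P{i}": ["EGFR"] for i in range(4)})
        (score,) = compute_dominance(anns, 8)
        assert score.score == pytest.approx(1.0)
        assert score.carrier_fraction == pytest.approx(0.5)

    def test_constant_single_codriver_half(self):
        anns = self._annotations({"P1": ["EGFR", "TP53"], "P2": ["EGFR", "RB1"]})
        scores = {s.gene: s for s in compute_dominance(anns, 2)}
        assert scores["EGFR"].score == pytest.approx(0.5)

    def test_mixed_carriers_seven_twelfths(self):
        anns = self._annotations({
            "P1": ["EGFR"],
            "P2": ["EGFR", "TP53"],
            "P3": ["EGFR", "TP53", "RB1", "KRAS"],
        })
        scores = {s.gene: s for s in compute_dominance(anns, 3)}
        assert scores["EGFR"].score == pytest.approx(7 / 12)

    def test_duplicate_mutations_in_gene_count_once(self):
        anns = self._annotations({"P1": ["EGFR", "EGFR", "TP53"]})
        scores = {s.gene: s for s in compute_dominance(anns, 1)}
        assert scores["EGFR"].score == pytest.approx(0.5)

    def test_removing_codriver_never_decreases_score(self):
        base = {"P1": ["EGFR", "TP53", "RB1"], "P2": ["EGFR", "TP53"],
                "P3": ["EGFR"]}
        before = {s.gene: s.score for s in
                  compute_dominance(self._annotations(base), 3)}
        base["P1"].remove("RB1")
        after = {s.gene: s.score for s in
                 compute_dominance(self._annotations(base), 3)}
        assert after["EGFR"] >= before["EGFR"]
        assert after["TP53"] >= before["TP53"]

    def test_codriver_free_subtype_driver_dominates_in_simulation(self):
        # EGFR-mutant patients get only their forced EGFR driver
        config = SimulationConfig(seed=9, driver_prob={
            Subtype.EGFR_LUAD: 0.0, Subtype.KRAS_LUAD: 0.6,
            Subtype.WT_LUAD: 0.6, Subtype.LUSC: 0.6, Subtype.LELC: 0.6})
        sim = simulate_cohort(config)
        cohort = cohort_from_frame(sim.tissue)
        catalog = DriverCatalog({g: DriverRole(r) for g, r in
                                 sim.drivers.itertuples(index=False)})
        labels = {pid: classify_trunk_branch(build_mutation_matrix(
                      cohort.patients[pid], cohort.observations[pid]))
                  for pid in cohort.patients}
        anns = annotate_mutations(cohort, catalog, labels)
        scores = {s.gene: s.score for s in
                  compute_dominance(anns, len(cohort.patients))}
        assert all(scores["EGFR"] > v for g, v in scores.items() if g != "EGFR")
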