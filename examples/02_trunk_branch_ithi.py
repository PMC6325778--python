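"""Trunk/branch classification and the ITH index, per patient and by subtype.

A mutation shared by every sampled region of a tumor is clonal ("trunk");
one missing from any region is subclonal ("branch"). The ITH index
ithi = branch / (trunk + branch) is 0 for a fully clonal tumor and rises as
the trunk fraction falls.
"""

from mrith import (SimulationConfig, Subtype, build_mutation_matrix,
                   classify_trunk_branch, cohort_from_frame,
                   compare_ithi_by_subtype, compute_ithi, simulate_cohort)

cohort = cohort_from_frame(simulate_cohort(SimulationConfig(seed=42)).tissue)

results = {}
for pid in sorted(cohort.patients):
    matrix = build_mutation_matrix(cohort.patients[pid],
                                   cohort.observations[pid])
    labels = classify_trunk_branch(matrix)
    results[pid] = compute_ithi(labels, pid)

first = results["P001"]
print(f"{first.patient_id}: {first.n_trunk} trunk + {first.n_branch} branch "
      f"mutations -> ITHi = {first.ithi:.3f}")

cmp = compare_ithi_by_subtype(
    results, cohort.patients,
    {Subtype.EGFR_LUAD}, {Subtype.KRAS_LUAD, Subtype.WT_LUAD})
print(f"\nEGFR-mutant LUAD median ITHi  {cmp.median_a:.3f} (n={cmp.n_a})")
print(f"other LUAD median ITHi        {cmp.median_b:.3f} (n={cmp.n_b})")
print(f"Mann-Whitney two-sided p = {cmp.pvalue:.4f} ({cmp.method})")
print("\nA small p with a higher EGFR median says EGFR-mutant tumors carry "
      "proportionally fewer clonal (trunk) mutations than the other LUADs.")
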