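"""Driver/passenger composition of trunks and branches, and driver dominance.

Drivers come from a gene catalog (oncogene vs TSG); the composition table
tests each trunk/branch compartment for driver enrichment against an even
split (exact binomial). The dominance score of a driver gene is the mean of
1/(distinct mutated driver genes) over its carriers: 1 means the gene is
always the sole driver, lower means it needs co-drivers.
"""

from mrith import (DriverCatalog, DriverRole, SimulationConfig,
                   annotate_mutations, build_mutation_matrix,
                   classify_trunk_branch, cohort_from_frame,
                   composition_table, compute_dominance, simulate_cohort)

sim = simulate_cohort(SimulationConfig(seed=42))
cohort = cohort_from_frame(sim.tissue)
catalog = DriverCatalog({g: DriverRole(r)
                         for g, r in sim.drivers.itertuples(index=False)})

labels = {pid: classify_trunk_branch(build_mutation_matrix(
              cohort.patients[pid], cohort.observations[pid]))
          for pid in cohort.patients}
annotations = annotate_mutations(cohort, catalog, labels)

table = composition_table(annotations, cohort.patients)
overall = table[table.group == "ALL"]
print(overall[["compartment", "n_driver", "n_passenger", "pct_driver",
               "p_binomial"]].to_string(index=False))

scores = {s.gene: s for s in
          compute_dominance(annotations, len(cohort.patients))}
print()
for gene in ("EGFR", "KRAS", "TP53"):
    s = scores[gene]
    print(f"{gene:5s} dominance {s.score:.3f} "
          f"(carried by {s.n_carriers}/{len(cohort.patients)} patients)")
print("\npct_driver is the driver share of each compartment; p_binomial "
      "tests it against 50%. Dominance near 1 would mean a self-sufficient "
      "driver with few co-drivers.")
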