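"""Driver/passenger annotation, trunk-branch composition and driver dominance.

Drivers come from a supplied gene catalog (oncogene vs tumor-suppressor roles);
any gene outside the catalog is a passenger. Composition tables ask whether
driver mutations are over-represented on trunks or branches (and oncogenes vs
TSGs among drivers) with exact binomial tests against an even split.

The driver dominance score measures a driver gene's self-sufficiency: for each
patient carrying a mutation in gene g, count the distinct mutated driver genes
in that patient; the score is the mean of 1/count over carriers. It is 1
exactly when g is the sole mutated driver in every carrier and shrinks as
co-drivers accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import Cohort, DriverCatalog, DriverRole, PatientRecord, Subtype
from .ith import Clonality

__all__ = [
    "MutationAnnotation",
    "DominanceScore",
    "annotate_mutations",
    "composition_table",
    "compute_dominance",
]


@dataclass(frozen=True)
class MutationAnnotation:
    patient_id: str
    variant_key: str
    gene: str
    is_driver: bool
    role: DriverRole
    clonality: Clonality

    def __post_init__(self):
        if self.is_driver == (self.role is DriverRole.PASSENGER):
            raise ValueError("is_driver inconsistent with role")


@dataclass(frozen=True)
class DominanceScore:
    gene: str
    n_carriers: int
    carrier_fraction: float
    score: float


def annotate_mutations(cohort: Cohort, catalog: DriverCatalog,
                       labels: dict[str, dict[str, Clonality]]) -> list[MutationAnnotation]:
    """Attach driver role and clonality to every classified mutation.

    ``labels`` maps patient_id -> {variant_key -> clonality} as produced by
    trunk/branch classification; variants dropped by the presence rule carry
    no label and are skipped.
    """
    annotations = []
    for (pid, key), variant in sorted(cohort.variants.items()):
        clonality = labels.get(pid, {}).get(key)
        if clonality is None:
            continue
        role = catalog.role_of(variant.gene)
        annotations.append(MutationAnnotation(
            pid, key, variant.gene,
            is_driver=role is not DriverRole.PASSENGER,
            role=role, clonality=clonality))
    return annotations


def _binom_p(k: int, n: int) -> float:
    return float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)


def composition_table(annotations: list[MutationAnnotation],
                      patients: dict[str, PatientRecord],
                      grouping: dict[str, set[Subtype]] | None = None) -> pd.DataFrame:
    """Trunk/branch driver-passenger and oncogene-TSG composition per group.

    For each group and compartment (trunk, branch) the table reports mutation
    counts, the driver proportion with an exact two-sided binomial p against
    0.5, and — among drivers — the oncogene proportion with the same test.
    Compartments with zero mutations are omitted (no denominator).
    """
    grouping = dict(grouping or {})
    grouping.setdefault("ALL", set(Subtype))

    rows = []
    for group_name in grouping:
        subtypes = grouping[group_name]
        anns = [a for a in annotations
                if patients[a.patient_id].subtype in subtypes]
        for compartment in (Clonality.TRUNK, Clonality.BRANCH):
            comp = [a for a in anns if a.clonality is compartment]
            if not comp:
                continue
            n_driver = sum(a.is_driver for a in comp)
            n_pass = len(comp) - n_driver
            row = {
                "group": group_name,
                "compartment": compartment.value.lower(),
                "n_driver": n_driver,
                "n_passenger": n_pass,
                "pct_driver": 100.0 * n_driver / len(comp),
                "p_binomial": _binom_p(n_driver, len(comp)),
            }
            drivers = [a for a in comp if a.is_driver]
            if drivers:
                n_onc = sum(a.role is DriverRole.ONCOGENE for a in drivers)
                row.update(
                    n_oncogene=n_onc,
                    n_tsg=len(drivers) - n_onc,
                    pct_oncogene=100.0 * n_onc / len(drivers),
                    p_binomial_role=_binom_p(n_onc, len(drivers)),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def compute_dominance(annotations: list[MutationAnnotation],
                      n_patients: int) -> list[DominanceScore]:
    """Driver dominance score per driver gene.

    score(g) = mean over carriers of 1 / (distinct mutated driver genes in the
    carrier); co-drivers are counted at gene level across all regions, trunk
    or branch alike. Genes with no carriers are omitted.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    driver_genes_by_patient: dict[str, set[str]] = {}
    for a in annotations:
        if a.is_driver:
            driver_genes_by_patient.setdefault(a.patient_id, set()).add(a.gene)

    scores = []
    all_genes = sorted({g for genes in driver_genes_by_patient.values() for g in genes})
    for gene in all_genes:
        carriers = [genes for genes in driver_genes_by_patient.values()
                    if gene in genes]
        score = sum(1.0 / len(genes) for genes in carriers) / len(carriers)
        scores.append(DominanceScore(gene, len(carriers),
                                     len(carriers) / n_patients, score))
    return scores
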