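"""Trunk/branch classification and the intratumor-heterogeneity index (ITHi).

A somatic alteration shared by every sampled region of a tumor is a *trunk*
(clonal) mutation; one absent from at least one region is a *branch*
(subclonal) mutation. The ITH index summarizes per-patient heterogeneity as
the branch fraction, ithi = n_branch / (n_trunk + n_branch): 0 for a fully
clonal tumor, 1 when nothing is fully shared, and higher the fewer trunk
mutations the tumor has.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort, PatientRecord, RegionObservation, Subtype, VariantClass

__all__ = [
    "Clonality",
    "PatientMutationMatrix",
    "ITHResult",
    "build_mutation_matrix",
    "classify_trunk_branch",
    "compute_ithi",
    "compare_ithi_by_subtype",
    "gene_frequency_table",
    "SubtypeComparison",
]


class Clonality(str, Enum):
    TRUNK = "TRUNK"
    BRANCH = "BRANCH"


@dataclass
class PatientMutationMatrix:
    """Binary mutations x regions presence matrix for one patient.

    Rows are variant keys, columns region ids; entries are 0/1. Every row has
    at least one 1 (a variant was observed somewhere, or it is not a row).
    """

    patient_id: str
    variant_keys: list[str]
    region_ids: list[str]
    presence: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.variant_keys), len(self.region_ids)):
            raise ValueError("presence shape does not match key/region lists")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        if len(self.variant_keys) and (self.presence.sum(axis=1) == 0).any():
            raise ValueError("all-zero mutation row")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass
class ITHResult:
    patient_id: str
    n_trunk: int
    n_branch: int

    @property
    def ithi(self) -> float:
        return self.n_branch / (self.n_trunk + self.n_branch)


def _observation_present(obs: RegionObservation, min_alt_reads: int) -> bool:
    # Rows without read counts (CNV/FUSION or missing) count as present:
    # the calls were already filtered upstream.
    if obs.alt_reads is None:
        return True
    return obs.alt_reads >= min_alt_reads


def build_mutation_matrix(patient: PatientRecord,
                          observations: list[RegionObservation],
                          min_alt_reads: int = 1) -> PatientMutationMatrix:
    """Build the binary presence matrix for one patient.

    An observation marks its variant present in its region iff it has at least
    ``min_alt_reads`` supporting reads (observations without read counts always
    count). Variants present nowhere after this rule are dropped. The result
    is invariant to observation order.
    """
    regions = sorted(patient.region_ids)
    region_index = {r: i for i, r in enumerate(regions)}
    rows: dict[str, np.ndarray] = {}
    for obs in observations:
        if obs.region_id not in region_index:
            raise ValueError(f"observation in unknown region '{obs.region_id}' "
                             f"for patient {patient.patient_id}")
        row = rows.setdefault(obs.variant_key, np.zeros(len(regions), dtype=np.int8))
        if _observation_present(obs, min_alt_reads):
            row[region_index[obs.region_id]] = 1
    keys = sorted(k for k, row in rows.items() if row.any())
    presence = (np.vstack([rows[k] for k in keys]) if keys
                else np.zeros((0, len(regions)), dtype=np.int8))
    return PatientMutationMatrix(patient.patient_id, keys, regions, presence)


def classify_trunk_branch(matrix: PatientMutationMatrix) -> dict[str, Clonality]:
    """Label each mutation TRUNK iff present in every sampled region.

    Single-region patients carry no heterogeneity information, so every
    mutation is trunk by the literal all-regions rule.
    """
    all_ones = matrix.presence.sum(axis=1) == matrix.n_regions
    return {key: (Clonality.TRUNK if full else Clonality.BRANCH)
            for key, full in zip(matrix.variant_keys, all_ones)}


def compute_ithi(labels: dict[str, Clonality],
                 patient_id: str = "") -> ITHResult:
    """ITH index from trunk/branch labels: branch / (trunk + branch)."""
    if not labels:
        raise ValueError("ITH index is undefined with zero mutations")
    n_trunk = sum(1 for c in labels.values() if c is Clonality.TRUNK)
    return ITHResult(patient_id, n_trunk, len(labels) - n_trunk)


@dataclass
class SubtypeComparison:
    statistic: float
    pvalue: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str


def compare_ithi_by_subtype(results: dict[str, ITHResult],
                            patients: dict[str, PatientRecord],
                            group_a: set[Subtype],
                            group_b: set[Subtype],
                            min_regions: int = 2) -> SubtypeComparison:
    """Two-sided Mann-Whitney U comparison of ITHi between two subtype groups.

    The exact no-tie null distribution is used for total n <= 20 without ties;
    otherwise the normal approximation with tie correction. Patients with
    fewer than ``min_regions`` regions carry no ITH information and are
    excluded.
    """
    def values(group: set[Subtype]) -> list[float]:
        return [res.ithi for pid, res in sorted(results.items())
                if patients[pid].subtype in group
                and len(patients[pid].region_ids) >= min_regions]

    a, b = values(group_a), values(group_b)
    if not a or not b:
        raise ValueError("both subtype groups must be non-empty")
    has_ties = len(set(a + b)) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
    # no continuity correction: z = 0 (hence p = 1) for identical groups
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=False)
    return SubtypeComparison(float(stat), float(p),
                             float(np.median(a)), float(np.median(b)),
                             len(a), len(b), f"mann-whitney-{method}")


def gene_frequency_table(cohort: Cohort, threshold: float = 0.10) -> pd.DataFrame:
    """Per-gene fraction of patients mutated, flagging genes above threshold.

    A patient counts once per gene regardless of how many variants or regions
    carry it; ``recurrent`` marks genes mutated in strictly more than
    ``threshold`` of patients.
    """
    if not cohort.patients:
        raise ValueError("empty cohort")
    n_patients = len(cohort.patients)
    carriers: dict[str, set[str]] = {}
    for (pid, _), variant in cohort.variants.items():
        carriers.setdefault(variant.gene, set()).add(pid)
    rows = [{"gene": gene, "n_patients": len(pids),
             "fraction": len(pids) / n_patients,
             "recurrent": len(pids) / n_patients > threshold}
            for gene, pids in carriers.items()]
    df = pd.DataFrame(rows).sort_values(["fraction", "gene"],
                                        ascending=[False, True],
                                        ignore_index=True)
    return df
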