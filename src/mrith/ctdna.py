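"""Concordance between tissue-confirmed mutations and plasma ctDNA.

A tumor-derived mutation is a tissue-confirmed alteration looked up in the
matched plasma sample; it is *detected* when the plasma assay reports at least
one high-quality mutant read (the read counts are assumed quality-filtered
upstream). Detection rates are pooled over mutations per stratum and trunk is
contrasted with branch by Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import Cohort, CtdnaRecord, PatientRecord, Subtype
from .ith import Clonality

__all__ = [
    "DetectionRow",
    "DetectionSummary",
    "match_tumor_to_plasma",
    "summarize_detection",
    "DETECTION_THRESHOLD",
]

DETECTION_THRESHOLD = 1  # mutant reads needed to call a plasma detection


@dataclass(frozen=True)
class DetectionRow:
    patient_id: str
    variant_key: str
    clonality: Clonality
    mutant_reads: int
    detected: bool


@dataclass
class DetectionSummary:
    strata: pd.DataFrame          # stratum, n_total, n_detected, rate, p_fisher
    n_patients_assayed: int
    n_patients_positive: int

    @property
    def patient_positive_fraction(self) -> float:
        return self.n_patients_positive / self.n_patients_assayed


def match_tumor_to_plasma(cohort: Cohort,
                          ctdna: list[CtdnaRecord],
                          labels: dict[str, dict[str, Clonality]],
                          threshold: int = DETECTION_THRESHOLD,
                          count_uncovered: bool = True) -> list[DetectionRow]:
    """One row per tumor-derived mutation with plasma evidence.

    Tissue mutations missing from the plasma table are scored as assayed with
    zero mutant reads when the patient has a plasma sample (``count_uncovered``,
    the default) or dropped from the denominator otherwise. Plasma records with
    no matching tissue mutation are plasma-private and excluded. Patients with
    no plasma records at all contribute nothing.
    """
    plasma_reads: dict[tuple[str, str], int] = {}
    patients_with_plasma: set[str] = set()
    for rec in ctdna:
        patients_with_plasma.add(rec.patient_id)
        plasma_reads[(rec.patient_id, rec.variant_key)] = rec.mutant_reads

    rows = []
    for pid in sorted(labels):
        if pid not in patients_with_plasma:
            continue
        for key, clonality in sorted(labels[pid].items()):
            reads = plasma_reads.get((pid, key))
            if reads is None:
                if not count_uncovered:
                    continue
                reads = 0
            rows.append(DetectionRow(pid, key, clonality, reads,
                                     reads >= threshold))
    return rows


def _stratum(rows: list[DetectionRow], name: str) -> dict:
    n_det = sum(r.detected for r in rows)
    return {"stratum": name, "n_total": len(rows), "n_detected": n_det,
            "rate": n_det / len(rows)}


def _fisher_trunk_branch(rows: list[DetectionRow]) -> float | None:
    trunk = [r for r in rows if r.clonality is Clonality.TRUNK]
    branch = [r for r in rows if r.clonality is Clonality.BRANCH]
    if not trunk or not branch:
        return None
    table = [[sum(r.detected for r in trunk), sum(not r.detected for r in trunk)],
             [sum(r.detected for r in branch), sum(not r.detected for r in branch)]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def summarize_detection(rows: list[DetectionRow],
                        patients: dict[str, PatientRecord]) -> DetectionSummary:
    """Pooled detection rates overall and per subtype x clonality stratum.

    Rates pool mutations, not patients, so each stratum is a single binomial
    count. The trunk-vs-branch contrast is a two-sided Fisher exact test on
    the 2x2 detected/undetected table, overall and within each subtype.
    Empty strata are absent from the table.
    """
    if not rows:
        raise ValueError("no tumor-derived mutations with plasma evidence")

    records = []
    for clon in (Clonality.TRUNK, Clonality.BRANCH):
        sub = [r for r in rows if r.clonality is clon]
        if sub:
            records.append(_stratum(sub, f"overall_{clon.value.lower()}")
                           | {"p_fisher": _fisher_trunk_branch(rows)})
    for subtype in Subtype:
        srows = [r for r in rows if patients[r.patient_id].subtype is subtype]
        if not srows:
            continue
        p = _fisher_trunk_branch(srows)
        for clon in (Clonality.TRUNK, Clonality.BRANCH):
            sub = [r for r in srows if r.clonality is clon]
            if sub:
                records.append(_stratum(sub, f"{subtype.value}_{clon.value.lower()}")
                               | {"p_fisher": p})

    assayed = {r.patient_id for r in rows}
    positive = {r.patient_id for r in rows if r.detected}
    return DetectionSummary(pd.DataFrame(records), len(assayed), len(positive))
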