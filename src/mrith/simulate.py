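"""Clonal-evolution cohort simulator with matched plasma sampling.

Generates multi-region NSCLC-like cohorts with known ground truth so every
pipeline stage can be validated end to end. Each patient gets a random rooted
bifurcating region tree with a germline root; mutations are placed on its
edges — on the trunk (root edge, shared by all regions) with a per-subtype
probability, otherwise uniformly on a subclonal edge — so presence matrices
are perfect-phylogeny compatible by construction. A matched plasma sample
draws mutant reads per mutation from a binomial whose per-read rate is
calibrated so the probability of seeing >= 1 mutant read equals the
configured detection probability for that mutation's stratum (trunk mutations
are detected more often than branch mutations, as in real ctDNA).

Defaults mirror the study conditions the package targets: 32 patients
(9 EGFR-mutant LUAD, 6 KRAS-mutant LUAD, 11 EGFR&KRAS-wild-type LUAD, 5 LUSC,
1 LELC), 3-7 regions per tumor, ~14 mutations per patient, the lowest trunk
fraction in EGFR-mutant LUAD, and subtype-specific plasma detection rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DriverRole, Subtype, write_tsv
from .ith import Clonality

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "truth_check",
    "DRIVER_CATALOG",
]

# bundled driver catalog for simulation (lung-cancer driver genes)
DRIVER_CATALOG: dict[str, DriverRole] = {
    **{g: DriverRole.ONCOGENE for g in
       ("EGFR", "KRAS", "BRAF", "MET", "ERBB2", "PIK3CA", "ALK", "RET",
        "ROS1", "MYC", "CCND1", "FGFR1")},
    **{g: DriverRole.TSG for g in
       ("TP53", "STK11", "KEAP1", "RB1", "PTEN", "CDKN2A", "NF1", "SMAD4",
        "ARID1A", "ATM")},
}

N_PASSENGER_GENES = 999  # panel-like background gene symbols GENE0001..

_SUBTYPES = (Subtype.EGFR_LUAD, Subtype.KRAS_LUAD, Subtype.WT_LUAD,
             Subtype.LUSC, Subtype.LELC)


def _per_subtype(value, defaults=None) -> dict[Subtype, float]:
    """Scalar -> every subtype; partial dict -> merged over the defaults."""
    if isinstance(value, dict):
        out = {Subtype(k): float(v) for k, v in (defaults or {}).items()}
        out.update({Subtype(k): float(v) for k, v in value.items()})
        return out
    return {s: float(value) for s in _SUBTYPES}


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Scalar values for the per-subtype fields apply to every subtype; dicts
    override per subtype. Probabilities must lie in [0, 1] and the region
    range within [1, 10].
    """

    seed: int
    n_patients: dict = field(default_factory=lambda: {
        Subtype.EGFR_LUAD: 9, Subtype.KRAS_LUAD: 6, Subtype.WT_LUAD: 11,
        Subtype.LUSC: 5, Subtype.LELC: 1})
    regions_range: tuple[int, int] = (3, 7)
    mutation_burden: dict | float = 14.0
    trunk_fraction: dict | float = field(default_factory=lambda: {
        Subtype.EGFR_LUAD: 0.30, Subtype.KRAS_LUAD: 0.55,
        Subtype.WT_LUAD: 0.55, Subtype.LUSC: 0.60, Subtype.LELC: 0.55})
    driver_prob: dict | float = field(default_factory=lambda: {
        Subtype.EGFR_LUAD: 0.60, Subtype.KRAS_LUAD: 0.40,
        Subtype.WT_LUAD: 0.50, Subtype.LUSC: 0.60, Subtype.LELC: 0.50})
    oncogene_fraction: dict | float = field(default_factory=lambda: {
        Subtype.EGFR_LUAD: 0.70, Subtype.KRAS_LUAD: 0.50,
        Subtype.WT_LUAD: 0.50, Subtype.LUSC: 0.25, Subtype.LELC: 0.50})
    p_detect_trunk: dict | float = field(default_factory=lambda: {
        Subtype.EGFR_LUAD: 0.30, Subtype.KRAS_LUAD: 0.22,
        Subtype.WT_LUAD: 0.53, Subtype.LUSC: 0.81, Subtype.LELC: 0.40})
    p_detect_branch: dict | float = field(default_factory=lambda: {
        Subtype.EGFR_LUAD: 0.13, Subtype.KRAS_LUAD: 0.15,
        Subtype.WT_LUAD: 0.25, Subtype.LUSC: 0.20, Subtype.LELC: 0.15})
    plasma_depth: int = 1000
    tissue_depth: int = 800
    dropout: float = 0.0  # per-(mutation, region) presence dropout; > 0 adds homoplasy

    def __post_init__(self):
        self.n_patients = {Subtype(k): int(v) for k, v in self.n_patients.items()}
        lo, hi = self.regions_range
        if not (1 <= lo <= hi <= 10):
            raise ValueError(f"regions_range {self.regions_range} not within [1, 10]")
        dataclass_fields = type(self).__dataclass_fields__
        for name in ("trunk_fraction", "driver_prob", "oncogene_fraction",
                     "p_detect_trunk", "p_detect_branch"):
            defaults = dataclass_fields[name].default_factory()
            per = _per_subtype(getattr(self, name), defaults)
            if any(not 0.0 <= p <= 1.0 for p in per.values()):
                raise ValueError(f"{name} outside [0, 1]")
            setattr(self, name, per)
        self.mutation_burden = _per_subtype(self.mutation_burden)
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout outside [0, 1]")


@dataclass
class GroundTruth:
    """Generative truth: clonality, driver role and detection probability per
    mutation, and the true region-tree score (= mutation count) per patient."""

    subtype: dict[str, Subtype] = field(default_factory=dict)
    clonality: dict[tuple[str, str], Clonality] = field(default_factory=dict)
    role: dict[tuple[str, str], DriverRole] = field(default_factory=dict)
    p_detect: dict[tuple[str, str], float] = field(default_factory=dict)
    n_mutations: dict[str, int] = field(default_factory=dict)
    region_sets: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    tissue: pd.DataFrame
    ctdna: pd.DataFrame
    drivers: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit tissue.tsv, ctdna.tsv, drivers.tsv (and truth.json) to a
        directory; identical seed and config give byte-identical files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("tissue", self.tissue), ("ctdna", self.ctdna),
                         ("drivers", self.drivers)):
            paths[name] = outdir / f"{name}.tsv"
            write_tsv(df, paths[name])
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(self._truth_json(), encoding="utf-8")
        return paths

    def _truth_json(self) -> str:
        import json

        t = self.truth
        payload = {
            "subtype": {p: s.value for p, s in sorted(t.subtype.items())},
            "n_mutations": dict(sorted(t.n_mutations.items())),
            "clonality": {f"{p}|{k}": c.value
                          for (p, k), c in sorted(t.clonality.items())},
            "p_detect": {f"{p}|{k}": v
                         for (p, k), v in sorted(t.p_detect.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True) + "\n"


def _random_topology(rng: np.random.Generator, n: int):
    """Uniform stepwise-insertion rooted binary topology over leaves 0..n-1."""
    if n == 1:
        return 0
    tree = (0, 1)
    for leaf in range(2, n):
        positions = _insertion_count(tree)
        tree = _insert_at(tree, leaf, int(rng.integers(positions)))
    return tree


def _insertion_count(tree) -> int:
    return 1 if isinstance(tree, int) else 1 + _insertion_count(tree[0]) + \
        _insertion_count(tree[1])


def _insert_at(tree, leaf: int, pos: int):
    if pos == 0:
        return (tree, leaf)
    left, right = tree
    nl = _insertion_count(left)
    if pos - 1 < nl:
        return (_insert_at(left, leaf, pos - 1), right)
    return (left, _insert_at(right, leaf, pos - 1 - nl))


def _edges_below(tree) -> list[frozenset[int]]:
    """Leaf sets below each non-root edge (excludes the trunk/root edge)."""
    out: list[frozenset[int]] = []

    def collect(node) -> frozenset[int]:
        if isinstance(node, int):
            s = frozenset([node])
        else:
            s = collect(node[0]) | collect(node[1])
        out.append(s)
        return s

    full = collect(tree)
    return [s for s in out if s != full]


def _draw_placements(rng, n_total, n_forced, theta, n_regions,
                     subclonal_edges):
    """Draw (is_trunk, region_index_set) per mutation, conditioned on every
    region carrying at least one mutation.

    Sampled tumor regions with zero somatic calls would not appear in a
    variant table at all, so placements are redrawn (rejection sampling)
    until the union covers all regions; the forced canonical driver (last
    placement) rides the trunk except in the degenerate theta = 0 limit.
    """
    full = frozenset(range(n_regions))
    for _ in range(200):
        placements = []
        for m in range(n_total):
            if m >= n_total - n_forced:  # forced driver
                is_trunk = theta > 0 or not subclonal_edges
            else:
                is_trunk = not subclonal_edges or rng.random() < theta
            region_set = (full if is_trunk else
                          subclonal_edges[int(rng.integers(len(subclonal_edges)))])
            placements.append((is_trunk, region_set))
        covered = frozenset().union(*(s for _, s in placements))
        if covered == full:
            return placements
    # pathological draw (e.g. one branch mutation, many regions): reassign
    # branch placements to the uncovered regions' private edges
    branch_idx = [i for i, (t, _) in enumerate(placements) if not t]
    for j, region in enumerate(sorted(full - covered)):
        if not branch_idx:
            break
        i = branch_idx[j % len(branch_idx)]
        placements[i] = (False, frozenset([region]))
    return placements


_BASES = np.array(list("ACGT"))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort: tissue table, plasma table, driver
    catalog and ground truth. Deterministic given (seed, config)."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    tissue_rows: list[dict] = []
    ctdna_rows: list[dict] = []
    pos_counter = 0

    onc_genes = sorted(g for g, r in DRIVER_CATALOG.items()
                       if r is DriverRole.ONCOGENE)
    tsg_genes = sorted(g for g, r in DRIVER_CATALOG.items()
                       if r is DriverRole.TSG)

    patient_no = 0
    for subtype in _SUBTYPES:
        for _ in range(config.n_patients.get(subtype, 0)):
            patient_no += 1
            pid = f"P{patient_no:03d}"
            truth.subtype[pid] = subtype
            pos_counter = _simulate_patient(
                rng, config, pid, subtype, truth, tissue_rows, ctdna_rows,
                pos_counter, onc_genes, tsg_genes)

    tissue = pd.DataFrame(tissue_rows, columns=[
        "patient_id", "region_id", "subtype", "chrom", "pos", "ref", "alt",
        "gene", "vclass", "vaf", "alt_reads", "depth"])
    ctdna = pd.DataFrame(ctdna_rows, columns=[
        "patient_id", "chrom", "pos", "ref", "alt", "gene", "vclass",
        "mutant_reads", "depth"])
    drivers = pd.DataFrame(
        [{"gene": g, "role": r.value} for g, r in sorted(DRIVER_CATALOG.items())])
    return SimulatedCohort(tissue, ctdna, drivers, truth, config)


def _simulate_patient(rng, config, pid, subtype, truth, tissue_rows,
                      ctdna_rows, pos_counter, onc_genes, tsg_genes) -> int:
    lo, hi = config.regions_range
    n_regions = int(rng.integers(lo, hi + 1))
    regions = [f"R{i + 1}" for i in range(n_regions)]
    topology = _random_topology(rng, n_regions)
    subclonal_edges = _edges_below(topology) if n_regions > 1 else []

    n_mut = max(1, int(rng.poisson(config.mutation_burden[subtype])))
    theta = config.trunk_fraction[subtype]

    # canonical subtype driver forced as a trunk oncogene mutation
    forced_gene = {"EGFR_LUAD": "EGFR", "KRAS_LUAD": "KRAS"}.get(subtype.value)
    excluded = {"EGFR", "KRAS"} - ({forced_gene} if forced_gene else set())

    placements = _draw_placements(rng, n_mut + (1 if forced_gene else 0),
                                  1 if forced_gene else 0, theta,
                                  n_regions, subclonal_edges)

    used_keys: set[str] = set()
    muts = []  # (gene, role, is_trunk, region_index_set)
    for m, (is_trunk, region_set) in enumerate(placements):
        forced = forced_gene is not None and m == len(placements) - 1
        if forced:
            gene, role = forced_gene, DriverRole.ONCOGENE
        elif rng.random() < config.driver_prob[subtype]:
            if rng.random() < config.oncogene_fraction[subtype]:
                pool = [g for g in onc_genes if g not in excluded]
            else:
                pool = tsg_genes
            gene, role = pool[int(rng.integers(len(pool)))], None
            role = DRIVER_CATALOG[gene]
        else:
            gene = f"GENE{int(rng.integers(1, N_PASSENGER_GENES + 1)):04d}"
            role = DriverRole.PASSENGER
        muts.append((gene, role, is_trunk, region_set))

    for gene, role, is_trunk, region_set in muts:
        pos_counter += 1
        vclass, chrom, pos = "SNV", "chrS", pos_counter
        r = rng.random()
        if not role or role is DriverRole.PASSENGER:
            if r < 0.03:
                vclass = "CNV"
            elif r < 0.037:
                vclass = "FUSION"
            elif r < 0.13:
                vclass = "INDEL"
        ref, alt = (str(x) for x in rng.choice(_BASES, 2, replace=False))
        if vclass == "INDEL":
            alt = ref + str(rng.choice(_BASES))
        elif vclass == "CNV":
            alt = "AMP" if rng.random() < 0.5 else "DEL"
        elif vclass == "FUSION":
            alt = f"GENE{int(rng.integers(1, N_PASSENGER_GENES + 1)):04d}"
        if vclass in ("CNV", "FUSION"):
            key = f"{gene}:{vclass}:{alt}"
            if key in used_keys:  # gene-level key collision: fall back to SNV
                vclass = "SNV"
                ref, alt = (str(x) for x in rng.choice(_BASES, 2, replace=False))
        if vclass in ("SNV", "INDEL"):
            key = f"{chrom}:{pos}:{ref}:{alt}"
        used_keys.add(key)

        present = set(region_set)
        if config.dropout > 0 and len(present) > 1:
            kept = {i for i in present if rng.random() >= config.dropout}
            present = kept or {sorted(present)[int(rng.integers(len(present)))]}

        truth.clonality[(pid, key)] = (Clonality.TRUNK if is_trunk
                                       else Clonality.BRANCH)
        truth.role[(pid, key)] = role
        truth.region_sets[(pid, key)] = frozenset(regions[i] for i in present)

        has_counts = vclass in ("SNV", "INDEL")
        for i in sorted(present):
            if has_counts:
                vaf = float(rng.uniform(0.05, 0.5))
                alt_reads = max(1, int(round(vaf * config.tissue_depth)))
                row_vaf = round(alt_reads / config.tissue_depth, 4)
                tissue_rows.append(dict(
                    patient_id=pid, region_id=regions[i], subtype=subtype.value,
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                    vclass=vclass, vaf=row_vaf, alt_reads=alt_reads,
                    depth=config.tissue_depth))
            else:
                tissue_rows.append(dict(
                    patient_id=pid, region_id=regions[i], subtype=subtype.value,
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                    vclass=vclass, vaf=".", alt_reads=".", depth="."))

        # plasma draw: per-read rate q gives P(>=1 mutant read) = p_detect
        p_detect = (config.p_detect_trunk if is_trunk
                    else config.p_detect_branch)[subtype]
        truth.p_detect[(pid, key)] = p_detect
        q = 1.0 - (1.0 - p_detect) ** (1.0 / config.plasma_depth)
        mutant_reads = int(rng.binomial(config.plasma_depth, q))
        ctdna_rows.append(dict(
            patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            vclass=vclass, mutant_reads=mutant_reads, depth=config.plasma_depth))

    truth.n_mutations[pid] = len(muts)
    return pos_counter


def truth_check(labels: dict[str, dict[str, Clonality]],
                trees: dict[str, "object"],
                detection_rows,
                truth: GroundTruth) -> dict:
    """Compare pipeline outputs with generative truth.

    Reports trunk/branch accuracy (exact for noiseless simulations), the
    fraction of patients whose parsimony score equals the true tree score
    (= mutation count, perfect phylogeny), and observed-vs-configured plasma
    detection rates per (subtype, clonality) stratum.
    """
    if set(labels) != set(truth.subtype):
        raise ValueError("patient sets of pipeline output and truth differ")

    n_ok = n_tot = 0
    for pid, per_patient in labels.items():
        for key, call in per_patient.items():
            n_tot += 1
            n_ok += call is truth.clonality[(pid, key)]
    report = {"trunk_branch_accuracy": n_ok / n_tot if n_tot else float("nan")}

    if trees:
        match = [trees[pid].parsimony_score == truth.n_mutations[pid]
                 for pid in trees]
        report["parsimony_score_match_fraction"] = sum(match) / len(match)

    strata: dict[tuple, list] = {}
    for row in detection_rows or []:
        stratum = (truth.subtype[row.patient_id].value,
                   truth.clonality[(row.patient_id, row.variant_key)].value)
        strata.setdefault(stratum, []).append(
            (row.detected, truth.p_detect[(row.patient_id, row.variant_key)]))
    recovery = {}
    for stratum, vals in sorted(strata.items()):
        observed = sum(d for d, _ in vals) / len(vals)
        expected = vals[0][1]
        recovery["/".join(stratum)] = {
            "n": len(vals), "observed": observed, "expected": expected,
            "abs_error": abs(observed - expected)}
    report["detection_recovery"] = recovery
    return report
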