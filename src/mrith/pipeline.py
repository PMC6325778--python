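"""End-to-end orchestration: cohort in, result tables and trees out.

Runs trunk/branch classification, ITH indexing, per-patient parsimony trees,
driver composition and dominance, and plasma concordance over one cohort, and
assembles a single summary report. All outputs are TSVs (plus one Newick file
per patient); a run is deterministic given its inputs and configuration.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ctdna as ctdna_mod
from . import drivers as drivers_mod
from . import ith as ith_mod
from . import phylo as phylo_mod
from .io import (Cohort, DriverCatalog, Subtype, filter_to_panel,
                 read_ctdna_table, read_driver_catalog, read_panel_bed,
                 read_tissue_table, write_newick, write_tsv)

log = logging.getLogger("mrith")

ALL_STAGES = frozenset({"ith", "tree", "drivers", "ctdna", "report"})

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "infer_subtypes"]


@dataclass
class PipelineConfig:
    tissue: Path
    out: Path
    drivers: Path | None = None
    ctdna: Path | None = None
    panel: Path | None = None
    min_alt_reads: int = 1      # presence rule: reads needed to call a region positive
    detect_threshold: int = 1   # plasma mutant reads needed for a detection
    count_uncovered: bool = True
    stages: frozenset = ALL_STAGES

    def __post_init__(self):
        self.tissue = Path(self.tissue)
        self.out = Path(self.out)
        for name in ("drivers", "ctdna", "panel"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
                if not Path(value).exists():
                    raise FileNotFoundError(f"{name} file not found: {value}")
        if not self.tissue.exists():
            raise FileNotFoundError(f"tissue file not found: {self.tissue}")


@dataclass
class PipelineResult:
    cohort: Cohort
    labels: dict = field(default_factory=dict)        # pid -> {key -> Clonality}
    ith_results: dict = field(default_factory=dict)   # pid -> ITHResult
    trees: dict = field(default_factory=dict)         # pid -> PhyloTree
    tables: dict = field(default_factory=dict)        # name -> DataFrame
    detection_rows: list = field(default_factory=list)


def infer_subtypes(cohort: Cohort) -> None:
    """Fill in missing subtype labels from the mutation profile.

    A patient with any EGFR mutation is EGFR-mutant LUAD, else any KRAS
    mutation means KRAS-mutant LUAD; carrying both requires explicit
    annotation (the subtype groups are disjoint). Patients with neither and
    no histology label default to EGFR&KRAS-wild-type LUAD.
    """
    genes_by_patient: dict[str, set[str]] = {}
    for (pid, _), variant in cohort.variants.items():
        genes_by_patient.setdefault(pid, set()).add(variant.gene)
    for pid, record in cohort.patients.items():
        genes = genes_by_patient.get(pid, set())
        has_egfr, has_kras = "EGFR" in genes, "KRAS" in genes
        if has_egfr and has_kras:
            if record.subtype is None:
                raise ValueError(
                    f"patient {pid} carries both EGFR and KRAS mutations; "
                    "subtype must be annotated explicitly")
            continue
        if record.subtype is not None:
            continue
        if has_egfr:
            record.subtype = Subtype.EGFR_LUAD
        elif has_kras:
            record.subtype = Subtype.KRAS_LUAD
        else:
            log.warning("patient %s: no subtype label and no EGFR/KRAS "
                        "mutation; defaulting to WT_LUAD", pid)
            record.subtype = Subtype.WT_LUAD


def _ith_stage(cohort: Cohort, config: PipelineConfig, result: PipelineResult):
    rows = []
    for pid in sorted(cohort.patients):
        patient = cohort.patients[pid]
        matrix = ith_mod.build_mutation_matrix(
            patient, cohort.observations[pid], config.min_alt_reads)
        if not matrix.variant_keys:
            log.warning("patient %s has no mutations after the presence rule", pid)
            continue
        labels = ith_mod.classify_trunk_branch(matrix)
        res = ith_mod.compute_ithi(labels, pid)
        result.labels[pid] = labels
        result.ith_results[pid] = res
        result.tables.setdefault("_matrices", {})[pid] = matrix
        rows.append({"patient_id": pid,
                     "subtype": patient.subtype.value if patient.subtype else ".",
                     "n_regions": len(patient.region_ids),
                     "n_trunk": res.n_trunk, "n_branch": res.n_branch,
                     "ithi": round(res.ithi, 6)})
    result.tables["ithi"] = pd.DataFrame(rows)
    result.tables["gene_freq"] = ith_mod.gene_frequency_table(cohort)


def _tree_stage(result: PipelineResult, outdir: Path):
    matrices = result.tables["_matrices"]
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    rows = []
    for pid in sorted(matrices):
        tree = phylo_mod.build_phylogenetic_tree(matrices[pid])
        result.trees[pid] = tree
        write_newick(tree, tree_dir / f"{pid}.nwk")
        rows.append({"patient_id": pid, "n_regions": matrices[pid].n_regions,
                     "parsimony_score": tree.parsimony_score,
                     "trunk_len": tree.trunk_length,
                     "pattern": tree.pattern.value})
    result.tables["trees"] = pd.DataFrame(rows)


def _driver_stage(cohort: Cohort, catalog: DriverCatalog, result: PipelineResult):
    annotations = drivers_mod.annotate_mutations(cohort, catalog, result.labels)
    result.tables["_annotations"] = annotations
    grouping = {s.value: {s} for s in Subtype
                if any(p.subtype is s for p in cohort.patients.values())}
    result.tables["composition"] = drivers_mod.composition_table(
        annotations, cohort.patients, grouping)
    dominance = drivers_mod.compute_dominance(annotations, len(cohort.patients))
    result.tables["dominance"] = pd.DataFrame(
        [{"gene": d.gene, "n_carriers": d.n_carriers,
          "carrier_fraction": round(d.carrier_fraction, 6),
          "score": round(d.score, 6)} for d in dominance])


def _ctdna_stage(cohort: Cohort, config: PipelineConfig, result: PipelineResult):
    records = read_ctdna_table(config.ctdna)
    known = {(pid, key) for pid, labels in result.labels.items() for key in labels}
    plasma_only = [r for r in records if (r.patient_id, r.variant_key) not in known]
    for r in plasma_only:
        log.info("plasma-only variant excluded: %s %s", r.patient_id, r.variant_key)
    rows = ctdna_mod.match_tumor_to_plasma(
        cohort, records, result.labels,
        threshold=config.detect_threshold,
        count_uncovered=config.count_uncovered)
    result.detection_rows = rows
    result.tables["detection"] = pd.DataFrame(
        [{"patient_id": r.patient_id, "variant_key": r.variant_key,
          "clonality": r.clonality.value, "mutant_reads": r.mutant_reads,
          "detected": int(r.detected)} for r in rows])
    summary = ctdna_mod.summarize_detection(rows, cohort.patients)
    result.tables["detection_summary"] = summary.strata
    result.tables["_detection_meta"] = summary


def _report_stage(cohort: Cohort, result: PipelineResult) -> pd.DataFrame:
    rows = []

    def add(metric, value):
        rows.append({"metric": metric, "value": value})

    ithi = result.tables["ithi"]
    for subtype in Subtype:
        sub = ithi[(ithi.subtype == subtype.value) & (ithi.n_regions >= 2)]
        if len(sub):
            add(f"median_ithi_{subtype.value}", round(float(sub.ithi.median()), 6))
    try:
        cmp = ith_mod.compare_ithi_by_subtype(
            result.ith_results, cohort.patients,
            {Subtype.EGFR_LUAD}, {Subtype.KRAS_LUAD, Subtype.WT_LUAD})
        add("p_ithi_egfr_vs_other_luad", cmp.pvalue)
    except ValueError:
        pass

    comp = result.tables.get("composition")
    if comp is not None and len(comp):
        overall = comp[comp.group == "ALL"] if "ALL" in set(comp.group) else comp
        for _, row in overall.iterrows():
            add(f"pct_driver_{row.compartment}", round(row.pct_driver, 2))
            add(f"p_driver_{row.compartment}", row.p_binomial)

    dom = result.tables.get("dominance")
    if dom is not None:
        for gene in ("EGFR", "KRAS"):
            hit = dom[dom.gene == gene]
            if len(hit):
                add(f"dominance_{gene}", float(hit.score.iloc[0]))

    det = result.tables.get("detection_summary")
    if det is not None:
        for _, row in det[det.stratum.str.startswith("overall")].iterrows():
            add(f"detection_rate_{row.stratum}", round(row.rate, 4))
            add("p_fisher_trunk_vs_branch", row.p_fisher)
        meta = result.tables["_detection_meta"]
        add("fraction_patients_ctdna_positive",
            round(meta.patient_positive_fraction, 4))
    # de-duplicate repeated metrics (fisher p appears once per stratum row)
    df = pd.DataFrame(rows).drop_duplicates(subset="metric", keep="first")
    return df.reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write all result files.

    Outputs land in ``config.out``: ithi.tsv, gene_freq.tsv, trees/ and
    trees.tsv, composition.tsv, dominance.tsv, detection.tsv,
    detection_summary.tsv and report.tsv (stage-dependent). The directory is
    staged under a temporary name and moved into place only on success, so a
    failed run leaves no partial outputs.
    """
    cohort = read_tissue_table(config.tissue)
    if config.panel is not None:
        cohort = filter_to_panel(cohort, read_panel_bed(config.panel))
        log.info("panel filter kept %d variants", len(cohort.variants))
    infer_subtypes(cohort)
    catalog = read_driver_catalog(config.drivers) if config.drivers else DriverCatalog()

    result = PipelineResult(cohort)
    staging = config.out.with_name(config.out.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        _ith_stage(cohort, config, result)
        log.info("presence rule: alt_reads >= %d; detection threshold: >= %d "
                 "mutant reads", config.min_alt_reads, config.detect_threshold)
        if "tree" in config.stages:
            _tree_stage(result, staging)
        if "drivers" in config.stages and config.drivers is not None:
            _driver_stage(cohort, catalog, result)
        if "ctdna" in config.stages and config.ctdna is not None:
            _ctdna_stage(cohort, config, result)
        if "report" in config.stages:
            result.tables["report"] = _report_stage(cohort, result)

        for name, table in result.tables.items():
            if name.startswith("_"):
                continue
            write_tsv(table, staging / f"{name}.tsv")
        if config.out.exists():
            shutil.rmtree(config.out)
        staging.rename(config.out)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    return result
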