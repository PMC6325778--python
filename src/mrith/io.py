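"""Cohort input/output: tissue and plasma variant tables, driver catalogs, panels, trees.

Variant tables are MAF-like TSVs with one row per (patient, region, variant)
observation; plasma (ctDNA) tables carry per-variant mutant read counts from deep
sequencing of cell-free DNA. Variants are identified across regions and between
tissue and plasma by a canonical key: genomic coordinates for SNVs/indels,
gene-level identity for copy-number and fusion events (which have no single
breakpoint coordinate in these tables).

Coordinate conventions: variant positions are 1-based (VCF-style); panel BED
files are 0-based half-open, converted only inside :func:`filter_to_panel`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

__all__ = [
    "VariantClass",
    "DriverRole",
    "Subtype",
    "Variant",
    "RegionObservation",
    "PatientRecord",
    "DriverCatalog",
    "Cohort",
    "SchemaError",
    "RowError",
    "canonical_key",
    "read_tissue_table",
    "read_ctdna_table",
    "read_driver_catalog",
    "read_panel_bed",
    "filter_to_panel",
    "write_newick",
    "read_newick",
    "CtdnaRecord",
    "cohort_from_frame",
    "ctdna_from_frame",
]


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    CNV = "CNV"
    FUSION = "FUSION"


class DriverRole(str, Enum):
    ONCOGENE = "ONCOGENE"
    TSG = "TSG"
    PASSENGER = "PASSENGER"


class Subtype(str, Enum):
    """NSCLC molecular/histological subtypes."""

    EGFR_LUAD = "EGFR_LUAD"
    KRAS_LUAD = "KRAS_LUAD"
    WT_LUAD = "WT_LUAD"
    LUSC = "LUSC"
    LELC = "LELC"


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class RowError(ValueError):
    """A single row violates the format; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


def canonical_key(chrom: str, pos: int, ref: str, alt: str, gene: str,
                  vclass: VariantClass) -> str:
    """Canonical identity of an alteration, shared by tissue and plasma tables.

    SNV/INDEL: ``chrom:pos:ref:alt``. CNV/FUSION: ``gene:vclass:alt`` (alt carries
    the event, e.g. ``AMP``, ``DEL`` or the fusion partner); such events are
    matched at gene level because they have no single base-pair coordinate.
    """
    if vclass in (VariantClass.SNV, VariantClass.INDEL):
        return f"{chrom}:{pos}:{ref}:{alt}"
    return f"{gene}:{vclass.value}:{alt}"


@dataclass(frozen=True)
class Variant:
    """One somatic alteration observed in one patient."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    vclass: VariantClass

    @property
    def key(self) -> str:
        return canonical_key(self.chrom, self.pos, self.ref, self.alt,
                             self.gene, self.vclass)

    def __post_init__(self):
        if self.vclass in (VariantClass.SNV, VariantClass.INDEL) and self.pos < 1:
            raise ValueError(f"pos must be >= 1 for {self.vclass.value}, got {self.pos}")


@dataclass(frozen=True)
class RegionObservation:
    """Per-region sequencing evidence for one variant."""

    variant_key: str
    region_id: str
    vaf: float | None = None
    alt_reads: int | None = None
    depth: int | None = None

    def __post_init__(self):
        if self.alt_reads is not None and self.depth is not None:
            if self.alt_reads > self.depth:
                raise ValueError("alt_reads exceeds depth")
        if self.alt_reads is not None and self.alt_reads < 0:
            raise ValueError("negative alt_reads")


@dataclass
class PatientRecord:
    patient_id: str
    region_ids: list[str]
    subtype: Subtype | None = None
    stage: str | None = None

    def __post_init__(self):
        if not self.region_ids:
            raise ValueError(f"patient {self.patient_id} has no regions")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError(f"patient {self.patient_id} has duplicate region ids")


@dataclass
class DriverCatalog:
    """Mapping gene -> driver role; genes absent are passengers by definition."""

    roles: dict[str, DriverRole] = field(default_factory=dict)

    def role_of(self, gene: str) -> DriverRole:
        return self.roles.get(gene, DriverRole.PASSENGER)

    def __contains__(self, gene: str) -> bool:
        return gene in self.roles

    def __len__(self) -> int:
        return len(self.roles)


@dataclass
class Cohort:
    """All tissue evidence for a set of patients.

    ``variants`` maps (patient_id, variant_key) to the deduplicated Variant;
    ``observations`` maps patient_id to that patient's region observations.
    """

    patients: dict[str, PatientRecord] = field(default_factory=dict)
    variants: dict[tuple[str, str], Variant] = field(default_factory=dict)
    observations: dict[str, list[RegionObservation]] = field(default_factory=dict)

    def patient_variants(self, patient_id: str) -> list[Variant]:
        return [v for (pid, _), v in sorted(self.variants.items()) if pid == patient_id]


import contextlib
import io as _io


@contextlib.contextmanager
def _open_text(path_or_buffer):
    """Accept a filesystem path or an open text buffer."""
    if hasattr(path_or_buffer, "read"):
        yield path_or_buffer
    else:
        with open(path_or_buffer, newline="", encoding="utf-8") as fh:
            yield fh


def _frame_buffer(df) -> _io.StringIO:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    buf.seek(0)
    return buf


def cohort_from_frame(df) -> "Cohort":
    """Build a Cohort from an in-memory tissue DataFrame; exactly equivalent
    to writing the frame as TSV and calling :func:`read_tissue_table`."""
    return read_tissue_table(_frame_buffer(df))


def ctdna_from_frame(df) -> "list[CtdnaRecord]":
    """In-memory counterpart of :func:`read_ctdna_table`."""
    return read_ctdna_table(_frame_buffer(df))


REQUIRED_TISSUE_COLUMNS = ("patient_id", "region_id", "chrom", "pos", "ref",
                           "alt", "gene", "vclass")
CTDNA_COLUMNS = ("patient_id", "chrom", "pos", "ref", "alt", "gene", "vclass",
                 "mutant_reads", "depth")

_MISSING = (".", "", "NA")


def _parse_vclass(text: str, line: int) -> VariantClass:
    try:
        return VariantClass(text.strip().upper())
    except ValueError:
        raise RowError(line, f"vclass '{text}' not one of "
                             f"{[c.value for c in VariantClass]}") from None


def _parse_int(text: str, name: str, line: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise RowError(line, f"non-integer {name}: '{text}'") from None


def _opt_float(text: str) -> float | None:
    return None if text in _MISSING else float(text)


def _opt_int(text: str, name: str, line: int) -> int | None:
    return None if text in _MISSING else _parse_int(text, name, line)


def read_tissue_table(path: str | Path,
                      schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a multi-region tissue variant TSV into a :class:`Cohort`.

    Parameters
    ----------
    path
        Tab-separated file with a header. Required columns:
        patient_id, region_id, chrom, pos, ref, alt, gene, vclass.
        Optional: subtype, stage, vaf, alt_reads, depth ('.' = missing).
        Extra columns are ignored.
    schema
        Optional mapping from the canonical column name to the name used in the
        file, for tables with renamed headers.

    Row order does not affect the result. Duplicate (patient, region, key) rows
    are rejected as ambiguous evidence.
    """
    schema = dict(schema or {})
    col = lambda name: schema.get(name, name)

    cohort = Cohort()
    seen: set[tuple[str, str, str]] = set()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for name in REQUIRED_TISSUE_COLUMNS:
            if col(name) not in header:
                raise SchemaError(f"missing required column '{col(name)}'")
        has = lambda name: col(name) in header

        for line_no, row in enumerate(reader, start=2):
            vclass = _parse_vclass(row[col("vclass")], line_no)
            pos_text = row[col("pos")]
            pos = 0 if pos_text in _MISSING else _parse_int(pos_text, "pos", line_no)
            pid = row[col("patient_id")].strip()
            region = row[col("region_id")].strip()
            try:
                variant = Variant(pid, row[col("chrom")].strip(), pos,
                                  row[col("ref")].strip(), row[col("alt")].strip(),
                                  row[col("gene")].strip(), vclass)
            except ValueError as exc:
                raise RowError(line_no, str(exc)) from None
            key = variant.key

            dup = (pid, region, key)
            if dup in seen:
                raise RowError(line_no, f"duplicate observation of {key} in "
                                        f"patient {pid} region {region}")
            seen.add(dup)

            try:
                obs = RegionObservation(
                    variant_key=key, region_id=region,
                    vaf=_opt_float(row[col("vaf")]) if has("vaf") else None,
                    alt_reads=_opt_int(row[col("alt_reads")], "alt_reads", line_no)
                    if has("alt_reads") else None,
                    depth=_opt_int(row[col("depth")], "depth", line_no)
                    if has("depth") else None,
                )
            except ValueError as exc:
                raise RowError(line_no, str(exc)) from None

            subtype = None
            if has("subtype") and row[col("subtype")] not in _MISSING:
                subtype = Subtype(row[col("subtype")].strip())
            stage = row[col("stage")].strip() if has("stage") and \
                row[col("stage")] not in _MISSING else None

            if pid not in cohort.patients:
                cohort.patients[pid] = PatientRecord(pid, [region], subtype, stage)
                cohort.observations[pid] = []
            else:
                rec = cohort.patients[pid]
                if region not in rec.region_ids:
                    rec.region_ids.append(region)
                if rec.subtype is None and subtype is not None:
                    rec.subtype = subtype
            cohort.variants.setdefault((pid, key), variant)
            cohort.observations[pid].append(obs)

    # canonical ordering independent of input row order
    for rec in cohort.patients.values():
        rec.region_ids.sort()
    for pid in cohort.observations:
        cohort.observations[pid].sort(key=lambda o: (o.variant_key, o.region_id))
    return cohort


@dataclass(frozen=True)
class CtdnaRecord:
    patient_id: str
    variant_key: str
    mutant_reads: int
    depth: int


def read_ctdna_table(path: str | Path) -> list[CtdnaRecord]:
    """Read plasma mutant-read counts; keys canonicalized as in tissue tables.

    mutant_reads is the count of high-quality mutant reads after upstream
    filtering; zero-read rows are retained (detection is decided downstream).
    """
    records: list[CtdnaRecord] = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for name in CTDNA_COLUMNS:
            if name not in header:
                raise SchemaError(f"missing required column '{name}'")
        for line_no, row in enumerate(reader, start=2):
            vclass = _parse_vclass(row["vclass"], line_no)
            pos = 0 if row["pos"] in _MISSING else _parse_int(row["pos"], "pos", line_no)
            reads = _parse_int(row["mutant_reads"], "mutant_reads", line_no)
            depth = _parse_int(row["depth"], "depth", line_no)
            if reads < 0 or depth < 0:
                raise RowError(line_no, "negative read counts")
            if reads > depth:
                raise RowError(line_no, f"mutant_reads {reads} > depth {depth}")
            key = canonical_key(row["chrom"].strip(), pos, row["ref"].strip(),
                                row["alt"].strip(), row["gene"].strip(), vclass)
            records.append(CtdnaRecord(row["patient_id"].strip(), key, reads, depth))
    return records


def read_driver_catalog(path: str | Path) -> DriverCatalog:
    """Read a two-column gene/role TSV; roles parsed case-insensitively."""
    roles: dict[str, DriverRole] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for name in ("gene", "role"):
            if name not in header:
                raise SchemaError(f"missing required column '{name}'")
        for line_no, row in enumerate(reader, start=2):
            gene = row["gene"].strip()
            text = row["role"].strip().upper()
            if text not in (DriverRole.ONCOGENE.value, DriverRole.TSG.value):
                raise RowError(line_no, f"unknown driver role '{row['role']}'")
            role = DriverRole(text)
            if gene in roles and roles[gene] != role:
                raise RowError(line_no, f"gene {gene} listed with conflicting roles")
            roles[gene] = role
    return DriverCatalog(roles)


def read_panel_bed(path: str | Path) -> tuple[dict[str, IntervalTree], set[str]]:
    """Read a 4-column BED of panel target regions (0-based half-open).

    Returns per-chromosome interval trees and the set of panel gene names
    (column 4), used for matching gene-level CNV/fusion records.
    """
    trees: dict[str, IntervalTree] = {}
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError(line_no, f"BED line has {len(fields)} fields, need >= 3")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise RowError(line_no, f"non-integer BED coordinates: {line!r}") from None
            if end < start:
                raise RowError(line_no, f"BED end < start: {line!r}")
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
            if len(fields) >= 4 and fields[3]:
                genes.add(fields[3])
    return trees, genes


def filter_to_panel(cohort: Cohort, panel: tuple[dict[str, IntervalTree], set[str]]) -> Cohort:
    """Restrict a cohort to variants covered by a capture panel.

    SNV/INDEL records are kept when their 1-based position falls inside a panel
    interval (BED half-open (start, end] in 1-based terms); CNV/FUSION records
    are kept when their gene is a panel gene name. Observations of dropped
    variants are dropped with them. Idempotent.
    """
    trees, genes = panel
    kept: dict[tuple[str, str], Variant] = {}
    for (pid, key), variant in cohort.variants.items():
        if variant.vclass in (VariantClass.SNV, VariantClass.INDEL):
            tree = trees.get(variant.chrom)
            # 1-based pos p lies in 0-based half-open [start, end) iff p-1 in it
            if tree is not None and tree.overlaps_point(variant.pos - 1):
                kept[(pid, key)] = variant
        else:
            if variant.gene in genes:
                kept[(pid, key)] = variant

    kept_keys_by_patient: dict[str, set[str]] = {}
    for pid, key in kept:
        kept_keys_by_patient.setdefault(pid, set()).add(key)

    out = Cohort()
    for pid, rec in cohort.patients.items():
        keys = kept_keys_by_patient.get(pid, set())
        if not keys:
            continue
        out.patients[pid] = replace(rec, region_ids=list(rec.region_ids))
        out.observations[pid] = [o for o in cohort.observations[pid]
                                 if o.variant_key in keys]
    out.variants = kept
    return out


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialize a phylogeny as Newick with mutation-count branch lengths.

    The root is labeled ``germline``; leaves are region names. Re-reading the
    file reproduces topology and edge lengths exactly.
    """
    for leaf in tree.leaves():
        if not leaf.name:
            raise ValueError("tree has an unnamed leaf")
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_newick(path: str | Path):
    """Parse a Newick file with dendropy; returns a dendropy Tree."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tsv(df, path: str | Path) -> None:
    """Write a result table as UTF-8, LF, tab-separated with header."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
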