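"""Gene annotation I/O and the protein-coding filtering cascade.

Gene boundaries are genomic ``(start, end)`` coordinates, 1-based and
inclusive on both ends, as exported by Ensembl/BioMart.  Overlap analysis
downstream works purely on these gene-level boundaries; transcript and exon
structure is out of scope.

The filtering cascade mirrors a typical curation of an Ensembl gene dump:

1. keep protein-coding biotype only,
2. drop records on non-primary assemblies (scaffolds, patches),
3. collapse duplicated gene names (keep the lexicographically smallest
   stable ID),
4. drop readthrough transcripts,
5. drop novel genes without a description or an official symbol,
6. drop anything on an explicit exclusion list.

Each removed record is attributed to exactly one stage (first match wins),
and the :class:`FilterReport` arithmetic ``retained = input - sum(removed)``
always holds.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GeneRecord",
    "FilterReport",
    "AnnotationParseError",
    "AnnotationValidationError",
    "PRIMARY_CHROMOSOMES",
    "read_gene_annotation",
    "filter_genes",
    "write_gene_table",
    "write_bed",
    "chromosome_sort_key",
]

FORWARD = "+"
REVERSE = "-"

#: Primary human-style assembly: autosomes plus the sex chromosomes.
#: The mitochondrial genome is excluded by default (configurable).
PRIMARY_CHROMOSOMES = frozenset(str(c) for c in range(1, 23)) | {"X", "Y"}

_STRAND_MAP = {
    "+": FORWARD,
    "1": FORWARD,
    "forward": FORWARD,
    "-": REVERSE,
    "-1": REVERSE,
    "reverse": REVERSE,
}


class AnnotationParseError(ValueError):
    """A line of an annotation file could not be parsed."""


class AnnotationValidationError(ValueError):
    """Parsed records violate a GeneRecord invariant."""


def normalize_strand(value) -> str:
    """Map ``+/-`` and ``1/-1`` encodings onto the internal ``+``/``-``."""
    key = str(value).strip()
    try:
        return _STRAND_MAP[key]
    except KeyError:
        raise AnnotationValidationError(f"unrecognized strand encoding: {value!r}")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with 1-based inclusive genomic boundaries."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    gene_name: Optional[str] = None
    description: Optional[str] = None
    readthrough_flag: bool = False

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise AnnotationValidationError(
                f"gene {self.gene_id}: invalid coordinates "
                f"start={self.start} end={self.end} (need 1 <= start <= end)"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise AnnotationValidationError(
                f"gene {self.gene_id}: strand must be {FORWARD!r} or {REVERSE!r}, "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_readthrough(self) -> bool:
        """Flagged explicitly, or the description mentions 'readthrough'."""
        if self.readthrough_flag:
            return True
        return bool(self.description) and "readthrough" in self.description.lower()

    @property
    def is_novel_without_description(self) -> bool:
        """Novel gene: no free-text description and no official symbol."""
        return not self.description and not self.gene_name


@dataclass
class FilterReport:
    """Per-stage removal counts for one run of :func:`filter_genes`."""

    input_records: int = 0
    removed_non_protein_coding: int = 0
    removed_nonprimary_assembly: int = 0
    removed_duplicate_names: int = 0
    removed_readthrough: int = 0
    removed_novel_embedded: int = 0
    removed_via_exclusion_list: int = 0
    retained: int = 0

    def total_removed(self) -> int:
        return (
            self.removed_non_protein_coding
            + self.removed_nonprimary_assembly
            + self.removed_duplicate_names
            + self.removed_readthrough
            + self.removed_novel_embedded
            + self.removed_via_exclusion_list
        )

    def check(self) -> None:
        if self.retained != self.input_records - self.total_removed():
            raise AnnotationValidationError(
                f"inconsistent filter report: {self.input_records} input, "
                f"{self.total_removed()} removed, {self.retained} retained"
            )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

#: BioMart export header -> internal field name.  Plain internal names are
#: accepted as well, so the module's own TSV output round-trips.
BIOMART_COLUMNS = {
    "Gene stable ID": "gene_id",
    "Gene name": "gene_name",
    "Chromosome/scaffold name": "chromosome",
    "Gene start (bp)": "start",
    "Gene end (bp)": "end",
    "Strand": "strand",
    "Gene type": "biotype",
    "Gene description": "description",
}

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _gene_from_fields(
    fieldmap: Mapping[str, str], lineno: int, path
) -> GeneRecord:
    try:
        start = int(fieldmap["start"])
        end = int(fieldmap["end"])
    except (KeyError, ValueError) as exc:
        raise AnnotationParseError(
            f"{path}:{lineno}: bad or missing coordinates ({exc})"
        ) from None
    name = fieldmap.get("gene_name") or None
    desc = fieldmap.get("description") or None
    rt = str(fieldmap.get("readthrough", "")).strip().lower() in {"1", "true", "yes"}
    try:
        return GeneRecord(
            gene_id=fieldmap["gene_id"],
            chromosome=str(fieldmap["chromosome"]),
            start=start,
            end=end,
            strand=normalize_strand(fieldmap["strand"]),
            biotype=fieldmap.get("biotype", "protein_coding"),
            gene_name=name,
            description=desc,
            readthrough_flag=rt,
        )
    except KeyError as exc:
        raise AnnotationParseError(f"{path}:{lineno}: missing field {exc}") from None


def _read_tsv(path: Path, column_map: Mapping[str, str]) -> list[GeneRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return []
        cols = [column_map.get(h, h) for h in header]
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(cols):
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(row)}"
                )
            records.append(_gene_from_fields(dict(zip(cols, row)), lineno, path))
    return records


def _read_gtf(path: Path) -> list[GeneRecord]:
    # Only 'gene' feature lines carry gene-level boundaries; everything else
    # (transcripts, exons, CDS) is skipped.
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF columns, "
                    f"got {len(parts)}"
                )
            if parts[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR_RE.findall(parts[8]))
            if "gene_id" not in attrs:
                raise AnnotationParseError(
                    f"{path}:{lineno}: gene feature without gene_id attribute"
                )
            fieldmap = {
                "gene_id": attrs["gene_id"],
                "chromosome": parts[0],
                "start": parts[3],
                "end": parts[4],
                "strand": parts[6],
                "biotype": attrs.get("gene_biotype", ""),
                "gene_name": attrs.get("gene_name", ""),
                "description": attrs.get("description", ""),
                "readthrough": attrs.get("readthrough", ""),
            }
            records.append(_gene_from_fields(fieldmap, lineno, path))
    return records


def read_gene_annotation(
    path,
    format: str = "tsv",
    column_map: Optional[Mapping[str, str]] = None,
) -> list[GeneRecord]:
    """Read gene records from a TSV (BioMart-like) or Ensembl-dialect GTF.

    Parameters
    ----------
    path
        Annotation file.
    format
        ``"tsv"`` or ``"gtf"``.
    column_map
        For TSV input, mapping of file header names to internal field names.
        Defaults to the BioMart export headers; internal names always work.

    Returns
    -------
    list of GeneRecord, in file order.

    Raises
    ------
    AnnotationParseError
        On malformed lines (the message names the offending line).
    AnnotationValidationError
        On start > end, bad strand, or duplicated gene IDs.
    """
    path = Path(path)
    if format == "tsv":
        cmap = dict(BIOMART_COLUMNS)
        if column_map:
            cmap.update(column_map)
        records = _read_tsv(path, cmap)
    elif format == "gtf":
        records = _read_gtf(path)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")

    seen: dict[str, int] = {}
    for rec in records:
        if rec.gene_id in seen:
            raise AnnotationValidationError(
                f"{path}: duplicate gene_id {rec.gene_id!r}"
            )
        seen[rec.gene_id] = 1
    return records


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

def filter_genes(
    records: Sequence[GeneRecord],
    primary_chromosomes: Iterable[str] = PRIMARY_CHROMOSOMES,
    exclusion_ids: Optional[Iterable[str]] = None,
    protein_coding_biotype: str = "protein_coding",
) -> tuple[list[GeneRecord], FilterReport]:
    """Apply the curation cascade and return (retained records, report).

    Stage order is fixed: biotype -> assembly -> duplicate gene name ->
    readthrough -> novel-without-description -> exclusion list.  Each record
    is charged to the first stage that removes it.  Among records sharing a
    gene name, the one with the lexicographically smallest gene_id is kept
    (a deterministic stand-in for manual curation).
    """
    primary = {str(c) for c in primary_chromosomes}
    if not primary:
        raise ValueError("primary_chromosomes must be non-empty")
    excluded = set(exclusion_ids) if exclusion_ids else set()

    report = FilterReport(input_records=len(records))

    stage1 = []
    for rec in records:
        if rec.biotype != protein_coding_biotype:
            report.removed_non_protein_coding += 1
        elif rec.chromosome not in primary:
            report.removed_nonprimary_assembly += 1
        else:
            stage1.append(rec)

    # duplicate gene names: keep smallest gene_id per shared (non-empty) name
    keep_for_name: dict[str, str] = {}
    for rec in stage1:
        if rec.gene_name:
            cur = keep_for_name.get(rec.gene_name)
            if cur is None or rec.gene_id < cur:
                keep_for_name[rec.gene_name] = rec.gene_id

    retained = []
    for rec in stage1:
        if rec.gene_name and keep_for_name[rec.gene_name] != rec.gene_id:
            report.removed_duplicate_names += 1
        elif rec.is_readthrough:
            report.removed_readthrough += 1
        elif rec.is_novel_without_description:
            report.removed_novel_embedded += 1
        elif rec.gene_id in excluded:
            report.removed_via_exclusion_list += 1
        else:
            retained.append(rec)

    report.retained = len(retained)
    report.check()
    return retained, report


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "gene_id", "gene_name", "chromosome", "start", "end",
    "strand", "biotype", "description", "readthrough",
]


def write_gene_table(records: Sequence[GeneRecord], path) -> None:
    """Write records as a TSV that round-trips through read_gene_annotation."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.gene_id,
                rec.gene_name or "",
                rec.chromosome,
                rec.start,
                rec.end,
                rec.strand,
                rec.biotype,
                rec.description or "",
                "1" if rec.readthrough_flag else "",
            ])


def write_bed(records: Sequence[GeneRecord], path) -> None:
    """Write BED6: 0-based half-open, name=gene_id, score=0, strand +/-."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chromosome}\t{rec.start - 1}\t{rec.end}\t"
                f"{rec.gene_id}\t0\t{rec.strand}\n"
            )


_CHROM_SPECIAL = {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chromosome_sort_key(chrom: str):
    """Natural ordering: 1..22, X, Y, MT, then everything else by name."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    if c in _CHROM_SPECIAL:
        return (0, _CHROM_SPECIAL[c], "")
    return (1, 0, c)
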