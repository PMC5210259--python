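"""Per-data-type converters from original TCGA row layouts to free-BED records.

One converter exists per (experiment type, subtype); all share the same
contract: ``convert(rows, store) -> (records, report)`` where *rows* are
the parsed tab-delimited rows of one source file and *report* accounts
for every input row (``rows_in == records_out + dropped`` except for the
miRNA multi-locus expansion, where one surviving row may emit several
records).  Records come out sorted in karyotype order so repeated runs
serialize byte-identically.

Coordinates in the source files are already one-based (the convention the
whole repository keeps), so converters copy positions; they never shift
them.  Quantification values are copied, never recalculated — only their
textual representation is canonicalized per the schema value kinds.

Rows whose genomic region cannot be established (unknown miRNA/gene/
isoform id, end before start, junction spanning two chromosomes) are
dropped and counted; a missing *strand* alone never drops a row — the
record is emitted with the ``*`` placeholder and the miss is reported.

Converters register themselves in a dispatch table keyed by
(type, subtype); supporting a new layout only requires one new
registration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .annotations import (
    AnnotationMiss,
    AnnotationStore,
    coords_by_entrez,
    coords_by_mirna,
    entrez_by_ucsc,
    strand_by_symbol,
)
from .core import (
    BedRecord,
    GenomicRegion,
    UNKNOWN_STRAND,
    format_value,
    normalize_chrom,
    records_sorted,
)
from .errors import ChromosomeError, MalformedInputError, SchemaError
from .schemas import get_schema

logger = logging.getLogger(__name__)

__all__ = [
    "ConversionReport",
    "CONVERTERS",
    "get_converter",
    "read_source_file",
    "convert_cnv",
    "convert_methylation",
    "convert_dnaseq",
    "convert_mirnaseq",
    "convert_rnaseq_gene",
    "convert_rnaseq_exon",
    "convert_rnaseq_spljxn",
    "convert_rnaseqv2_isoform",
]

#: Hidden per-row key carrying the original file line number.
LINE_KEY = "__line__"


@dataclass
class ConversionReport:
    """Per-file conversion accounting."""

    rows_in: int = 0
    records_out: int = 0
    dropped: int = 0
    misses: list[AnnotationMiss] = field(default_factory=list)

    def merge(self, other: "ConversionReport") -> "ConversionReport":
        self.rows_in += other.rows_in
        self.records_out += other.records_out
        self.dropped += other.dropped
        self.misses.extend(other.misses)
        return self


Converter = Callable[..., tuple[list[BedRecord], ConversionReport]]

CONVERTERS: dict[tuple[str, str | None], Converter] = {}


def _register(exp_type: str, subtype: str | None = None):
    def deco(fn: Converter) -> Converter:
        CONVERTERS[(exp_type, subtype)] = fn
        return fn
    return deco


def get_converter(exp_type: str, subtype: str | None = None) -> Converter:
    try:
        return CONVERTERS[(exp_type, subtype)]
    except KeyError:
        raise SchemaError(
            f"no converter registered for type {exp_type!r}, subtype {subtype!r}"
        ) from None


# ---------------------------------------------------------------------------
# source-file reading
# ---------------------------------------------------------------------------

def read_source_file(path: str | Path) -> list[dict[str, str]]:
    """Read a tab-delimited original file into row mappings.

    The first non-comment line is the header; leading ``#`` lines (MAF
    version pragmas) are skipped.  Each row keeps its 1-based file line
    number under :data:`LINE_KEY` so errors can cite the exact line.
    """
    path = Path(path)
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if header is None:
                if line.startswith("#") or not line.strip():
                    continue
                header = line.split("\t")
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise MalformedInputError(
                    f"expected {len(header)} fields, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            row = dict(zip(header, fields))
            row[LINE_KEY] = str(lineno)
            rows.append(row)
    return rows


def _iter_rows(rows: Iterable[Mapping[str, str]]):
    for idx, row in enumerate(rows):
        lineno = int(row.get(LINE_KEY, idx + 2))  # header assumed on line 1
        yield lineno, row


def _get(row: Mapping[str, str], column: str, source: str | None, lineno: int) -> str:
    try:
        return row[column]
    except KeyError:
        raise MalformedInputError(
            "missing mandatory column", path=source, line=lineno, column=column
        ) from None


def _int(text: str, column: str, source: str | None, lineno: int) -> int:
    try:
        return int(float(text)) if "." in text else int(text)
    except ValueError:
        raise MalformedInputError(
            f"not an integer: {text!r}", path=source, line=lineno, column=column
        ) from None


def _chrom(text: str, column: str, source: str | None, lineno: int) -> str:
    try:
        return normalize_chrom(text)
    except ChromosomeError as exc:
        raise MalformedInputError(
            str(exc), path=source, line=lineno, column=column
        ) from exc


def _attr(kind: str, raw: str | None, column: str, source: str | None, lineno: int):
    try:
        return format_value(kind, raw)
    except ValueError as exc:
        raise MalformedInputError(
            str(exc), path=source, line=lineno, column=column
        ) from exc


def _record(schema, region: GenomicRegion,
            values: Mapping[str, str | None]) -> BedRecord:
    return BedRecord(
        region=region,
        attributes=tuple(
            (name, values.get(name)) for name, _ in schema.attribute_columns
        ),
    )


def _is_null(text: str) -> bool:
    return text.strip().lower() in {"", "na", "n/a", "null", "none", "nan"}


def _finish(records: list[BedRecord], report: ConversionReport):
    report.records_out = len(records)
    return records_sorted(records), report


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

@_register("cnv")
def convert_cnv(rows: Iterable[Mapping[str, str]],
                store: AnnotationStore | None = None, *,
                source: str | None = None):
    """Convert a copy-number segment file.

    Segments carry their own coordinates and no strand; the strand field
    takes the ``*`` placeholder.  Rows whose interval is inverted or
    starts before base 1 are dropped and counted.
    """
    schema = get_schema("cnv")
    records: list[BedRecord] = []
    report = ConversionReport()
    for lineno, row in _iter_rows(rows):
        report.rows_in += 1
        chrom = _chrom(_get(row, "Chromosome", source, lineno), "Chromosome",
                       source, lineno)
        start = _int(_get(row, "Start", source, lineno), "Start", source, lineno)
        end = _int(_get(row, "End", source, lineno), "End", source, lineno)
        if start < 1 or end < start:
            report.dropped += 1
            logger.debug("%s line %d: invalid segment %s:%d-%d, dropped",
                         source, lineno, chrom, start, end)
            continue
        records.append(_record(schema, GenomicRegion(chrom, start, end), {
            "num_probes": _attr("integer", row.get("Num_Probes"), "Num_Probes",
                                source, lineno),
            "segment_mean": _attr("float", row.get("Segment_Mean"), "Segment_Mean",
                                  source, lineno),
        }))
    return _finish(records, report)


# ---------------------------------------------------------------------------
# DNA methylation
# ---------------------------------------------------------------------------

@_register("dnamethylation")
def convert_methylation(rows: Iterable[Mapping[str, str]],
                        store: AnnotationStore, *,
                        source: str | None = None):
    """Convert a methylation beta-value file.

    Probes give chromosome and position directly; each probe becomes a
    single-base region (start == end, legal under the closed-interval
    convention).  The strand is not in the source file: it is recovered
    through the gene-symbol → Entrez id → coordinates chain, and left as
    ``*`` (with a reported miss) when the chain breaks — the position is
    present, so the row itself is kept.
    """
    schema = get_schema("dnamethylation")
    records: list[BedRecord] = []
    report = ConversionReport()
    for lineno, row in _iter_rows(rows):
        report.rows_in += 1
        chrom_raw = _get(row, "Chromosome", source, lineno)
        pos_raw = _get(row, "Genomic_Coordinate", source, lineno)
        if _is_null(chrom_raw) or _is_null(pos_raw):
            report.dropped += 1
            logger.debug("%s line %d: probe without coordinates, dropped",
                         source, lineno)
            continue
        chrom = _chrom(chrom_raw, "Chromosome", source, lineno)
        pos = _int(pos_raw, "Genomic_Coordinate", source, lineno)
        if pos < 1:
            report.dropped += 1
            continue
        symbol_raw = _get(row, "Gene_Symbol", source, lineno)
        strand = UNKNOWN_STRAND
        if _is_null(symbol_raw):
            report.misses.append(
                AnnotationMiss("symbol", symbol_raw.strip(), "symbol_to_entrez"))
        else:
            resolved = strand_by_symbol(store, symbol_raw.strip())
            if isinstance(resolved, AnnotationMiss):
                report.misses.append(resolved)
            else:
                strand = resolved
        records.append(_record(
            schema, GenomicRegion(chrom, pos, pos, strand), {
                "composite_element_ref": _attr(
                    "string", row.get("Composite Element REF"),
                    "Composite Element REF", source, lineno),
                "beta_value": _attr("float", row.get("Beta_value"), "Beta_value",
                                    source, lineno),
                "gene_symbol": _attr("string", symbol_raw, "Gene_Symbol",
                                     source, lineno),
            }))
    return _finish(records, report)


# ---------------------------------------------------------------------------
# somatic mutations (MAF)
# ---------------------------------------------------------------------------

_MAF_ATTRS = (
    ("hugo_symbol", "Hugo_Symbol"),
    ("entrez_gene_id", "Entrez_Gene_Id"),
    ("variant_classification", "Variant_Classification"),
    ("variant_type", "Variant_Type"),
    ("reference_allele", "Reference_Allele"),
    ("tumor_seq_allele1", "Tumor_Seq_Allele1"),
    ("tumor_seq_allele2", "Tumor_Seq_Allele2"),
    ("dbsnp_rs", "dbSNP_RS"),
    ("tumor_sample_barcode", "Tumor_Sample_Barcode"),
    ("matched_norm_sample_barcode", "Matched_Norm_Sample_Barcode"),
    ("mutation_status", "Mutation_Status"),
    ("sequencer", "Sequencer"),
    ("validation_status", "Validation_Status"),
)


@_register("dnaseq")
def convert_dnaseq(rows: Iterable[Mapping[str, str]],
                   store: AnnotationStore | None = None, *,
                   source: str | None = None):
    """Convert a somatic-mutation MAF file (level-2 DNA-seq).

    Mutations carry complete coordinates and strand; thirteen MAF columns
    are carried through as attributes.  A row lacking a mandatory
    coordinate column is a malformed input, not a droppable row.
    """
    schema = get_schema("dnaseq")
    records: list[BedRecord] = []
    report = ConversionReport()
    for lineno, row in _iter_rows(rows):
        report.rows_in += 1
        chrom = _chrom(_get(row, "Chromosome", source, lineno), "Chromosome",
                       source, lineno)
        start = _int(_get(row, "Start_position", source, lineno),
                     "Start_position", source, lineno)
        end = _int(_get(row, "End_position", source, lineno),
                   "End_position", source, lineno)
        if start < 1 or end < start:
            report.dropped += 1
            logger.debug("%s line %d: invalid mutation interval, dropped",
                         source, lineno)
            continue
        strand_raw = _get(row, "Strand", source, lineno).strip()
        strand = strand_raw if strand_raw in ("+", "-") else UNKNOWN_STRAND
        values = {
            name: _attr(schema.kind_of(name), row.get(maf_col), maf_col,
                        source, lineno)
            for name, maf_col in _MAF_ATTRS
        }
        records.append(_record(schema, GenomicRegion(chrom, start, end, strand),
                               values))
    return _finish(records, report)


# ---------------------------------------------------------------------------
# miRNA-seq
# ---------------------------------------------------------------------------

@_register("mirnaseq")
def convert_mirnaseq(rows: Iterable[Mapping[str, str]],
                     store: AnnotationStore, *,
                     source: str | None = None):
    """Convert a miRNA quantification file.

    The source rows name miRNAs only; their genomic loci come from the
    miRBase-derived table.  A miRNA mapping to several loci expands into
    one record per locus (identical attributes), so ``records_out`` may
    exceed ``rows_in - dropped``.  An unknown id drops the row: the
    coordinates *are* the region, nothing can be emitted without them.
    """
    schema = get_schema("mirnaseq")
    records: list[BedRecord] = []
    report = ConversionReport()
    for lineno, row in _iter_rows(rows):
        report.rows_in += 1
        mirna_id = _get(row, "miRNA_ID", source, lineno).strip()
        loci = coords_by_mirna(store, mirna_id)
        if isinstance(loci, AnnotationMiss):
            report.misses.append(loci)
            report.dropped += 1
            logger.debug("%s line %d: unknown miRNA id %s, dropped",
                         source, lineno, mirna_id)
            continue
        values = {
            "mirna_id": mirna_id,
            "read_count": _attr("integer", row.get("read_count"), "read_count",
                                source, lineno),
            "reads_per_million_mirna_mapped": _attr(
                "float", row.get("reads_per_million_miRNA_mapped"),
                "reads_per_million_miRNA_mapped", source, lineno),
            "cross_mapped": _attr("char", row.get("cross-mapped"), "cross-mapped",
                                  source, lineno),
        }
        for locus in loci:
            records.append(_record(schema, locus, values))
    return _finish(records, report)


# ---------------------------------------------------------------------------
# RNA-seq gene quantifications (V1 and V2)
# ---------------------------------------------------------------------------

def _split_gene_id(token: str, column: str, source: str | None, lineno: int):
    """Split the composite ``SYMBOL|entrez`` gene key; ``?`` means no symbol."""
    if "|" not in token:
        raise MalformedInputError(
            f"expected 'symbol|entrez_id', got {token!r}",
            path=source, line=lineno, column=column,
        )
    symbol, entrez_text = token.split("|", 1)
    entrez = _int(entrez_text.strip(), column, source, lineno)
    symbol = symbol.strip()
    return (None if symbol in ("?", "") else symbol), entrez


def convert_rnaseq_gene(rows: Iterable[Mapping[str, str]],
                        store: AnnotationStore,
                        version: str = "v2", *,
                        source: str | None = None):
    """Convert a gene quantification file (RNA-seq V1 or V2).

    The source provides only the ``SYMBOL|entrez`` gene key plus
    quantifications; coordinates and strand are recovered from the Entrez
    gene table.  Rows whose Entrez id has no stored placement are dropped
    (no coordinates, no region) with a reported miss.
    """
    version = version.lower()
    if version not in ("v1", "v2"):
        raise ValueError(f"unknown RNA-seq version {version!r}")
    if version == "v1":
        schema = get_schema("rnaseq", "gene")
        key_col = "gene"
        quant_cols = (("raw_counts", "raw_counts"),
                      ("median_length_normalized", "median_length_normalized"),
                      ("rpkm", "RPKM"))
    else:
        schema = get_schema("rnaseqv2", "gene")
        key_col = "gene_id"
        quant_cols = (("raw_count", "raw_count"),
                      ("scaled_estimate", "scaled_estimate"),
                      ("normalized_count", "normalized_count"))
    records: list[BedRecord] = []
    report = ConversionReport()
    for lineno, row in _iter_rows(rows):
        report.rows_in += 1
        symbol, entrez = _split_gene_id(_get(row, key_col, source, lineno),
                                        key_col, source, lineno)
        region = coords_by_entrez(store, entrez)
        if isinstance(region, AnnotationMiss):
            report.misses.append(region)
            report.dropped += 1
            logger.debug("%s line %d: no coordinates for Entrez id %s, dropped",
                         source, lineno, entrez)
            continue
        values: dict[str, str | None] = {
            "entrez_gene_id": str(entrez),
            "gene_symbol": symbol,
        }
        for name, col in quant_cols:
            values[name] = _attr(schema.kind_of(name), row.get(col), col,
                                 source, lineno)
        records.append(_record(schema, region, values))
    return _finish(records, report)


CONVERTERS[("rnaseq", "gene")] = lambda rows, store, **kw: convert_rnaseq_gene(
    rows, store, version="v1", **kw)
CONVERTERS[("rnaseqv2", "gene")] = lambda rows, store, **kw: convert_rnaseq_gene(
    rows, store, version="v2", **kw)


# ---------------------------------------------------------------------------
# RNA-seq exon quantifications
# ---------------------------------------------------------------------------

def _parse_exon_key(token: str, source: str | None, lineno: int):
    parts = token.strip().split(":")
    if len(parts) != 3 or "-" not in parts[1]:
        raise MalformedInputError(
            f"malformed exon key {token!r}", path=source, line=lineno,
            column="exon",
        )
    chrom = _chrom(parts[0], "exon", source, lineno)
    lo, _, hi = parts[1].partition("-")
    a = _int(lo, "exon", source, lineno)
    b = _int(hi, "exon", source, lineno)
    strand = parts[2].strip()
    if strand not in ("+", "-"):
        strand = UNKNOWN_STRAND
    return chrom, min(a, b), max(a, b), strand


def convert_rnaseq_exon(rows: Iterable[Mapping[str, str]],
                        store: AnnotationStore | None = None,
                        version: str = "v1", *,
                        source: str | None = None):
    """Convert an exon quantification file.

    Coordinates are embedded in the composite ``chrom:start-end:strand``
    exon key; no lookup is needed.  Minus-strand keys sometimes print the
    interval reversed, so start/end are normalized to start ≤ end while
    the original key is preserved as the ``exon`` attribute.
    """
    exp_type = "rnaseq" if version.lower() == "v1" else "rnaseqv2"
    schema = get_schema(exp_type, "exon")
    records: list[BedRecord] = []
    report = ConversionReport()
    for lineno, row in _iter_rows(rows):
        report.rows_in += 1
        key = _get(row, "exon", source, lineno)
        chrom, start, end, strand = _parse_exon_key(key, source, lineno)
        records.append(_record(
            schema, GenomicRegion(chrom, start, end, strand), {
                "exon": key.strip(),
                "raw_counts": _attr("integer", row.get("raw_counts"),
                                    "raw_counts", source, lineno),
                "median_length_normalized": _attr(
                    "float", row.get("median_length_normalized"),
                    "median_length_normalized", source, lineno),
                "rpkm": _attr("float", row.get("RPKM"), "RPKM", source, lineno),
            }))
    return _finish(records, report)


CONVERTERS[("rnaseq", "exon")] = lambda rows, store=None, **kw: convert_rnaseq_exon(
    rows, store, version="v1", **kw)
CONVERTERS[("rnaseqv2", "exon")] = lambda rows, store=None, **kw: convert_rnaseq_exon(
    rows, store, version="v2", **kw)


# ---------------------------------------------------------------------------
# RNA-seq splice-junction quantifications
# ---------------------------------------------------------------------------

def _parse_junction_half(token: str, source: str | None, lineno: int):
    parts = token.strip().split(":")
    if len(parts) != 3:
        raise MalformedInputError(
            f"malformed junction endpoint {token!r}", path=source, line=lineno,
            column="junction",
        )
    chrom = _chrom(parts[0], "junction", source, lineno)
    pos = _int(parts[1], "junction", source, lineno)
    strand = parts[2].strip()
    if strand not in ("+", "-"):
        strand = UNKNOWN_STRAND
    return chrom, pos, strand


def convert_rnaseq_spljxn(rows: Iterable[Mapping[str, str]],
                          store: AnnotationStore | None = None,
                          version: str = "v1", *,
                          source: str | None = None):
    """Convert a splice-junction quantification file.

    The composite junction key names donor and acceptor sites; the record
    region spans from the lower to the higher of the two positions
    (start ≤ end), while the ad-hoc donor/acceptor attributes preserve
    the original orientation.  A junction whose two sites sit on
    different chromosomes cannot form a single region and is dropped.
    """
    exp_type = "rnaseq" if version.lower() == "v1" else "rnaseqv2"
    schema = get_schema(exp_type, "spljxn")
    records: list[BedRecord] = []
    report = ConversionReport()
    for lineno, row in _iter_rows(rows):
        report.rows_in += 1
        key = _get(row, "junction", source, lineno)
        halves = key.strip().split(",")
        if len(halves) != 2:
            raise MalformedInputError(
                f"malformed junction key {key!r}", path=source, line=lineno,
                column="junction",
            )
        d_chrom, d_pos, d_strand = _parse_junction_half(halves[0], source, lineno)
        a_chrom, a_pos, _a_strand = _parse_junction_half(halves[1], source, lineno)
        if d_chrom != a_chrom:
            report.dropped += 1
            logger.debug("%s line %d: junction spans %s and %s, dropped",
                         source, lineno, d_chrom, a_chrom)
            continue
        region = GenomicRegion(d_chrom, min(d_pos, a_pos), max(d_pos, a_pos),
                               d_strand)
        records.append(_record(schema, region, {
            "donor_chrom": d_chrom,
            "donor_pos": str(d_pos),
            "acceptor_chrom": a_chrom,
            "acceptor_pos": str(a_pos),
            "raw_counts": _attr("integer", row.get("raw_counts"), "raw_counts",
                                source, lineno),
        }))
    return _finish(records, report)


CONVERTERS[("rnaseq", "spljxn")] = lambda rows, store=None, **kw: (
    convert_rnaseq_spljxn(rows, store, version="v1", **kw))
CONVERTERS[("rnaseqv2", "spljxn")] = lambda rows, store=None, **kw: (
    convert_rnaseq_spljxn(rows, store, version="v2", **kw))


# ---------------------------------------------------------------------------
# RNA-seq V2 isoform quantifications
# ---------------------------------------------------------------------------

@_register("rnaseqv2", "isoform")
def convert_rnaseqv2_isoform(rows: Iterable[Mapping[str, str]],
                             store: AnnotationStore, *,
                             source: str | None = None):
    """Convert an isoform quantification file (RNA-seq V2).

    Chain: UCSC transcript id → Entrez Gene id → gene coordinates, so two
    isoforms of one gene share a region and differ only in ``isoform_id``.
    Unresolvable transcripts are dropped with a reported miss.
    """
    schema = get_schema("rnaseqv2", "isoform")
    records: list[BedRecord] = []
    report = ConversionReport()
    for lineno, row in _iter_rows(rows):
        report.rows_in += 1
        isoform_id = _get(row, "isoform_id", source, lineno).strip()
        entrez = entrez_by_ucsc(store, isoform_id)
        if isinstance(entrez, AnnotationMiss):
            report.misses.append(entrez)
            report.dropped += 1
            continue
        region = coords_by_entrez(store, entrez)
        if isinstance(region, AnnotationMiss):
            report.misses.append(
                AnnotationMiss("ucsc", isoform_id, "entrez_coords"))
            report.dropped += 1
            continue
        records.append(_record(schema, region, {
            "isoform_id": isoform_id,
            "entrez_gene_id": str(entrez),
            "raw_count": _attr("float", row.get("raw_count"), "raw_count",
                               source, lineno),
            "scaled_estimate": _attr("float", row.get("scaled_estimate"),
                                     "scaled_estimate", source, lineno),
            "normalized_count": _attr("float", row.get("normalized_count"),
                                      "normalized_count", source, lineno),
        }))
    return _finish(records, report)
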