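"""Writers (and round-trip readers) for the supported output formats.

The primary output is the free-BED file: tab-delimited, headerless, one
line per feature, four mandatory fields followed by the schema's
attribute tail.  Structure lives solely in the companion
``header.schema`` XML descriptor, which is validated against the
package's shipped XML Schema.  CSV (RFC 4180), JSON, XML and GTF are
secondary renderings of the same records.

Coordinates are written one-based closed in every format — a deliberate,
documented deviation from UCSC BED's zero-based half-open convention:
the repository keeps the convention of the source data end to end (GTF is
natively one-based closed, so it needs no shift either).

BED, CSV and JSON have matching readers so round trips can be checked;
the null token is ``null`` in the text formats and a real JSON null.
"""

from __future__ import annotations

import csv
import json
from contextlib import contextmanager
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Sequence

from lxml import etree

from .core import (
    BedRecord,
    DataTypeSchema,
    GenomicRegion,
    MANDATORY_FIELDS,
    NULL_TOKEN,
    check_schema_conformity,
    format_float,
)
from .errors import MalformedInputError, SchemaError
from .schemas import get_schema

__all__ = [
    "write_bed", "read_bed",
    "write_csv", "read_csv",
    "write_json", "read_json",
    "write_xml",
    "write_gtf",
    "write_header_schema", "read_header_schema",
    "GTF_FEATURE_TOKENS",
    "GTF_SOURCE",
]


@contextmanager
def _sink(target):
    if hasattr(target, "write"):
        yield target
    else:
        with open(target, "w", encoding="utf-8", newline="") as fh:
            yield fh


@contextmanager
def _source(target):
    if hasattr(target, "read"):
        yield target
    else:
        with open(target, "r", encoding="utf-8", newline="") as fh:
            yield fh


def _text_fields(record: BedRecord) -> list[str]:
    r = record.region
    fields = [r.chrom, str(r.start), str(r.end), r.strand]
    fields.extend(v if v is not None else NULL_TOKEN
                  for _, v in record.attributes)
    return fields


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(records: Sequence[BedRecord], schema: DataTypeSchema, sink) -> None:
    """Write free-BED: headerless, tab-delimited, fields in schema order.

    Every line of a file carries the same ``4 + N`` field count; an empty
    record list produces an empty (0-byte) file.
    """
    check_schema_conformity(records, schema)
    with _sink(sink) as fh:
        for record in records:
            fh.write("\t".join(_text_fields(record)) + "\n")


def read_bed(source, schema: DataTypeSchema) -> list[BedRecord]:
    """Parse a free-BED file back into records under the given schema."""
    records: list[BedRecord] = []
    n_fields = len(schema.columns)
    attr_names = [name for name, _ in schema.attribute_columns]
    with _source(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise MalformedInputError(
                    f"expected {n_fields} fields, got {len(fields)}",
                    path=getattr(source, "name", None) if hasattr(source, "read")
                    else str(source),
                    line=lineno,
                )
            region = GenomicRegion(fields[0], int(fields[1]), int(fields[2]),
                                   fields[3])
            attrs = tuple(
                (name, None if value == NULL_TOKEN else value)
                for name, value in zip(attr_names, fields[4:])
            )
            records.append(BedRecord(region=region, attributes=attrs))
    return records


# ---------------------------------------------------------------------------
# CSV (RFC 4180)
# ---------------------------------------------------------------------------

def write_csv(records: Sequence[BedRecord], schema: DataTypeSchema, sink) -> None:
    """CSV with a header row of schema field names; RFC 4180 quoting."""
    check_schema_conformity(records, schema)
    with _sink(sink) as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(schema.field_names)
        for record in records:
            writer.writerow(_text_fields(record))


def read_csv(source, schema: DataTypeSchema) -> list[BedRecord]:
    attr_names = [name for name, _ in schema.attribute_columns]
    records: list[BedRecord] = []
    with _source(source) as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and tuple(header) != schema.field_names:
            raise MalformedInputError(
                f"CSV header {header} does not match schema "
                f"{list(schema.field_names)}"
            )
        for fields in reader:
            if not fields:
                continue
            region = GenomicRegion(fields[0], int(fields[1]), int(fields[2]),
                                   fields[3])
            attrs = tuple(
                (name, None if value == NULL_TOKEN else value)
                for name, value in zip(attr_names, fields[4:])
            )
            records.append(BedRecord(region=region, attributes=attrs))
    return records


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _typed(kind: str, value: str | None):
    if value is None:
        return None
    if kind == "integer":
        return int(value)
    if kind == "float":
        return float(value)
    return value


def _untyped(kind: str, value) -> str | None:
    if value is None:
        return None
    if kind == "integer":
        return str(int(value))
    if kind == "float":
        return format_float(float(value))
    return str(value)


def write_json(records: Sequence[BedRecord], schema: DataTypeSchema, sink) -> None:
    """JSON array of objects keyed by schema field names.

    Integer/float attributes are written as JSON numbers and the null
    token as a JSON null, per the schema's value kinds.
    """
    check_schema_conformity(records, schema)
    payload = []
    for record in records:
        r = record.region
        obj = {
            "chrom": r.chrom,
            "chromStart": r.start,
            "chromEnd": r.end,
            "strand": r.strand,
        }
        for name, value in record.attributes:
            obj[name] = _typed(schema.kind_of(name), value)
        payload.append(obj)
    with _sink(sink) as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_json(source, schema: DataTypeSchema) -> list[BedRecord]:
    with _source(source) as fh:
        payload = json.load(fh)
    records: list[BedRecord] = []
    for obj in payload:
        region = GenomicRegion(obj["chrom"], int(obj["chromStart"]),
                               int(obj["chromEnd"]), obj["strand"])
        attrs = tuple(
            (name, _untyped(kind, obj.get(name)))
            for name, kind in schema.attribute_columns
        )
        records.append(BedRecord(region=region, attributes=attrs))
    return records


# ---------------------------------------------------------------------------
# XML
# ---------------------------------------------------------------------------

def write_xml(records: Sequence[BedRecord], schema: DataTypeSchema, sink) -> None:
    """One ``record`` element per record, one child element per field."""
    check_schema_conformity(records, schema)
    root = etree.Element("bedRecords", experimentType=schema.experiment_type)
    if schema.subtype:
        root.set("subtype", schema.subtype)
    for record in records:
        el = etree.SubElement(root, "record")
        for name, value in zip(schema.field_names, _text_fields(record)):
            child = etree.SubElement(el, name)
            child.text = value
    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    with _sink(sink) as fh:
        fh.write(text.decode("utf-8"))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

#: Feature-column token per (experiment type, subtype).
GTF_FEATURE_TOKENS: dict[tuple[str, str | None], str] = {
    ("cnv", None): "cnv_segment",
    ("dnamethylation", None): "methylation_site",
    ("dnaseq", None): "mutation",
    ("mirnaseq", None): "mirna",
    ("rnaseq", "gene"): "gene",
    ("rnaseq", "exon"): "exon",
    ("rnaseq", "spljxn"): "splice_junction",
    ("rnaseqv2", "gene"): "gene",
    ("rnaseqv2", "exon"): "exon",
    ("rnaseqv2", "spljxn"): "splice_junction",
    ("rnaseqv2", "isoform"): "isoform",
}

#: Value of the GTF ``source`` column.
GTF_SOURCE = "tcgabed"


def write_gtf(records: Sequence[BedRecord], schema: DataTypeSchema, sink) -> None:
    """Nine-column GTF; coordinates unchanged (GTF is natively one-based
    closed).  The unknown-strand placeholder ``*`` maps to GTF's ``.``;
    attribute-tail fields become ``key "value";`` pairs."""
    check_schema_conformity(records, schema)
    feature = GTF_FEATURE_TOKENS[schema.key]
    with _sink(sink) as fh:
        for record in records:
            r = record.region
            attrs = " ".join(
                f'{name} "{value if value is not None else NULL_TOKEN}";'
                for name, value in record.attributes
            )
            strand = "." if r.strand == "*" else r.strand
            fh.write("\t".join([
                r.chrom, GTF_SOURCE, feature, str(r.start), str(r.end),
                ".", strand, ".", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# header.schema
# ---------------------------------------------------------------------------

def _xsd() -> etree.XMLSchema:
    if not hasattr(_xsd, "_cache"):
        with resources.files("tcgabed").joinpath(
                "data/header_schema.xsd").open("rb") as fh:
            _xsd._cache = etree.XMLSchema(etree.parse(fh))
    return _xsd._cache


def _schema_tree(schema: DataTypeSchema) -> etree._Element:
    root = etree.Element("bedSchema", experimentType=schema.experiment_type)
    if schema.subtype:
        root.set("subtype", schema.subtype)
    for name, kind in schema.columns:
        etree.SubElement(root, "field", name=name, kind=kind)
    return root


def write_header_schema(schema: DataTypeSchema, sink) -> None:
    """Write the ``header.schema`` XML descriptor of a BED layout.

    One ``field`` element per column, in order, carrying the name and
    value kind; the document is validated against the shipped XML Schema
    before it is written.
    """
    root = _schema_tree(schema)
    _xsd().assertValid(root)
    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    with _sink(sink) as fh:
        fh.write(text.decode("utf-8"))


def read_header_schema(source) -> DataTypeSchema:
    """Parse and validate a ``header.schema`` document back into a schema."""
    with _source(source) as fh:
        text = fh.read()
    root = etree.fromstring(text.encode("utf-8"))
    xsd = _xsd()
    if not xsd.validate(root):
        raise SchemaError(f"invalid header.schema: {xsd.error_log.last_error}")
    columns = tuple(
        (el.get("name"), el.get("kind")) for el in root.iter("field")
    )
    return DataTypeSchema(
        experiment_type=root.get("experimentType"),
        subtype=root.get("subtype"),
        columns=columns,
    )


def render_bed(records: Sequence[BedRecord], schema: DataTypeSchema) -> str:
    """Convenience: free-BED serialization as a string."""
    buf = StringIO()
    write_bed(records, schema, buf)
    return buf.getvalue()
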