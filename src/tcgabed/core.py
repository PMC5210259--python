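"""Core domain model: TCGA barcodes, one-based closed genomic regions,
free-BED records and per-data-type column schemas.

The unit of analysis throughout the package is the *aliquot*, the physical
portion of a tumor/normal sample that one genomic experiment was run on.
Every aliquot carries a hierarchical TCGA barcode such as
``TCGA-02-0021-01A-01D-0002-04``; prefixes of the barcode identify the
patient (first three groups) and the sample (first four).

Coordinates follow the one-based, base-counted convention used by the TCGA
level-2/3 files themselves: the first base of a chromosome is position 1 and
a region is a closed interval, so the 3rd through 7th bases are ``[3, 7]``.
This deviates deliberately from the zero-based half-open convention of UCSC
BED; :func:`to_one_based_closed` converts between the two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import (
    ChromosomeError,
    EmptyIntervalError,
    MalformedBarcodeError,
    SchemaError,
)

__all__ = [
    "TcgaBarcode",
    "GenomicRegion",
    "BedRecord",
    "DataTypeSchema",
    "EXPERIMENT_TYPES",
    "MANDATORY_FIELDS",
    "NULL_TOKEN",
    "STRANDS",
    "UNKNOWN_STRAND",
    "parse_barcode",
    "render_barcode",
    "patient_id",
    "sample_id",
    "normalize_chrom",
    "karyotype_rank",
    "to_one_based_closed",
    "to_zero_based_half_open",
    "sort_key",
    "format_float",
    "format_value",
]

#: The six experiment types handled by the conversion engine, with the
#: directory names used by the output repository layout.
EXPERIMENT_TYPES = (
    "cnv",
    "dnamethylation",
    "dnaseq",
    "mirnaseq",
    "rnaseq",
    "rnaseqv2",
)

#: The four mandatory leading columns of every free-BED file, in order.
MANDATORY_FIELDS = ("chrom", "chromStart", "chromEnd", "strand")

#: Placeholder used when a feature's strand is unknown or not applicable.
#: "*" is chosen over "." to avoid colliding with GTF's empty-field dot.
UNKNOWN_STRAND = "*"

STRANDS = ("+", "-", UNKNOWN_STRAND)

#: Uniform serialization token for a missing attribute value.
NULL_TOKEN = "null"

_BARCODE_RE = re.compile(
    r"TCGA-(?P<tss>[A-Z0-9]{2})-(?P<participant>[A-Z0-9]{4})"
    r"-(?P<sample>\d{2})(?P<vial>[A-Z])"
    r"-(?P<portion>\d{2})(?P<analyte>[A-Z])"
    r"-(?P<plate>[A-Z0-9]{4})-(?P<center>\d{2})\Z"
)

_CHROM_RE = re.compile(r"chr(\d+|X|Y|M)\Z")


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class TcgaBarcode:
    """Structured form of an aliquot barcode.

    Fields mirror the dash-separated groups of the rendered barcode
    ``TCGA-<tss>-<participant>-<sample><vial>-<portion><analyte>-<plate>-<center>``.
    Validation is strict on structure (group lengths and character classes)
    but deliberately permissive on the actual tissue-source-site and center
    codes: no code registry is shipped.
    """

    tss: str
    participant: str
    sample: str
    vial: str
    portion: str
    analyte: str
    plate: str
    center: str

    def __post_init__(self) -> None:
        if _BARCODE_RE.fullmatch(self.render()) is None:
            raise MalformedBarcodeError(
                f"invalid barcode parts: {self!r}"
            )

    def render(self) -> str:
        return (
            f"TCGA-{self.tss}-{self.participant}"
            f"-{self.sample}{self.vial}"
            f"-{self.portion}{self.analyte}"
            f"-{self.plate}-{self.center}"
        )

    def __str__(self) -> str:  # pragma: no cover - trivial alias
        return self.render()

    @property
    def patient_id(self) -> str:
        """``TCGA-<tss>-<participant>`` — identifies the patient."""
        return f"TCGA-{self.tss}-{self.participant}"

    @property
    def sample_id(self) -> str:
        """``TCGA-<tss>-<participant>-<sample><vial>`` — identifies the sample."""
        return f"{self.patient_id}-{self.sample}{self.vial}"


def parse_barcode(text: str) -> TcgaBarcode:
    """Parse a rendered aliquot barcode into its seven-part decomposition.

    >>> parse_barcode("TCGA-02-0021-01A-01D-0002-04").patient_id
    'TCGA-02-0021'

    Raises :class:`MalformedBarcodeError` when the group count, group
    lengths or character classes do not match the barcode grammar.
    """
    if not text:
        raise MalformedBarcodeError("empty barcode")
    m = _BARCODE_RE.fullmatch(text)
    if m is None:
        raise MalformedBarcodeError(f"not a valid aliquot barcode: {text!r}")
    return TcgaBarcode(**m.groupdict())


def render_barcode(barcode: TcgaBarcode) -> str:
    return barcode.render()


def patient_id(barcode: TcgaBarcode) -> str:
    return barcode.patient_id


def sample_id(barcode: TcgaBarcode) -> str:
    return barcode.sample_id


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def normalize_chrom(token: str) -> str:
    """Normalize a chromosome token to the ``chr``-prefixed convention.

    TCGA platforms mix naming conventions; ``"17"``, ``"chr17"`` and
    ``"MT"`` are all accepted and map to ``chr17``/``chr17``/``chrM``.
    The mitochondrion is always rendered ``chrM``.
    """
    raw = token.strip()
    body = raw[3:] if raw[:3].lower() == "chr" else raw
    body = body.upper()
    if body == "MT":
        body = "M"
    if body.isdigit():
        body = str(int(body))  # drop leading zeros: "07" -> "7"
    chrom = f"chr{body}"
    if _CHROM_RE.fullmatch(chrom) is None:
        raise ChromosomeError(f"unrecognized chromosome token: {token!r}")
    return chrom


def karyotype_rank(chrom: str) -> int:
    """Rank of a chromosome in karyotype order chr1..chr22, chrX, chrY, chrM."""
    body = chrom[3:]
    if body == "X":
        return 23
    if body == "Y":
        return 24
    if body == "M":
        return 25
    return int(body)


def to_one_based_closed(start0: int, end0: int) -> tuple[int, int]:
    """Map a zero-based half-open interval to one-based closed coordinates.

    The image of ``[start0, end0)`` is ``[start0 + 1, end0]``; the region
    covering the 3rd through 7th bases, ``(2, 7)`` in zero-based half-open
    form, becomes ``(3, 7)``.  Length ``end0 - start0`` is preserved.

    Raises :class:`EmptyIntervalError` when ``start0 >= end0`` (an empty
    interval has no closed image).
    """
    if start0 < 0:
        raise ValueError(f"negative start: {start0}")
    if start0 >= end0:
        raise EmptyIntervalError(
            f"empty zero-based interval [{start0}, {end0})"
        )
    return start0 + 1, end0


def to_zero_based_half_open(start1: int, end1: int) -> tuple[int, int]:
    """Inverse of :func:`to_one_based_closed`."""
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid one-based closed interval [{start1}, {end1}]")
    return start1 - 1, end1


@dataclass(frozen=True, slots=True)
class GenomicRegion:
    """A one-based closed genomic interval with a strand.

    ``strand`` is ``+``/``-`` or ``*`` when unknown or not applicable
    (e.g. copy-number segments carry no strand).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN_STRAND

    def __post_init__(self) -> None:
        if _CHROM_RE.fullmatch(self.chrom) is None:
            raise ChromosomeError(f"chromosome not normalized: {self.chrom!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid one-based closed region {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# schemas and records
# ---------------------------------------------------------------------------

#: Value kinds a schema column may declare.
VALUE_KINDS = ("string", "integer", "float", "char")


@dataclass(frozen=True)
class DataTypeSchema:
    """Ordered column definition for one (experiment type, subtype) pair.

    The first four columns are always the mandatory free-BED fields
    ``chrom``, ``chromStart``, ``chromEnd``, ``strand``; the remaining
    columns are the data-type-specific attribute tail, unlimited in number.
    This object is the single source of the ``header.schema`` side file.
    """

    experiment_type: str
    subtype: str | None
    columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.experiment_type not in EXPERIMENT_TYPES:
            raise SchemaError(f"unknown experiment type: {self.experiment_type!r}")
        names = [name for name, _ in self.columns]
        if tuple(names[:4]) != MANDATORY_FIELDS:
            raise SchemaError(
                f"first four columns must be {MANDATORY_FIELDS}, got {names[:4]}"
            )
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate column names in schema: {names}")
        for name, kind in self.columns:
            if kind not in VALUE_KINDS:
                raise SchemaError(f"unknown value kind {kind!r} for column {name!r}")

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.columns)

    @property
    def attribute_columns(self) -> tuple[tuple[str, str], ...]:
        """Columns after the four mandatory fields, in order."""
        return self.columns[4:]

    @property
    def key(self) -> tuple[str, str | None]:
        return (self.experiment_type, self.subtype)

    def kind_of(self, name: str) -> str:
        for col, kind in self.columns:
            if col == name:
                return kind
        raise KeyError(name)


@dataclass(frozen=True)
class BedRecord:
    """One genomic feature: a region plus the ordered attribute tail.

    ``attributes`` holds ``(name, value-text)`` pairs in schema order;
    a ``None`` value is the in-memory form of the serialization null
    token.  Attribute names and order must equal the record's schema
    minus the four mandatory fields — enforced by :meth:`conforms_to`.
    """

    region: GenomicRegion
    attributes: tuple[tuple[str, str | None], ...] = ()

    def conforms_to(self, schema: DataTypeSchema) -> bool:
        return tuple(name for name, _ in self.attributes) == tuple(
            name for name, _ in schema.attribute_columns
        )

    def attribute(self, name: str) -> str | None:
        for key, value in self.attributes:
            if key == name:
                return value
        raise KeyError(name)


def sort_key(record: BedRecord):
    """Total ordering for deterministic, diffable output.

    Chromosomes sort in karyotype order (chr1..chr22, chrX, chrY, chrM)
    rather than lexicographically, then by start, end, strand and the
    attribute values.
    """
    r = record.region
    attr_values = tuple(v if v is not None else "" for _, v in record.attributes)
    return (karyotype_rank(r.chrom), r.start, r.end, r.strand, attr_values)


# ---------------------------------------------------------------------------
# value formatting
# ---------------------------------------------------------------------------

def format_float(value: float) -> str:
    """Locale-independent float rendering: up to 6 significant digits,
    positional notation down to 1e-4, scientific below.  Idempotent under
    parse/format round trips, which keeps serialized output byte-stable."""
    text = f"{value:.6g}"
    # "%.6g" never emits a locale decimal separator, so nothing to fix up.
    return text


_NULL_INPUTS = frozenset({"", "na", "n/a", "null", "none", "nan"})


def format_value(kind: str, raw: str | None) -> str | None:
    """Canonicalize a raw input token according to its schema value kind.

    Empty strings and the usual missing-data spellings (``NA``, ``null``,
    ``NaN`` …) all canonicalize to ``None``, serialized later as the
    uniform null token.  Raises ``ValueError`` when a non-null token does
    not parse under the declared kind.
    """
    if raw is None:
        return None
    text = raw.strip()
    if text.lower() in _NULL_INPUTS:
        return None
    if kind == "integer":
        return str(int(text))
    if kind == "float":
        return format_float(float(text))
    if kind == "char":
        if len(text) != 1:
            raise ValueError(f"expected single character, got {text!r}")
        return text
    return text


def records_sorted(records: Iterable[BedRecord]) -> list[BedRecord]:
    return sorted(records, key=sort_key)


def check_schema_conformity(records: Sequence[BedRecord], schema: DataTypeSchema) -> None:
    for rec in records:
        if not rec.conforms_to(schema):
            raise SchemaError(
                f"record attributes {[n for n, _ in rec.attributes]} do not match "
                f"schema {schema.experiment_type}/{schema.subtype}"
            )
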