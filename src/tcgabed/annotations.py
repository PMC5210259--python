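"""Gene/miRNA annotation lookups used to enrich converted records.

Four local lookup tables stand in for the remote services a converter
would otherwise have to query row by row (NCBI Entrez Gene for gene
coordinates, HGNC for symbol→Entrez, the UCSC Genome Browser for
transcript→Entrez, miRBase for miRNA loci).  Conversion-time enrichment
composes them into chains:

* gene quantifications:  Entrez id → coordinates + strand
* methylation:           gene symbol → Entrez id → strand
* isoform quantifications: UCSC transcript id → Entrez id → coordinates
* miRNA quantifications: miRNA id → one or more loci

A failed link never raises: lookups return an :class:`AnnotationMiss`
value naming the identifier and the chain stage that failed, so
converters can count and report misses instead of silently dropping
information.  The whole store round-trips through a single cache file so
a table set only has to be assembled once.

The store is genome-assembly-agnostic: it serves whatever coordinates the
tables were built from, and the table provenance must declare the build.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

from .core import GenomicRegion, normalize_chrom
from .errors import TableFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationStore",
    "AnnotationMiss",
    "coords_by_entrez",
    "strand_by_symbol",
    "entrez_by_ucsc",
    "coords_by_ucsc",
    "coords_by_mirna",
    "load_store",
    "save_store",
    "load_cache",
]


@dataclass(frozen=True)
class AnnotationMiss:
    """A lookup that could not be resolved.

    ``id_kind`` names the identifier namespace (entrez/symbol/ucsc/mirna),
    ``stage`` the table at which the chain broke.  Misses are values, not
    exceptions: they travel in conversion reports and are never silently
    discarded.
    """

    id_kind: str
    id_value: str
    stage: str


LookupResult = Union[GenomicRegion, AnnotationMiss]


@dataclass
class AnnotationStore:
    """The four lookup tables and their composition chains.

    Gene symbols are case-preserving; miRNA identifiers are
    case-insensitive (miRBase ids are lowercase ``hsa-...``) and stored
    lower-cased.  Each Entrez id maps to exactly one region (the table
    builder pre-selects the primary-assembly placement); only miRNAs may
    map to multiple loci.
    """

    entrez_coords: dict[int, GenomicRegion] = field(default_factory=dict)
    symbol_to_entrez: dict[str, int] = field(default_factory=dict)
    ucsc_to_entrez: dict[str, int] = field(default_factory=dict)
    mirna_coords: dict[str, list[GenomicRegion]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# lookups (pure reads: no lookup mutates the store)
# ---------------------------------------------------------------------------

def coords_by_entrez(store: AnnotationStore, gene_id: int | str) -> LookupResult:
    """Genomic coordinates (chromosome, start, end, strand) for an Entrez
    Gene id, or a miss when the id is absent from the table."""
    try:
        key = int(gene_id)
    except (TypeError, ValueError):
        return AnnotationMiss("entrez", str(gene_id), "entrez_coords")
    region = store.entrez_coords.get(key)
    if region is None:
        return AnnotationMiss("entrez", str(gene_id), "entrez_coords")
    return region


def strand_by_symbol(store: AnnotationStore, symbol: str) -> str | AnnotationMiss:
    """DNA strand of the gene named by an HGNC symbol.

    Two-step chain: symbol → Entrez id (HGNC table), then Entrez id →
    coordinates (gene table), of which only the strand is returned.  The
    miss records which link failed.
    """
    entrez = store.symbol_to_entrez.get(symbol)
    if entrez is None:
        return AnnotationMiss("symbol", symbol, "symbol_to_entrez")
    region = store.entrez_coords.get(entrez)
    if region is None:
        return AnnotationMiss("symbol", symbol, "entrez_coords")
    return region.strand


def entrez_by_ucsc(store: AnnotationStore, transcript_id: str) -> int | AnnotationMiss:
    """Entrez Gene id of a UCSC transcript (isoform) id.

    TCGA isoform files and UCSC tables disagree on id versions, so a
    versioned id like ``uc001aaa.3`` falls back to the unversioned
    ``uc001aaa`` when the exact key is absent.
    """
    entrez = store.ucsc_to_entrez.get(transcript_id)
    if entrez is None and "." in transcript_id:
        entrez = store.ucsc_to_entrez.get(transcript_id.rsplit(".", 1)[0])
    if entrez is None:
        return AnnotationMiss("ucsc", transcript_id, "ucsc_to_entrez")
    return entrez


def coords_by_ucsc(store: AnnotationStore, transcript_id: str) -> LookupResult:
    """Genomic coordinates for a UCSC transcript (isoform) id via its gene.

    Chain: transcript id → Entrez id (UCSC table) → coordinates (gene
    table).  The miss records which link failed.
    """
    entrez = entrez_by_ucsc(store, transcript_id)
    if isinstance(entrez, AnnotationMiss):
        return entrez
    region = store.entrez_coords.get(entrez)
    if region is None:
        return AnnotationMiss("ucsc", transcript_id, "entrez_coords")
    return region


def coords_by_mirna(
    store: AnnotationStore, mirna_id: str
) -> list[GenomicRegion] | AnnotationMiss:
    """All genomic loci of a miRNA id (a miRNA may map to several), in
    store order; case-insensitive on the id."""
    loci = store.mirna_coords.get(mirna_id.lower())
    if not loci:
        return AnnotationMiss("mirna", mirna_id, "mirna_coords")
    return list(loci)


# ---------------------------------------------------------------------------
# table loading
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = {
    "entrez_coords": ("entrez_id", "chrom", "start", "end", "strand"),
    "symbol_to_entrez": ("symbol", "entrez_id"),
    "ucsc_to_entrez": ("ucsc_id", "entrez_id"),
    "mirna_coords": ("mirna_id", "chrom", "start", "end", "strand"),
}


def _read_table(path: Path, table: str):
    """Yield (lineno, field-list) for a tab-delimited table with a header.

    Raises :class:`TableFormatError` naming file and line on a wrong
    column count or a header that does not match the declared layout.
    """
    expected = _TABLE_COLUMNS[table]
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return  # empty file == empty table
        if tuple(h.strip() for h in header) != expected:
            raise TableFormatError(
                f"expected header {list(expected)}, got {header}",
                path=str(path), line=1,
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(expected):
                raise TableFormatError(
                    f"expected {len(expected)} columns, got {len(row)}",
                    path=str(path), line=lineno,
                )
            yield lineno, [f.strip() for f in row]


def _region(fields: list[str], path: Path, lineno: int) -> GenomicRegion:
    # fields = [chrom, start, end, strand] already stripped
    try:
        return GenomicRegion(
            chrom=normalize_chrom(fields[0]),
            start=int(fields[1]),
            end=int(fields[2]),
            strand=fields[3],
        )
    except ValueError as exc:
        raise TableFormatError(str(exc), path=str(path), line=lineno) from exc


def load_store(paths: Mapping[str, str | Path]) -> AnnotationStore:
    """Load the four lookup tables into a store.

    ``paths`` maps table names (``entrez_coords``, ``symbol_to_entrez``,
    ``ucsc_to_entrez``, ``mirna_coords``) to tab-delimited files; a
    missing entry leaves that table empty.  Duplicate keys: the last
    occurrence wins, with a logged warning (miRNA tables are the
    exception — repeated ids accumulate loci).
    """
    store = AnnotationStore()
    for table in _TABLE_COLUMNS:
        if table not in paths:
            continue
        path = Path(paths[table])
        for lineno, fields in _read_table(path, table):
            if table == "entrez_coords":
                try:
                    key = int(fields[0])
                except ValueError as exc:
                    raise TableFormatError(
                        f"bad entrez id {fields[0]!r}", path=str(path), line=lineno
                    ) from exc
                if key in store.entrez_coords:
                    logger.warning(
                        "%s line %d: duplicate entrez id %s, keeping last",
                        path, lineno, key,
                    )
                store.entrez_coords[key] = _region(fields[1:], path, lineno)
            elif table == "symbol_to_entrez":
                symbol = fields[0]
                if symbol in store.symbol_to_entrez:
                    logger.warning(
                        "%s line %d: duplicate symbol %s, keeping last",
                        path, lineno, symbol,
                    )
                store.symbol_to_entrez[symbol] = _int_field(fields[1], path, lineno)
            elif table == "ucsc_to_entrez":
                ucsc = fields[0]
                if ucsc in store.ucsc_to_entrez:
                    logger.warning(
                        "%s line %d: duplicate transcript id %s, keeping last",
                        path, lineno, ucsc,
                    )
                store.ucsc_to_entrez[ucsc] = _int_field(fields[1], path, lineno)
            else:  # mirna_coords: repeatable key, loci accumulate in file order
                store.mirna_coords.setdefault(fields[0].lower(), []).append(
                    _region(fields[1:], path, lineno)
                )
    return store


def _int_field(text: str, path: Path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise TableFormatError(
            f"bad entrez id {text!r}", path=str(path), line=lineno
        ) from exc


# ---------------------------------------------------------------------------
# cache (single-file persistence)
# ---------------------------------------------------------------------------

def save_store(store: AnnotationStore, path: str | Path) -> None:
    """Persist the whole store to one tab-delimited cache file.

    Each line starts with the table name; rows are written in sorted key
    order (miRNA loci keep their in-store order) so the file is
    byte-stable and reloads bit-exactly.
    """
    path = Path(path)
    lines: list[str] = []
    for key in sorted(store.entrez_coords):
        r = store.entrez_coords[key]
        lines.append(f"entrez_coords\t{key}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}")
    for symbol in sorted(store.symbol_to_entrez):
        lines.append(f"symbol_to_entrez\t{symbol}\t{store.symbol_to_entrez[symbol]}")
    for ucsc in sorted(store.ucsc_to_entrez):
        lines.append(f"ucsc_to_entrez\t{ucsc}\t{store.ucsc_to_entrez[ucsc]}")
    for mirna in sorted(store.mirna_coords):
        for r in store.mirna_coords[mirna]:
            lines.append(
                f"mirna_coords\t{mirna}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}"
            )
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def load_cache(path: str | Path) -> AnnotationStore:
    """Reload a store persisted by :func:`save_store`."""
    path = Path(path)
    store = AnnotationStore()
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            table = fields[0]
            body = fields[1:]
            expected = _TABLE_COLUMNS.get(table)
            if expected is None:
                raise TableFormatError(
                    f"unknown table name {table!r}", path=str(path), line=lineno
                )
            if len(body) != len(expected):
                raise TableFormatError(
                    f"expected {len(expected)} fields after table name, got {len(body)}",
                    path=str(path), line=lineno,
                )
            if table == "entrez_coords":
                store.entrez_coords[_int_field(body[0], path, lineno)] = _region(
                    body[1:], path, lineno
                )
            elif table == "symbol_to_entrez":
                store.symbol_to_entrez[body[0]] = _int_field(body[1], path, lineno)
            elif table == "ucsc_to_entrez":
                store.ucsc_to_entrez[body[0]] = _int_field(body[1], path, lineno)
            else:
                store.mirna_coords.setdefault(body[0].lower(), []).append(
                    _region(body[1:], path, lineno)
                )
    return store
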