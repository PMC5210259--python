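"""Flattening of clinical/biospecimen documents into per-aliquot .meta files.

TCGA distributes clinical information per patient and biospecimen
information per sample/aliquot, both as hierarchical XML.  The output
repository is aliquot-oriented, so both documents are flattened to
``key<TAB>value`` pairs and denormalized into one ``.meta`` file per
aliquot: the clinical pairs of a patient are copied into the .meta of
every aliquot of that patient.

Key naming: element names are lowercased, path segments from the root
(root excluded) are joined with ``__``; repeated siblings get a 1-based
``__k`` suffix.  Clinical and biospecimen pairs are prefixed
``clinical__``/``biospecimen__`` so identically named fields cannot
collide, and three ``manually_curated__`` provenance keys record the
tumor tag, the experiment data type and the full aliquot barcode.

Alongside the .meta files, each (tumor, data type) directory gets a
``metadata_dictionary.txt`` listing every attribute with all the distinct
values it assumes across that directory's .meta files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .core import TcgaBarcode
from .errors import DocumentParseError, LinkageError

__all__ = [
    "MetaRecord",
    "MetadataDictionary",
    "flatten_document",
    "assemble_meta",
    "build_dictionary",
    "render_meta",
    "parse_meta",
    "write_meta",
    "render_dictionary",
    "write_dictionary",
    "PROVENANCE_TUMOR_TAG",
    "PROVENANCE_DATA_TYPE",
    "PROVENANCE_ALIQUOT",
]

PROVENANCE_TUMOR_TAG = "manually_curated__tumor_tag"
PROVENANCE_DATA_TYPE = "manually_curated__exp_data_type"
PROVENANCE_ALIQUOT = "manually_curated__tcga_aliquot_barcode"


@dataclass(frozen=True)
class MetaRecord:
    """Per-aliquot flat metadata: the aliquot and its sorted (key, value) pairs."""

    aliquot: TcgaBarcode
    pairs: tuple[tuple[str, str], ...]

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)


@dataclass
class MetadataDictionary:
    """Map attribute-key → set of distinct values observed across records."""

    entries: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# document flattening
# ---------------------------------------------------------------------------

def flatten_document(doc) -> list[tuple[str, str]]:
    """Flatten a clinical or biospecimen XML document to (key, value) pairs.

    ``doc`` may be a path or an already-parsed element.  One pair is
    emitted per non-empty leaf element; empty leaves emit nothing.  The
    result order follows document order, but keys are position-independent
    (sibling repetition is encoded in the ``__k`` suffix, not in order).
    """
    if isinstance(doc, (str, Path)):
        try:
            root = etree.parse(str(doc)).getroot()
        except (etree.XMLSyntaxError, OSError) as exc:
            raise DocumentParseError(f"{doc}: {exc}") from exc
    elif isinstance(doc, bytes):
        try:
            root = etree.fromstring(doc)
        except etree.XMLSyntaxError as exc:
            raise DocumentParseError(str(exc)) from exc
    else:
        root = doc
    pairs: list[tuple[str, str]] = []
    _walk(root, (), pairs)
    return pairs


def _walk(elem, prefix: tuple[str, ...], out: list[tuple[str, str]]) -> None:
    children = [c for c in elem if isinstance(c.tag, str)]
    tag_totals: dict[str, int] = {}
    for child in children:
        tag_totals[child.tag] = tag_totals.get(child.tag, 0) + 1
    seen: dict[str, int] = {}
    for child in children:
        tag = child.tag
        seen[tag] = seen.get(tag, 0) + 1
        segment = tag.lower()
        if tag_totals[tag] > 1:
            segment = f"{segment}__{seen[tag]}"
        path = prefix + (segment,)
        if any(isinstance(c.tag, str) for c in child):
            _walk(child, path, out)
        else:
            text = (child.text or "").strip()
            if text:
                out.append(("__".join(path), text))


# ---------------------------------------------------------------------------
# per-aliquot assembly
# ---------------------------------------------------------------------------

def assemble_meta(aliquot: TcgaBarcode,
                  clinical_pairs: Sequence[tuple[str, str]],
                  biospecimen_pairs: Sequence[tuple[str, str]],
                  provenance: Mapping[str, str]) -> MetaRecord:
    """Assemble the flat metadata record of one aliquot.

    ``provenance`` must provide ``tumor_tag`` and ``exp_data_type``; the
    aliquot barcode provenance key is derived from ``aliquot`` itself.
    Linkage is verified from the documents' own barcode fields when
    present: a clinical document whose ``bcr_patient_barcode`` does not
    prefix the aliquot, or a biospecimen entry for a different aliquot,
    raises :class:`LinkageError`.
    """
    _check_linkage(aliquot, clinical_pairs, "bcr_patient_barcode",
                   aliquot.patient_id, "clinical")
    _check_linkage(aliquot, biospecimen_pairs, "bcr_aliquot_barcode",
                   aliquot.render(), "biospecimen")

    merged: dict[str, str] = {}
    for key, value in clinical_pairs:
        _put(merged, f"clinical__{key}", value)
    for key, value in biospecimen_pairs:
        _put(merged, f"biospecimen__{key}", value)
    _put(merged, PROVENANCE_TUMOR_TAG, provenance["tumor_tag"])
    _put(merged, PROVENANCE_DATA_TYPE, provenance["exp_data_type"])
    _put(merged, PROVENANCE_ALIQUOT, aliquot.render())
    return MetaRecord(aliquot=aliquot, pairs=tuple(sorted(merged.items())))


def _put(mapping: dict[str, str], key: str, value: str) -> None:
    if key in mapping:
        raise LinkageError(f"duplicate metadata key {key!r}")
    mapping[key] = value


def _check_linkage(aliquot: TcgaBarcode, pairs: Sequence[tuple[str, str]],
                   barcode_key: str, expected: str, kind: str) -> None:
    for key, value in pairs:
        if key == barcode_key or key.endswith(f"__{barcode_key}"):
            if value != expected:
                raise LinkageError(
                    f"{kind} document for {value!r} attached to aliquot "
                    f"{aliquot.render()!r} (expected {expected!r})"
                )


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

def build_dictionary(records: Iterable[MetaRecord]) -> MetadataDictionary:
    """Collect every attribute with all the distinct values it assumes."""
    d = MetadataDictionary()
    for record in records:
        for key, value in record.pairs:
            d.entries.setdefault(key, set()).add(value)
    return d


# ---------------------------------------------------------------------------
# serialization — bit-exact contracts
# ---------------------------------------------------------------------------

def render_meta(record: MetaRecord) -> str:
    """``key<TAB>value<NEWLINE>`` lines, sorted by key, UTF-8."""
    return "".join(f"{k}\t{v}\n" for k, v in sorted(record.pairs))


def write_meta(record: MetaRecord, path: str | Path) -> None:
    Path(path).write_text(render_meta(record), encoding="utf-8")


def parse_meta(text: str, aliquot: TcgaBarcode) -> MetaRecord:
    pairs = []
    for line in text.splitlines():
        if not line:
            continue
        key, _, value = line.partition("\t")
        pairs.append((key, value))
    return MetaRecord(aliquot=aliquot, pairs=tuple(pairs))


def render_dictionary(dictionary: MetadataDictionary) -> str:
    """``key<TAB>v1<TAB>v2...`` lines, keys and values lexicographically sorted."""
    lines = []
    for key in sorted(dictionary.entries):
        values = "\t".join(sorted(dictionary.entries[key]))
        lines.append(f"{key}\t{values}\n")
    return "".join(lines)


def write_dictionary(dictionary: MetadataDictionary, path: str | Path) -> None:
    Path(path).write_text(render_dictionary(dictionary), encoding="utf-8")
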