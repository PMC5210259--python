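"""Source→convert→layout orchestration producing the *bed* repository tree.

A run is a list of jobs; each job names a source tree (the local
``tcga_original`` directory of one cohort), a tumor tag, an experiment
type, the output formats and the annotation tables.  For every aliquot
file found, the matching converter runs and the records are written as
``<aliquot-barcode>.<ext>`` next to a ``<aliquot-barcode>.bed.meta``
companion assembled from the patient's clinical document and the
aliquot's biospecimen document.  Each output directory then receives one
``header.schema`` and one ``metadata_dictionary.txt``.

Layout: ``bed/<tumor-tag-lowercase>/<type>/`` with type in cnv,
dnamethylation, dnaseq, mirnaseq, rnaseq, rnaseqv2; the multi-subtype
RNA-seq types add one subdirectory per subtype (gene/exon/spljxn/
isoform), since a directory holds exactly one schema.

Everything written is deterministic: re-running an unchanged job over
unchanged inputs rewrites byte-identical files.  The original download
path is abstracted behind this local source-directory layout; no network
is touched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from lxml import etree

from . import serializers
from .annotations import AnnotationStore, load_cache, load_store
from .converters import ConversionReport, get_converter, read_source_file
from .core import EXPERIMENT_TYPES, TcgaBarcode, parse_barcode
from .errors import ConfigError, TcgaBedError
from .metadata import (
    assemble_meta,
    build_dictionary,
    flatten_document,
    write_dictionary,
    write_meta,
)
from .schemas import SUBTYPES, get_schema

logger = logging.getLogger(__name__)

__all__ = ["Job", "JobReport", "RunReport", "run_convert", "file_name",
           "parse_config", "FORMATS", "load_annotations"]

FORMATS = ("bed", "csv", "gtf", "json", "xml")

_WRITERS = {
    "bed": serializers.write_bed,
    "csv": serializers.write_csv,
    "gtf": serializers.write_gtf,
    "json": serializers.write_json,
    "xml": serializers.write_xml,
}


def file_name(aliquot: TcgaBarcode | str, fmt: str) -> str:
    """Output file name for one aliquot: ``<full-barcode>.<ext>``.

    The metadata companion is format-independent and attached to the
    canonical BED name: ``fmt="meta"`` yields ``<barcode>.bed.meta``.
    """
    barcode = aliquot.render() if isinstance(aliquot, TcgaBarcode) else aliquot
    if fmt == "meta":
        return f"{barcode}.bed.meta"
    if fmt not in FORMATS:
        raise ConfigError(f"unknown output format {fmt!r}")
    return f"{barcode}.{fmt}"


@dataclass(frozen=True)
class Job:
    """One conversion work item."""

    source: Path
    tumor: str
    exp_type: str
    annotations: Path
    out_root: Path
    formats: tuple[str, ...] = ("bed",)

    def validate(self) -> None:
        if self.exp_type not in EXPERIMENT_TYPES:
            raise ConfigError(f"unknown experiment type {self.exp_type!r}")
        bad = [f for f in self.formats if f not in FORMATS]
        if bad:
            raise ConfigError(f"unknown output format(s) {bad}")
        if not self.formats:
            raise ConfigError("job lists no output formats")


@dataclass
class JobReport:
    job: Job
    ok: bool = True
    error: str | None = None
    files_written: list[str] = dc_field(default_factory=list)
    conversions: dict[str, ConversionReport] = dc_field(default_factory=dict)

    @property
    def totals(self) -> ConversionReport:
        total = ConversionReport()
        for report in self.conversions.values():
            total.merge(report)
        return total


@dataclass
class RunReport:
    jobs: list[JobReport] = dc_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(j.ok for j in self.jobs)

    @property
    def totals(self) -> ConversionReport:
        total = ConversionReport()
        for job in self.jobs:
            total.merge(job.totals)
        return total

    def to_dict(self) -> dict:
        out = {"ok": self.ok, "jobs": []}
        for jr in self.jobs:
            t = jr.totals
            out["jobs"].append({
                "tumor": jr.job.tumor,
                "type": jr.job.exp_type,
                "ok": jr.ok,
                "error": jr.error,
                "files_written": sorted(jr.files_written),
                "rows_in": t.rows_in,
                "records_out": t.records_out,
                "dropped": t.dropped,
                "annotation_misses": len(t.misses),
            })
        t = self.totals
        out["totals"] = {
            "rows_in": t.rows_in,
            "records_out": t.records_out,
            "dropped": t.dropped,
            "annotation_misses": len(t.misses),
        }
        return out

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def load_annotations(path: str | Path) -> AnnotationStore:
    """Load annotation tables from a directory of the four conventional
    table files, or from a single saved cache file."""
    path = Path(path)
    if path.is_dir():
        return load_store({
            "entrez_coords": path / "entrez_coords.tsv",
            "symbol_to_entrez": path / "symbol_to_entrez.tsv",
            "ucsc_to_entrez": path / "ucsc_to_entrez.tsv",
            "mirna_coords": path / "mirna_coords.tsv",
        })
    return load_cache(path)


# ---------------------------------------------------------------------------
# job execution
# ---------------------------------------------------------------------------

def _discover(src_dir: Path, exp_type: str) -> dict[str | None, list[tuple[str, Path]]]:
    """Map subtype → [(aliquot barcode, file path)] for one type directory."""
    by_subtype: dict[str | None, list[tuple[str, Path]]] = {}
    subtypes = SUBTYPES[exp_type]
    for path in sorted(src_dir.glob("*.txt")):
        stem = path.name[:-len(".txt")]
        if subtypes == (None,):
            barcode, subtype = stem, None
        else:
            barcode, _, subtype = stem.rpartition(".")
            if subtype not in subtypes:
                logger.warning("%s: unrecognized subtype %r, skipped", path, subtype)
                continue
        parse_barcode(barcode)  # raises on a foreign file name
        by_subtype.setdefault(subtype, []).append((barcode, path))
    return by_subtype


def _run_job(job: Job, store: AnnotationStore, report: JobReport) -> None:
    tumor_dir = job.source / job.tumor.lower()
    src_dir = tumor_dir / job.exp_type
    meta_dir = tumor_dir / "meta"
    if not src_dir.is_dir():
        raise ConfigError(f"source directory not found: {src_dir}")
    discovered = _discover(src_dir, job.exp_type)
    for subtype in SUBTYPES[job.exp_type]:
        files = discovered.get(subtype, [])
        schema = get_schema(job.exp_type, subtype)
        converter = get_converter(job.exp_type, subtype)
        out_dir = job.out_root / "bed" / job.tumor.lower() / job.exp_type
        if subtype is not None:
            out_dir = out_dir / subtype
        out_dir.mkdir(parents=True, exist_ok=True)
        data_type = job.exp_type if subtype is None else f"{job.exp_type}_{subtype}"
        meta_records = []
        for barcode, path in files:
            rows = read_source_file(path)
            records, conv = converter(rows, store, source=str(path))
            report.conversions[str(path)] = conv
            for fmt in job.formats:
                out_path = out_dir / file_name(barcode, fmt)
                _WRITERS[fmt](records, schema, out_path)
                report.files_written.append(str(out_path))
            meta_record = _assemble_aliquot_meta(
                meta_dir, barcode, job.tumor, data_type)
            meta_path = out_dir / file_name(barcode, "meta")
            write_meta(meta_record, meta_path)
            report.files_written.append(str(meta_path))
            meta_records.append(meta_record)
            logger.info("%s/%s %s: %d rows -> %d records (%d dropped, "
                        "%d misses)", job.tumor.lower(), data_type, barcode,
                        conv.rows_in, conv.records_out, conv.dropped,
                        len(conv.misses))
        serializers.write_header_schema(schema, out_dir / "header.schema")
        report.files_written.append(str(out_dir / "header.schema"))
        write_dictionary(build_dictionary(meta_records),
                         out_dir / "metadata_dictionary.txt")
        report.files_written.append(str(out_dir / "metadata_dictionary.txt"))


def _assemble_aliquot_meta(meta_dir: Path, barcode: str, tumor: str,
                           data_type: str):
    aliquot = parse_barcode(barcode)
    clinical_path = meta_dir / f"{aliquot.patient_id}.clinical.xml"
    biospecimen_path = meta_dir / f"{barcode}.biospecimen.xml"
    clinical = flatten_document(clinical_path) if clinical_path.exists() else []
    biospecimen = (flatten_document(biospecimen_path)
                   if biospecimen_path.exists() else [])
    return assemble_meta(aliquot, clinical, biospecimen, {
        "tumor_tag": tumor.lower(),
        "exp_data_type": data_type,
    })


def run_convert(jobs: list[Job]) -> RunReport:
    """Execute a job list; config validation happens before any work.

    Per-job failures are logged and recorded in the run report rather
    than aborting the run; the report's ``ok`` is True iff no job failed.
    """
    for job in jobs:
        job.validate()
    report = RunReport()
    stores: dict[Path, AnnotationStore] = {}
    for job in jobs:
        jr = JobReport(job=job)
        report.jobs.append(jr)
        try:
            key = Path(job.annotations)
            if key not in stores:
                stores[key] = load_annotations(key)
            _run_job(job, stores[key], jr)
        except TcgaBedError as exc:
            jr.ok = False
            jr.error = str(exc)
            logger.error("job %s/%s failed: %s", job.tumor, job.exp_type, exc)
    return report


# ---------------------------------------------------------------------------
# XML job configuration
# ---------------------------------------------------------------------------

_JOB_FIELDS = ("source", "tumor", "type", "annotations", "out", "formats")


def parse_config(path: str | Path) -> list[Job]:
    """Parse an XML configuration file into a job list.

    Dialect: one ``<job>`` element per run item under a ``<jobs>`` root,
    with child elements source/tumor/type/annotations/out and an optional
    comma-separated ``formats`` (default ``bed``).
    """
    try:
        root = etree.parse(str(path)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ConfigError(f"cannot read configuration {path}: {exc}") from exc
    if root.tag != "jobs":
        raise ConfigError(f"expected <jobs> root element, got <{root.tag}>")
    jobs: list[Job] = []
    for el in root.iter("job"):
        values = {}
        for child in el:
            if isinstance(child.tag, str):
                if child.tag not in _JOB_FIELDS:
                    raise ConfigError(f"unknown job element <{child.tag}>")
                values[child.tag] = (child.text or "").strip()
        missing = [f for f in ("source", "tumor", "type", "annotations", "out")
                   if not values.get(f)]
        if missing:
            raise ConfigError(f"job is missing element(s): {missing}")
        formats = tuple(
            f.strip() for f in values.get("formats", "bed").split(",")
            if f.strip()
        )
        jobs.append(Job(
            source=Path(values["source"]),
            tumor=values["tumor"],
            exp_type=values["type"],
            annotations=Path(values["annotations"]),
            out_root=Path(values["out"]),
            formats=formats,
        ))
    if not jobs:
        raise ConfigError("configuration contains no <job> elements")
    return jobs
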