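"""Deterministic synthetic-cohort generator.

Emulates the source-side data the conversion engine consumes: a
``tcga_original`` directory tree (one directory per tumor tag, per-type
subdirectories of tab-delimited experiment files, a ``meta`` directory of
clinical/biospecimen XML documents) plus the four annotation lookup
tables, all internally consistent so the full pipeline runs end to end
with no download.

The generator is seeded and byte-deterministic: the same
:class:`CohortSpec` always produces an identical tree, summarized by a
SHA-256 manifest.  Value distributions are plausibility-only — the
conversion engine copies values, it never models them — and exist so the
serializers meet realistic numeric shapes: methylation beta values ~
Beta(0.5, 0.5), read/raw counts ~ negative binomial (mean 500,
dispersion 0.5), copy-number segment means ~ Normal(0, 0.5), coordinates
uniform over a synthetic genome of three 10-Mb chromosomes (chr1, chr2,
chrX).

``miss_fraction`` removes an exact fraction of gene and miRNA ids from
the emitted annotation tables (the ids still appear in the experiment
files), to exercise the annotation-miss paths; at the default 0.0 a full
conversion of the tree drops zero rows.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import EXPERIMENT_TYPES, GenomicRegion, TcgaBarcode
from .schemas import SUBTYPES

__all__ = ["CohortSpec", "ValueModels", "value_models", "generate",
           "annotation_paths", "GENOME", "read_manifest"]

#: Synthetic genome: chromosome name -> length (bp).
GENOME: dict[str, int] = {"chr1": 10_000_000, "chr2": 10_000_000,
                          "chrX": 10_000_000}

_ANALYTE = {"cnv": "D", "dnamethylation": "D", "dnaseq": "W",
            "mirnaseq": "H", "rnaseq": "R", "rnaseqv2": "R"}

_VARIANT_CLASSES = ("Missense_Mutation", "Silent", "Nonsense_Mutation",
                    "Frame_Shift_Del", "Splice_Site")
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort; equal specs yield identical trees."""

    seed: int = 0
    n_patients: int = 4
    tumor_tags: tuple[str, ...] = ("BRCA",)
    types: tuple[str, ...] = EXPERIMENT_TYPES
    n_genes: int = 100
    n_mirnas: int = 30
    n_transcripts: int = 60
    n_probes: int = 80
    n_exons: int = 60
    n_junctions: int = 40
    n_segments: int = 20
    n_mutations: int = 25
    miss_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if not (0.0 <= self.miss_fraction <= 1.0):
            raise ValueError("miss_fraction must be in [0, 1]")
        unknown = set(self.types) - set(EXPERIMENT_TYPES)
        if unknown:
            raise ValueError(f"unknown experiment types: {sorted(unknown)}")


class ValueModels:
    """The simple per-type value distributions used to fill experiment files."""

    def __init__(self, spec: CohortSpec):
        self.spec = spec

    def betas(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Methylation beta values ~ Beta(0.5, 0.5), support [0, 1]."""
        return np.clip(rng.beta(0.5, 0.5, size=n), 0.0, 1.0)

    def counts(self, rng: np.random.Generator, n: int,
               mean: float = 500.0, dispersion: float = 0.5) -> np.ndarray:
        """Read/raw counts ~ negative binomial with the given mean and
        dispersion (size) parameter; non-negative integers."""
        p = dispersion / (dispersion + mean)
        return rng.negative_binomial(dispersion, p, size=n)

    def segment_means(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Copy-number log2 segment means ~ Normal(0, 0.5)."""
        return rng.normal(0.0, 0.5, size=n)

    def region(self, rng: np.random.Generator, min_len: int,
               max_len: int) -> GenomicRegion:
        """A uniform region on the synthetic genome with start <= end."""
        chrom = str(rng.choice(list(GENOME)))
        chrom_len = GENOME[chrom]
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, chrom_len - 1)
        start = int(rng.integers(1, chrom_len - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        return GenomicRegion(chrom, start, start + length - 1, strand)


def value_models(spec: CohortSpec) -> ValueModels:
    return ValueModels(spec)


# ---------------------------------------------------------------------------
# feature universe
# ---------------------------------------------------------------------------

@dataclass
class _Universe:
    """The synthetic feature catalog shared by files and annotation tables."""

    genes: list[tuple[int, str, GenomicRegion]] = field(default_factory=list)
    transcripts: list[tuple[str, int]] = field(default_factory=list)
    mirnas: list[tuple[str, list[GenomicRegion]]] = field(default_factory=list)
    missing_entrez: set[int] = field(default_factory=set)
    missing_mirna: set[str] = field(default_factory=set)


def _build_universe(spec: CohortSpec, rng: np.random.Generator) -> _Universe:
    u = _Universe()
    models = ValueModels(spec)
    for i in range(spec.n_genes):
        entrez = 1000 + i
        symbol = f"GX{i:04d}"
        u.genes.append((entrez, symbol, models.region(rng, 2_000, 200_000)))
    for i in range(spec.n_transcripts):
        gene_idx = int(rng.integers(0, spec.n_genes))
        version = int(rng.integers(1, 4))
        u.transcripts.append((f"uc{i:06d}.{version}", 1000 + gene_idx))
    for i in range(spec.n_mirnas):
        loci = [models.region(rng, 60, 120)]
        if rng.random() < 0.1:  # ~10% of miRNAs map to a second locus
            loci.append(models.region(rng, 60, 120))
        u.mirnas.append((f"hsa-mir-{i + 1}", loci))
    n_miss_genes = int(round(spec.miss_fraction * spec.n_genes))
    if n_miss_genes:
        idx = rng.choice(spec.n_genes, size=n_miss_genes, replace=False)
        u.missing_entrez = {1000 + int(i) for i in idx}
    n_miss_mirnas = int(round(spec.miss_fraction * spec.n_mirnas))
    if n_miss_mirnas:
        idx = rng.choice(spec.n_mirnas, size=n_miss_mirnas, replace=False)
        u.missing_mirna = {u.mirnas[int(i)][0] for i in idx}
    return u


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text, encoding="utf-8")


def _write_annotation_tables(root: Path, u: _Universe) -> None:
    ann = root / "annotations"
    lines = ["entrez_id\tchrom\tstart\tend\tstrand"]
    for entrez, _symbol, r in u.genes:
        if entrez in u.missing_entrez:
            continue
        lines.append(f"{entrez}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}")
    _write(ann / "entrez_coords.tsv", "\n".join(lines) + "\n")

    lines = ["symbol\tentrez_id"]
    for entrez, symbol, _r in u.genes:
        lines.append(f"{symbol}\t{entrez}")
    _write(ann / "symbol_to_entrez.tsv", "\n".join(lines) + "\n")

    lines = ["ucsc_id\tentrez_id"]
    for ucsc, entrez in u.transcripts:
        lines.append(f"{ucsc}\t{entrez}")
    _write(ann / "ucsc_to_entrez.tsv", "\n".join(lines) + "\n")

    lines = ["mirna_id\tchrom\tstart\tend\tstrand"]
    for mirna_id, loci in u.mirnas:
        if mirna_id in u.missing_mirna:
            continue
        for r in loci:
            lines.append(f"{mirna_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}")
    _write(ann / "mirna_coords.tsv", "\n".join(lines) + "\n")


def annotation_paths(root: str | Path) -> dict[str, Path]:
    """Table-name → file-path mapping for :func:`tcgabed.annotations.load_store`."""
    ann = Path(root) / "annotations"
    return {
        "entrez_coords": ann / "entrez_coords.tsv",
        "symbol_to_entrez": ann / "symbol_to_entrez.tsv",
        "ucsc_to_entrez": ann / "ucsc_to_entrez.tsv",
        "mirna_coords": ann / "mirna_coords.tsv",
    }


# ---------------------------------------------------------------------------
# per-type experiment files
# ---------------------------------------------------------------------------

def _gene_positions(rng: np.random.Generator, region: GenomicRegion,
                    n: int) -> np.ndarray:
    return rng.integers(region.start, region.end + 1, size=n)


def _cnv_file(rng, models, u, barcode: str, spec: CohortSpec) -> str:
    lines = ["Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean"]
    means = models.segment_means(rng, spec.n_segments)
    for i in range(spec.n_segments):
        r = models.region(rng, 1_000, 500_000)
        probes = int(rng.integers(5, 500))
        # raw TCGA segment files print bare chromosome numbers
        lines.append(f"{barcode}\t{r.chrom[3:]}\t{r.start}\t{r.end}"
                     f"\t{probes}\t{means[i]:.4f}")
    return "\n".join(lines) + "\n"


def _methylation_file(rng, models, u, barcode: str, spec: CohortSpec) -> str:
    lines = ["Composite Element REF\tBeta_value\tGene_Symbol\tChromosome"
             "\tGenomic_Coordinate"]
    betas = models.betas(rng, spec.n_probes)
    gene_idx = rng.integers(0, spec.n_genes, size=spec.n_probes)
    for i in range(spec.n_probes):
        entrez, symbol, region = u.genes[int(gene_idx[i])]
        pos = int(_gene_positions(rng, region, 1)[0])
        beta = "NA" if rng.random() < 0.02 else f"{betas[i]:.4f}"
        lines.append(f"cg{i:08d}\t{beta}\t{symbol}\t{region.chrom[3:]}\t{pos}")
    return "\n".join(lines) + "\n"


def _maf_file(rng, models, u, barcode: TcgaBarcode, spec: CohortSpec) -> str:
    normal = TcgaBarcode(
        tss=barcode.tss, participant=barcode.participant, sample="10",
        vial="A", portion=barcode.portion, analyte=barcode.analyte,
        plate=barcode.plate, center=barcode.center,
    )
    header = ("Hugo_Symbol\tEntrez_Gene_Id\tCenter\tNCBI_Build\tChromosome"
              "\tStart_position\tEnd_position\tStrand\tVariant_Classification"
              "\tVariant_Type\tReference_Allele\tTumor_Seq_Allele1"
              "\tTumor_Seq_Allele2\tdbSNP_RS\tTumor_Sample_Barcode"
              "\tMatched_Norm_Sample_Barcode\tMutation_Status\tSequencer"
              "\tValidation_Status")
    lines = ["#version 2.4", header]
    gene_idx = rng.integers(0, spec.n_genes, size=spec.n_mutations)
    for i in range(spec.n_mutations):
        entrez, symbol, region = u.genes[int(gene_idx[i])]
        pos = int(_gene_positions(rng, region, 1)[0])
        ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
        vclass = str(rng.choice(_VARIANT_CLASSES))
        dbsnp = "novel" if rng.random() < 0.7 else f"rs{int(rng.integers(1, 10 ** 8))}"
        lines.append(
            f"{symbol}\t{entrez}\tsynthetic\t37\t{region.chrom[3:]}\t{pos}\t{pos}"
            f"\t+\t{vclass}\tSNP\t{ref}\t{ref}\t{alt}\t{dbsnp}"
            f"\t{barcode.render()}\t{normal.render()}\tSomatic"
            f"\tIllumina HiSeq\tUntested"
        )
    return "\n".join(lines) + "\n"


def _mirnaseq_file(rng, models, u, barcode: str, spec: CohortSpec) -> str:
    lines = ["miRNA_ID\tread_count\treads_per_million_miRNA_mapped\tcross-mapped"]
    counts = models.counts(rng, spec.n_mirnas)
    total = max(int(counts.sum()), 1)
    for i, (mirna_id, _loci) in enumerate(u.mirnas):
        rpm = counts[i] / total * 1e6
        cross = "Y" if rng.random() < 0.05 else "N"
        lines.append(f"{mirna_id}\t{int(counts[i])}\t{rpm:.6f}\t{cross}")
    return "\n".join(lines) + "\n"


def _rnaseq_gene_file(rng, models, u, spec: CohortSpec) -> str:
    lines = ["gene\traw_counts\tmedian_length_normalized\tRPKM"]
    counts = models.counts(rng, spec.n_genes)
    for i, (entrez, symbol, _region) in enumerate(u.genes):
        mln = rng.random()
        rpkm = counts[i] / max(rng.random() * 100.0, 1.0)
        lines.append(f"{symbol}|{entrez}\t{int(counts[i])}\t{mln:.4f}\t{rpkm:.4f}")
    return "\n".join(lines) + "\n"


def _rnaseqv2_gene_file(rng, models, u, spec: CohortSpec) -> str:
    lines = ["gene_id\traw_count\tscaled_estimate\tnormalized_count"]
    counts = models.counts(rng, spec.n_genes)
    for i, (entrez, symbol, _region) in enumerate(u.genes):
        shown = "?" if rng.random() < 0.05 else symbol  # TCGA's unknown-symbol token
        scaled = counts[i] / 1e8
        norm = counts[i] * (0.5 + rng.random())
        lines.append(f"{shown}|{entrez}\t{counts[i]:.4f}\t{scaled:.6e}\t{norm:.4f}")
    return "\n".join(lines) + "\n"


def _exon_file(rng, models, u, spec: CohortSpec) -> str:
    lines = ["exon\traw_counts\tmedian_length_normalized\tRPKM"]
    counts = models.counts(rng, spec.n_exons)
    gene_idx = rng.integers(0, spec.n_genes, size=spec.n_exons)
    for i in range(spec.n_exons):
        _entrez, _symbol, region = u.genes[int(gene_idx[i])]
        width = int(rng.integers(50, 400))
        start = int(rng.integers(region.start, max(region.end - width,
                                                   region.start) + 1))
        end = min(start + width, region.end)
        # minus-strand keys print the interval reversed, as some TCGA
        # platforms did; converters normalize to start <= end
        if region.strand == "-":
            key = f"{region.chrom}:{end}-{start}:-"
        else:
            key = f"{region.chrom}:{start}-{end}:+"
        mln = rng.random()
        rpkm = counts[i] / max(rng.random() * 100.0, 1.0)
        lines.append(f"{key}\t{int(counts[i])}\t{mln:.4f}\t{rpkm:.4f}")
    return "\n".join(lines) + "\n"


def _spljxn_file(rng, models, u, spec: CohortSpec) -> str:
    lines = ["junction\traw_counts"]
    counts = models.counts(rng, spec.n_junctions, mean=50.0)
    gene_idx = rng.integers(0, spec.n_genes, size=spec.n_junctions)
    for i in range(spec.n_junctions):
        _entrez, _symbol, region = u.genes[int(gene_idx[i])]
        a = int(rng.integers(region.start, region.end + 1))
        gap = int(rng.integers(80, 5_000))
        b = min(a + gap, region.end)
        if a == b:
            b = min(a + 1, region.end)
            a = max(b - 1, region.start)
        s = region.strand
        donor, acceptor = (a, b) if s == "+" else (b, a)
        key = f"{region.chrom}:{donor}:{s},{region.chrom}:{acceptor}:{s}"
        lines.append(f"{key}\t{int(counts[i])}")
    return "\n".join(lines) + "\n"


def _isoform_file(rng, models, u, spec: CohortSpec) -> str:
    lines = ["isoform_id\traw_count\tscaled_estimate\tnormalized_count"]
    counts = models.counts(rng, spec.n_transcripts)
    for i, (ucsc, _entrez) in enumerate(u.transcripts):
        scaled = counts[i] / 1e8
        norm = counts[i] * (0.5 + rng.random())
        lines.append(f"{ucsc}\t{counts[i]:.4f}\t{scaled:.6e}\t{norm:.4f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# metadata documents
# ---------------------------------------------------------------------------

_GENDERS = ("FEMALE", "MALE")
_RACES = ("WHITE", "BLACK OR AFRICAN AMERICAN", "ASIAN")
_VITAL = ("Alive", "Dead")


def _clinical_doc(rng, patient_id: str, tumor: str) -> str:
    gender = str(rng.choice(_GENDERS))
    age = int(rng.integers(30, 90))
    vital = str(rng.choice(_VITAL))
    race_lines = "".join(
        f"    <race>{r}</race>\n"
        for r in sorted(rng.choice(_RACES,
                                   size=1 if rng.random() < 0.9 else 2,
                                   replace=False).tolist())
    )
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        "<patient>\n"
        f"  <bcr_patient_barcode>{patient_id}</bcr_patient_barcode>\n"
        f"  <gender>{gender}</gender>\n"
        f"  <age_at_initial_pathologic_diagnosis>{age}"
        "</age_at_initial_pathologic_diagnosis>\n"
        f"  <vital_status>{vital}</vital_status>\n"
        "  <demographics>\n"
        f"{race_lines}"
        "  </demographics>\n"
        f"  <disease_code>{tumor.upper()}</disease_code>\n"
        "  <days_to_birth></days_to_birth>\n"
        "</patient>\n"
    )


def _biospecimen_doc(barcode: TcgaBarcode) -> str:
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        "<biospecimen>\n"
        f"  <bcr_patient_barcode>{barcode.patient_id}</bcr_patient_barcode>\n"
        f"  <bcr_sample_barcode>{barcode.sample_id}</bcr_sample_barcode>\n"
        f"  <bcr_aliquot_barcode>{barcode.render()}</bcr_aliquot_barcode>\n"
        f"  <sample_type_id>{barcode.sample}</sample_type_id>\n"
        "  <is_ffpe>NO</is_ffpe>\n"
        f"  <plate_id>{barcode.plate}</plate_id>\n"
        "</biospecimen>\n"
    )


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _aliquot(tumor_idx: int, patient_idx: int, type_idx: int) -> TcgaBarcode:
    return TcgaBarcode(
        tss=f"{tumor_idx + 10:02d}",
        participant=f"{patient_idx + 1:04d}",
        sample="01",
        vial="A",
        portion="01",
        analyte=_ANALYTE[EXPERIMENT_TYPES[type_idx]],
        plate=f"{1000 + type_idx:04d}",
        center="01",
    )


def generate(spec: CohortSpec, root: str | Path) -> dict[str, str]:
    """Write the synthetic source tree under ``root``.

    Produces ``tcga_original/<tumor>/<type>/`` experiment files, the
    ``meta`` documents, the ``annotations`` tables and a ``manifest.tsv``
    of SHA-256 checksums.  Returns the manifest as a relpath → digest
    mapping (the manifest file itself is not listed in it).
    """
    root = Path(root)
    rng = np.random.default_rng(spec.seed)
    models = ValueModels(spec)
    u = _build_universe(spec, rng)
    _write_annotation_tables(root, u)

    patients = [(i, spec.tumor_tags[i % len(spec.tumor_tags)])
                for i in range(spec.n_patients)]

    for p_idx, tumor in patients:
        tumor_idx = spec.tumor_tags.index(tumor)
        tdir = root / "tcga_original" / tumor.lower()
        patient_barcode = f"TCGA-{tumor_idx + 10:02d}-{p_idx + 1:04d}"
        _write(tdir / "meta" / f"{patient_barcode}.clinical.xml",
               _clinical_doc(rng, patient_barcode, tumor))
        for exp_type in spec.types:
            type_idx = EXPERIMENT_TYPES.index(exp_type)
            barcode = _aliquot(tumor_idx, p_idx, type_idx)
            _write(tdir / "meta" / f"{barcode.render()}.biospecimen.xml",
                   _biospecimen_doc(barcode))
            out = tdir / exp_type
            if exp_type == "cnv":
                _write(out / f"{barcode.render()}.txt",
                       _cnv_file(rng, models, u, barcode.render(), spec))
            elif exp_type == "dnamethylation":
                _write(out / f"{barcode.render()}.txt",
                       _methylation_file(rng, models, u, barcode.render(), spec))
            elif exp_type == "dnaseq":
                _write(out / f"{barcode.render()}.txt",
                       _maf_file(rng, models, u, barcode, spec))
            elif exp_type == "mirnaseq":
                _write(out / f"{barcode.render()}.txt",
                       _mirnaseq_file(rng, models, u, barcode.render(), spec))
            elif exp_type == "rnaseq":
                _write(out / f"{barcode.render()}.gene.txt",
                       _rnaseq_gene_file(rng, models, u, spec))
                _write(out / f"{barcode.render()}.exon.txt",
                       _exon_file(rng, models, u, spec))
                _write(out / f"{barcode.render()}.spljxn.txt",
                       _spljxn_file(rng, models, u, spec))
            else:  # rnaseqv2
                _write(out / f"{barcode.render()}.gene.txt",
                       _rnaseqv2_gene_file(rng, models, u, spec))
                _write(out / f"{barcode.render()}.exon.txt",
                       _exon_file(rng, models, u, spec))
                _write(out / f"{barcode.render()}.spljxn.txt",
                       _spljxn_file(rng, models, u, spec))
                _write(out / f"{barcode.render()}.isoform.txt",
                       _isoform_file(rng, models, u, spec))

    manifest = _build_manifest(root)
    lines = [f"{digest}\t{rel}" for rel, digest in sorted(manifest.items())]
    _write(root / "manifest.tsv", "\n".join(lines) + "\n")
    return manifest


def _build_manifest(root: Path) -> dict[str, str]:
    manifest: dict[str, str] = {}
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.name != "manifest.tsv":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[path.relative_to(root).as_posix()] = digest
    return manifest


def read_manifest(root: str | Path) -> dict[str, str]:
    manifest: dict[str, str] = {}
    for line in (Path(root) / "manifest.tsv").read_text(
            encoding="utf-8").splitlines():
        if line:
            digest, _, rel = line.partition("\t")
            manifest[rel] = digest
    return manifest
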