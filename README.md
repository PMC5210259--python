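# tcgabed

Convert TCGA-style level-2/3 cancer-genomics files into a uniform,
aliquot-oriented **free-BED** repository, with the clinical and
biospecimen metadata flattened to attribute–value text.

## Who this is for

TCGA distributes each experiment type (copy-number segments, DNA
methylation, somatic mutations, miRNA-seq, RNA-seq V1/V2 quantifications)
in its own tab-delimited layout, with inconsistent chromosome naming and
— for several types — no genomic coordinates at all. Anyone wanting to
query these data *together* (region intersections across data types,
joint filtering on clinical attributes) first has to normalize all of
them to one genomic data model. `tcgabed` does that normalization: every
record of every type becomes a line in a BED-like file whose first four
columns are always the same, and every experiment (identified by its
aliquot barcode) gets a metadata sidecar in the same flat format.

## The data model

**Free BED.** A tab-delimited, headerless file, one line per genomic
feature. The first four fields are mandatory and shared by all data
types:

```
chrom  chromStart  chromEnd  strand
```

followed by an *unlimited* attribute tail fixed per (experiment type,
subtype) — e.g. `num_probes, segment_mean` for copy-number segments —
declared in a `header.schema` XML sidecar. Coordinates are **one-based
closed**, the convention of the TCGA source files themselves (the region
covering the 3rd through 7th bases is `[3, 7]`); this deliberately
differs from UCSC BED's zero-based half-open convention. Strand is `+`,
`-`, or `*` when unknown/not applicable.

**Aliquot orientation.** The unit of analysis is the aliquot, named by
its barcode `TCGA-<tss>-<participant>-<sample><vial>-<portion><analyte>-<plate>-<center>`
(e.g. `TCGA-02-0021-01A-01D-0002-04`; the first three groups identify the
patient, the first four the sample). Each aliquot yields one data file
per format plus one `.bed.meta` file of sorted `key<TAB>value` pairs
merging the patient's clinical document, the aliquot's biospecimen
document and three provenance keys.

**Annotation enrichment.** Where the source files lack coordinates or
strand, they are recovered from four local lookup tables composed into
chains, mirroring the classic gene databases:

| chain | used by |
|---|---|
| Entrez Gene id → coordinates + strand | RNA-seq V1/V2 gene quantifications |
| HGNC symbol → Entrez id → strand | DNA methylation |
| UCSC transcript id → Entrez id → coordinates | RNA-seq V2 isoforms |
| miRNA id → loci (possibly several) | miRNA-seq |

A broken chain is reported, never silently ignored: rows missing only a
strand are kept with `*`; rows whose *region* cannot be established are
dropped and counted.

## Worked example

Generate a small deterministic synthetic cohort (2 patients, all six
experiment types, internally consistent annotation tables), then convert
its DNA-methylation files:

```
$ tcgabed fixtures --out demo --seed 7 --patients 2
wrote 40 files under demo

$ tcgabed convert --source demo/tcga_original --tumor BRCA \
    --type dnamethylation --formats bed,gtf \
    --annotations demo/annotations --out repo
1 job(s): 160 rows in, 160 records out, 0 dropped, 0 annotation misses (report: repo/run_report.json)
```

160 methylation probes in, 160 BED records out, nothing dropped: every
probe position was present and every gene symbol resolved through the
HGNC→Entrez chain. The output tree is
`repo/bed/brca/dnamethylation/` with one `.bed`, `.gtf` and `.bed.meta`
per aliquot plus the two per-directory sidecars:

```
$ head -3 repo/bed/brca/dnamethylation/TCGA-10-0001-01A-01D-1001-01.bed
chr1	223152	223152	+	cg00000066	0.0777	GX0078
chr1	1150061	1150061	-	cg00000012	0.0248	GX0077
chr1	1437393	1437393	-	cg00000017	0.4445	GX0061
```

Each line is one probe: a single-base one-based region (start == end),
the strand recovered from the probe's gene symbol, then the attribute
tail `composite_element_ref, beta_value, gene_symbol` in the order
declared by `header.schema`:

```
$ head -8 repo/bed/brca/dnamethylation/header.schema
<?xml version='1.0' encoding='UTF-8'?>
<bedSchema experimentType="dnamethylation">
  <field name="chrom" kind="string"/>
  <field name="chromStart" kind="integer"/>
  <field name="chromEnd" kind="integer"/>
  <field name="strand" kind="char"/>
  <field name="composite_element_ref" kind="string"/>
  <field name="beta_value" kind="float"/>
```

and the metadata companion is flat attribute–value text:

```
$ head -5 repo/bed/brca/dnamethylation/TCGA-10-0001-01A-01D-1001-01.bed.meta
biospecimen__bcr_aliquot_barcode	TCGA-10-0001-01A-01D-1001-01
biospecimen__bcr_patient_barcode	TCGA-10-0001
biospecimen__bcr_sample_barcode	TCGA-10-0001-01A
biospecimen__is_ffpe	NO
biospecimen__plate_id	1001
```

The same records can be written as `csv`, `json` and `xml`; batch runs
are described by an XML job configuration (`tcgabed convert --config
jobs.xml`), and a `metadata_dictionary.txt` per directory lists every
metadata attribute with all the distinct values it assumes.

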