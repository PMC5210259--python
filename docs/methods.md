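# Methods

## The conversion model

The engine maps six TCGA-style experiment types onto one target model: a
*free-BED* record — a one-based closed genomic region with a strand plus
an ordered, typed attribute tail — organized per aliquot.

Coordinate convention. TCGA level-2/3 files count bases from 1 and state
regions as closed intervals, so the engine keeps that convention end to
end rather than shifting to UCSC BED's zero-based half-open form; the
`to_one_based_closed` / `to_zero_based_half_open` pair is the explicit,
length-preserving bijection between the two (the 3rd–7th bases are
`(2, 7)` half-open and `[3, 7]` closed). Single-base features
(methylation probes, point mutations) are legal regions with
start == end. Chromosome names are normalized to `chr1..chr22, chrX,
chrY, chrM` on input (`17`, `chr17`, `MT` are all accepted); records
sort in karyotype order, not lexicographically, so output files are
deterministic and diffable.

Strand. The model requires a strand column in every type, but
copy-number segments have none and several quantification layouts lose
it; `*` is the explicit unknown/not-applicable placeholder. `*` was
chosen over `.` so that the GTF writer (where `.` already means "empty
field") has an unambiguous mapping. A missing strand alone never costs a
row; a missing *region* always does, because the first three fields are
mandatory.

Schemas. Each (experiment type, subtype) pair has a fixed column schema:
the four mandatory fields then the attributes carried over from the
original layout (13 MAF columns for mutations; probe/beta/symbol for
methylation; and so on). The schema object is the single authority for
attribute order, value kinds (string/integer/float/char), the
`header.schema` sidecar and the typed JSON rendering. By construction
the intersection of all schemas' columns is exactly
{chrom, chromStart, chromEnd, strand} — measured, not assumed, by
`schemas.mandatory_field_intersection` and the acceptance script.

Splice junctions get ad-hoc attributes: the record region spans from the
lower to the higher of the two junction positions (regions require
start ≤ end), while `donor_chrom/donor_pos/acceptor_chrom/acceptor_pos`
preserve the original orientation, so no information is lost by the
normalization. Likewise the exon converter keeps the original composite
key as the `exon` attribute because minus-strand keys sometimes print
the interval reversed. Junctions whose two sites lie on different
chromosomes cannot form a single region and are dropped (counted and
logged).

## Annotation enrichment

Four local tables stand in for the live gene-database services, composed
into the chains the converters need:

- `entrez_coords` (Entrez Gene id → chrom, start, end, strand) — gene
  quantifications;
- `symbol_to_entrez` (HGNC symbol → Entrez id), then `entrez_coords` —
  methylation strand recovery;
- `ucsc_to_entrez` (UCSC transcript id → Entrez id), then
  `entrez_coords` — isoform quantifications, with a version-stripping
  fallback (`uc001aaa.3` → `uc001aaa`) because the quantification files
  and transcript tables disagree on id versions;
- `mirna_coords` (miRNA id → one or more loci, case-insensitive) —
  miRNA-seq, where one id may legitimately map to several genomic
  placements and then expands to one record per locus.

Lookups are pure reads returning either a value or a structured
`AnnotationMiss` naming the identifier and the failing chain stage;
misses travel in conversion reports. Duplicate table keys: last
occurrence wins with a logged warning (except miRNA ids, which
accumulate loci). Each Entrez id stores exactly one region — the table
builder is expected to pre-select the primary-assembly placement. The
store is genome-assembly-agnostic; the provenance of the tables must
declare the build. The whole store persists to a single sorted
tab-delimited cache file that reloads bit-exactly.

Unresolvable-annotation policy: drop the row when the missing datum is
the region itself (gene/isoform/miRNA coordinates), keep it with `*`
when only the strand is missing (methylation). Every conversion report
satisfies rows_in = records_out + dropped, with the miRNA multi-locus
expansion only ever adding records.

## Metadata flattening

Clinical documents (per patient) and biospecimen documents (per aliquot)
are hierarchical XML; they flatten to `key<TAB>value` pairs with keys =
lowercased element paths from (but excluding) the root, joined by `__`,
and repeated siblings disambiguated by a 1-based `__k` suffix. Empty
leaves emit nothing. Pairs are prefixed `clinical__`/`biospecimen__` to
prevent collisions, and three `manually_curated__` provenance keys
(tumor tag, experiment data type, full aliquot barcode) are added.
Because the repository is aliquot-oriented, a patient's clinical pairs
are denormalized into every one of their aliquots' `.meta` files. The
`.meta` line format (`key<TAB>value`, sorted, UTF-8) and the
`metadata_dictionary.txt` format (`key<TAB>v1<TAB>v2…`, keys and values
sorted) are bit-exact contracts; linkage between a document's own
barcode fields and the target aliquot is verified, not trusted.

## Output formats

BED is headerless; structure lives in `header.schema`, validated against
the package's shipped XML Schema. CSV follows RFC 4180 with a header
row; JSON writes integers/floats as numbers and the null token as a JSON
null; XML nests one element per field; GTF keeps the coordinates
unchanged (it is natively one-based closed), maps `*` strand to `.`,
uses the package name as its `source` column and a per-type feature
token (`cnv_segment`, `methylation_site`, `mutation`, `mirna`, `gene`,
`exon`, `splice_junction`, `isoform`). Numeric canonicalization happens
once, at conversion time: integers bare, floats with up to 6 significant
digits, positional notation down to 1e-4 and scientific below,
locale-independent — this makes every writer deterministic and the
BED↔CSV↔JSON round trips exact. The uniform null token is `null`;
`NA`/`N/A`/empty input cells canonicalize to it.

## Repository layout

`bed/<tumor-tag-lowercase>/<type>/` with type ∈ cnv, dnamethylation,
dnaseq, mirnaseq, rnaseq, rnaseqv2. One directory holds exactly one
schema, so the multi-subtype RNA-seq types add one subdirectory per
subtype (gene/exon/spljxn/isoform). Files are `<aliquot-barcode>.<ext>`
with the format-independent metadata companion
`<aliquot-barcode>.bed.meta`; each directory also carries
`header.schema` and `metadata_dictionary.txt`. Runs are described either
by CLI flags or by an XML job configuration (flags override); unknown
types or formats fail validation before any file is written, and
re-running an unchanged job rewrites byte-identical output. The original
portal-download path is out of scope — the source adapter reads a local
directory tree.

## Synthetic cohorts

The fixture generator emulates the *source* side so the full pipeline
runs with no network: a `tcga_original/<tumor>/` tree of per-type
experiment files, per-patient clinical and per-aliquot biospecimen
documents, and the four annotation tables, all referentially consistent
(every aliquot has exactly one biospecimen document; every feature id in
the files exists in the tables except an exact, configurable
miss-fraction used to exercise the miss paths).

Value models are plausibility-only — the engine copies values, it never
models them — and exist so the serializers face realistic numeric
shapes: beta values ~ Beta(0.5, 0.5); read/raw counts ~ negative
binomial with mean 500 and dispersion 0.5; copy-number segment means ~
Normal(0, 0.5); coordinates uniform on a synthetic genome of three 10-Mb
chromosomes (chr1, chr2, chrX). Defaults are desk-scale: 4 patients, one
tumor tag, 100 genes, 60 transcripts, 30 miRNAs, and per-file row counts
in the tens — small enough that the whole test suite runs in seconds
while every code path (multi-locus miRNAs, reversed minus-strand exon
keys, `?`-symbol gene ids, `NA` beta values, repeated clinical siblings)
is exercised. Generation is a pure function of the `CohortSpec`: one
seeded RNG, fixed iteration order, and a SHA-256 manifest proving two
runs identical.

What the fixtures do *not* emulate — and therefore what passing tests do
not show about real data: biological structure (linkage disequilibrium,
methylation co-variation, mutation signatures), real barcode code
registries, platform-specific quirks beyond the layout variations listed
above, hg18/hg19 assembly mixtures, or corpus-scale volumes. Tests
establish the correctness of the conversion algebra and the layout
contracts, not distributional realism.

## Numerical and degenerate-input choices

- Empty zero-based intervals (start ≥ end) have no closed image and are
  rejected; inverted or sub-base-1 source intervals are dropped rows,
  not errors, except in MAF files where a *missing* coordinate column is
  a malformed input (the layout itself is broken).
- Barcode validation is strict on structure, permissive on unknown
  TSS/center codes (no registry is shipped).
- Ties in record ordering are broken by strand and then the attribute
  values, giving a total order and byte-stable files.
- `float` parsing accepts scientific notation; canonical text is
  idempotent under parse/format, which the cross-format round-trip tests
  rely on.

## Known limitations

- No genome-build liftover; coordinates are whatever the annotation
  tables contain.
- Symbol resolution is exact-match against the HGNC symbol column; no
  synonym handling.
- Controlled-access data types, UUID-based identifiers, live database
  queries during conversion and FTP publishing are out of scope.
- The MAF handling targets the v2.x column set used by the public
  level-2 files; other MAF dialects may need a column-mapping shim.
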