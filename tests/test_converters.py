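"""Per-type conversion rules, annotation enrichment and count conservation."""

from __future__ import annotations

import pytest

from tcgabed.annotations import AnnotationStore
from tcgabed.converters import (
    convert_cnv,
    convert_dnaseq,
    convert_methylation,
    convert_mirnaseq,
    convert_rnaseq_exon,
    convert_rnaseq_gene,
    convert_rnaseq_spljxn,
    convert_rnaseqv2_isoform,
    get_converter,
    read_source_file,
)
from tcgabed.core import GenomicRegion, MANDATORY_FIELDS
from tcgabed.errors import MalformedInputError
from tcgabed.schemas import SCHEMAS, SUBTYPES, get_schema
from tcgabed.serializers import render_bed


@pytest.fixture
def chain_store() -> AnnotationStore:
    store = AnnotationStore()
    store.entrez_coords[100] = GenomicRegion("chr1", 1000, 2000, "+")
    store.symbol_to_entrez["GENE1"] = 100
    store.ucsc_to_entrez["uc001aaa"] = 100
    store.mirna_coords["hsa-mir-21"] = [
        GenomicRegion("chr17", 59841266, 59841337, "+")]
    store.mirna_coords["hsa-mir-9"] = [
        GenomicRegion("chr1", 100, 180, "+"),
        GenomicRegion("chr2", 500, 580, "-")]
    return store


class TestCnv:
    def test_column_mapping(self):
        rows = [{"Sample": "s", "Chromosome": "3", "Start": "1000",
                 "End": "5000", "Num_Probes": "52", "Segment_Mean": "-0.31"}]
        records, report = convert_cnv(rows)
        assert report.rows_in == 1 and report.records_out == 1
        (rec,) = records
        assert rec.region == GenomicRegion("chr3", 1000, 5000, "*")
        assert rec.attributes == (("num_probes", "52"),
                                  ("segment_mean", "-0.31"))

    def test_empty_input(self):
        records, report = convert_cnv([])
        assert records == [] and report.rows_in == 0

    def test_inverted_segment_dropped(self):
        rows = [{"Sample": "s", "Chromosome": "3", "Start": "5000",
                 "End": "1000", "Num_Probes": "1", "Segment_Mean": "0"}]
        records, report = convert_cnv(rows)
        assert records == []
        assert (report.rows_in, report.records_out, report.dropped) == (1, 0, 1)


class TestMethylation:
    ROW = {"Composite Element REF": "cg00000029", "Beta_value": "0.42",
           "Gene_Symbol": "GENE1", "Chromosome": "1",
           "Genomic_Coordinate": "1500"}

    def test_strand_recovered_through_symbol_chain(self, chain_store):
        records, report = convert_methylation([self.ROW], chain_store)
        (rec,) = records
        assert rec.region == GenomicRegion("chr1", 1500, 1500, "+")
        assert rec.attributes == (("composite_element_ref", "cg00000029"),
                                  ("beta_value", "0.42"),
                                  ("gene_symbol", "GENE1"))
        assert report.misses == []

    def test_unresolvable_symbol_keeps_row_with_placeholder(self, chain_store):
        row = dict(self.ROW, Gene_Symbol="NOSUCH")
        records, report = convert_methylation([row], chain_store)
        (rec,) = records
        assert rec.region.strand == "*"
        assert report.dropped == 0
        assert len(report.misses) == 1
        assert report.misses[0].id_value == "NOSUCH"

    def test_na_beta_becomes_null(self, chain_store):
        row = dict(self.ROW, Beta_value="NA")
        records, _ = convert_methylation([row], chain_store)
        assert records[0].attribute("beta_value") is None


class TestDnaseq:
    ROW = {"Hugo_Symbol": "GENE1", "Entrez_Gene_Id": "100",
           "Chromosome": "17", "Start_position": "7577120",
           "End_position": "7577120", "Strand": "+",
           "Variant_Classification": "Missense_Mutation",
           "Variant_Type": "SNP", "Reference_Allele": "C",
           "Tumor_Seq_Allele1": "C", "Tumor_Seq_Allele2": "T",
           "dbSNP_RS": "novel",
           "Tumor_Sample_Barcode": "TCGA-02-0021-01A-01D-0002-04",
           "Matched_Norm_Sample_Barcode": "TCGA-02-0021-10A-01D-0002-04",
           "Mutation_Status": "Somatic", "Sequencer": "Illumina HiSeq",
           "Validation_Status": "Untested"}

    def test_maf_passthrough_in_schema_order(self):
        records, _ = convert_dnaseq([self.ROW])
        (rec,) = records
        assert rec.region == GenomicRegion("chr17", 7577120, 7577120, "+")
        assert [n for n, _ in rec.attributes] == [
            n for n, _ in get_schema("dnaseq").attribute_columns]
        assert rec.attribute("hugo_symbol") == "GENE1"
        assert rec.attribute("entrez_gene_id") == "100"
        assert rec.attribute("tumor_seq_allele2") == "T"

    def test_mitochondrion_normalized(self):
        records, _ = convert_dnaseq([dict(self.ROW, Chromosome="MT")])
        assert records[0].region.chrom == "chrM"

    def test_missing_coordinate_column_is_malformed(self):
        row = {k: v for k, v in self.ROW.items() if k != "Start_position"}
        with pytest.raises(MalformedInputError, match="Start_position"):
            convert_dnaseq([row], source="f.maf")


class TestMirnaseq:
    ROW = {"miRNA_ID": "hsa-mir-21", "read_count": "5000",
           "reads_per_million_miRNA_mapped": "812.5", "cross-mapped": "N"}

    def test_single_locus(self, chain_store):
        records, report = convert_mirnaseq([self.ROW], chain_store)
        (rec,) = records
        assert rec.region == GenomicRegion("chr17", 59841266, 59841337, "+")
        assert rec.attributes == (("mirna_id", "hsa-mir-21"),
                                  ("read_count", "5000"),
                                  ("reads_per_million_mirna_mapped", "812.5"),
                                  ("cross_mapped", "N"))

    def test_multi_locus_expansion(self, chain_store):
        row = dict(self.ROW, miRNA_ID="hsa-mir-9")
        records, report = convert_mirnaseq([row], chain_store)
        assert report.rows_in == 1 and report.records_out == 2
        assert {r.region.chrom for r in records} == {"chr1", "chr2"}
        assert records[0].attributes[1:] == records[1].attributes[1:]

    def test_unknown_id_dropped_with_miss(self, chain_store):
        row = dict(self.ROW, miRNA_ID="hsa-mir-404")
        records, report = convert_mirnaseq([row], chain_store)
        assert records == [] and report.dropped == 1
        assert report.misses[0].id_kind == "mirna"


class TestRnaseqGene:
    def test_v2_lookup_and_split(self, chain_store):
        rows = [{"gene_id": "GENE1|100", "raw_count": "1523",
                 "scaled_estimate": "0.000012", "normalized_count": "820.1"}]
        records, _ = convert_rnaseq_gene(rows, chain_store, version="v2")
        (rec,) = records
        assert rec.region == GenomicRegion("chr1", 1000, 2000, "+")
        assert rec.attribute("entrez_gene_id") == "100"
        assert rec.attribute("gene_symbol") == "GENE1"
        assert rec.attribute("scaled_estimate") == "1.2e-05"
        assert rec.attribute("normalized_count") == "820.1"

    def test_question_mark_symbol_is_null(self, chain_store):
        rows = [{"gene_id": "?|100", "raw_count": "1", "scaled_estimate": "0",
                 "normalized_count": "1"}]
        records, _ = convert_rnaseq_gene(rows, chain_store, version="v2")
        assert records[0].attribute("gene_symbol") is None
        assert records[0].region.chrom == "chr1"  # still resolved via 100

    def test_unplaced_entrez_dropped(self, chain_store):
        rows = [{"gene_id": "OTHER|999", "raw_count": "1",
                 "scaled_estimate": "0", "normalized_count": "1"}]
        records, report = convert_rnaseq_gene(rows, chain_store, version="v2")
        assert records == [] and report.dropped == 1
        assert report.misses[0].id_kind == "entrez"

    def test_v1_layout(self, chain_store):
        rows = [{"gene": "GENE1|100", "raw_counts": "57",
                 "median_length_normalized": "0.43", "RPKM": "3.1"}]
        records, _ = convert_rnaseq_gene(rows, chain_store, version="v1")
        assert records[0].attribute("rpkm") == "3.1"


class TestRnaseqExon:
    def test_composite_key_parsed(self):
        rows = [{"exon": "chr1:1000-2000:+", "raw_counts": "57",
                 "median_length_normalized": "0.43", "RPKM": "3.1"}]
        records, _ = convert_rnaseq_exon(rows)
        (rec,) = records
        assert rec.region == GenomicRegion("chr1", 1000, 2000, "+")
        assert rec.attribute("exon") == "chr1:1000-2000:+"

    def test_reversed_minus_strand_key_normalized(self):
        rows = [{"exon": "chr1:2000-1000:-", "raw_counts": "1",
                 "median_length_normalized": "0", "RPKM": "0"}]
        records, _ = convert_rnaseq_exon(rows)
        (rec,) = records
        assert (rec.region.start, rec.region.end) == (1000, 2000)
        assert rec.region.strand == "-"
        assert rec.attribute("exon") == "chr1:2000-1000:-"  # original key kept

    def test_malformed_key_cites_line(self):
        rows = [{"exon": "chr1:1000", "raw_counts": "1",
                 "median_length_normalized": "0", "RPKM": "0"}]
        with pytest.raises(MalformedInputError, match="line 2"):
            convert_rnaseq_exon(rows)


class TestRnaseqSpljxn:
    def test_plus_strand_junction_span(self):
        rows = [{"junction": "chr1:12227:+,chr1:12595:+", "raw_counts": "12"}]
        records, _ = convert_rnaseq_spljxn(rows)
        (rec,) = records
        assert rec.region == GenomicRegion("chr1", 12227, 12595, "+")
        assert rec.attributes == (("donor_chrom", "chr1"),
                                  ("donor_pos", "12227"),
                                  ("acceptor_chrom", "chr1"),
                                  ("acceptor_pos", "12595"),
                                  ("raw_counts", "12"))

    def test_minus_strand_orientation_preserved_in_attrs(self):
        rows = [{"junction": "chr1:900:-,chr1:500:-", "raw_counts": "3"}]
        records, _ = convert_rnaseq_spljxn(rows)
        (rec,) = records
        assert (rec.region.start, rec.region.end, rec.region.strand) == (
            500, 900, "-")
        assert rec.attribute("donor_pos") == "900"
        assert rec.attribute("acceptor_pos") == "500"

    def test_cross_chromosome_junction_dropped(self):
        rows = [{"junction": "chr1:900:+,chr2:500:+", "raw_counts": "3"}]
        records, report = convert_rnaseq_spljxn(rows)
        assert records == [] and report.dropped == 1


class TestRnaseqv2Isoform:
    def test_chain_with_version_fallback(self, chain_store):
        rows = [{"isoform_id": "uc001aaa.3", "raw_count": "10",
                 "scaled_estimate": "1e-6", "normalized_count": "4.2"}]
        records, _ = convert_rnaseqv2_isoform(rows, chain_store)
        (rec,) = records
        assert rec.region == GenomicRegion("chr1", 1000, 2000, "+")
        assert rec.attribute("isoform_id") == "uc001aaa.3"
        assert rec.attribute("entrez_gene_id") == "100"

    def test_unresolvable_transcript_dropped(self, chain_store):
        rows = [{"isoform_id": "uc999zzz.1", "raw_count": "1",
                 "scaled_estimate": "0", "normalized_count": "0"}]
        records, report = convert_rnaseqv2_isoform(rows, chain_store)
        assert records == [] and report.dropped == 1
        assert report.misses[0].id_kind == "ucsc"

    def test_two_isoforms_share_gene_region(self, chain_store):
        chain_store.ucsc_to_entrez["uc001aab"] = 100
        rows = [{"isoform_id": i, "raw_count": "1", "scaled_estimate": "0",
                 "normalized_count": "0"}
                for i in ("uc001aaa.3", "uc001aab.1")]
        records, _ = convert_rnaseqv2_isoform(rows, chain_store)
        assert records[0].region == records[1].region
        assert (records[0].attribute("isoform_id")
                != records[1].attribute("isoform_id"))


def _fixture_files(cohort_root):
    """Yield (exp_type, subtype, path) over every generated source file."""
    for type_dir in sorted((cohort_root / "tcga_original" / "brca").iterdir()):
        if type_dir.name == "meta":
            continue
        subtypes = SUBTYPES[type_dir.name]
        for path in sorted(type_dir.glob("*.txt")):
            stem = path.name[:-4]
            subtype = None if subtypes == (None,) else stem.rpartition(".")[2]
            yield type_dir.name, subtype, path


class TestWholeFixtureProperties:
    def test_count_conservation(self, cohort_root, store):
        """rows_in == records_out + dropped for single-record types; the
        miRNA multi-locus expansion may only add records."""
        seen = 0
        for exp_type, subtype, path in _fixture_files(cohort_root):
            rows = read_source_file(path)
            _, report = get_converter(exp_type, subtype)(
                rows, store, source=str(path))
            assert report.rows_in == len(rows)
            if exp_type == "mirnaseq":
                assert report.records_out >= report.rows_in - report.dropped
            else:
                assert report.rows_in == report.records_out + report.dropped
            seen += 1
        assert seen > 0

    def test_schema_conformity_and_region_invariants(self, cohort_root, store):
        for exp_type, subtype, path in _fixture_files(cohort_root):
            schema = get_schema(exp_type, subtype)
            records, _ = get_converter(exp_type, subtype)(
                read_source_file(path), store, source=str(path))
            for rec in records:
                assert rec.conforms_to(schema)
                assert 1 <= rec.region.start <= rec.region.end
                assert rec.region.strand in "+-*"

    def test_conversion_is_deterministic(self, cohort_root, store):
        for exp_type, subtype, path in _fixture_files(cohort_root):
            schema = get_schema(exp_type, subtype)
            first, _ = get_converter(exp_type, subtype)(
                read_source_file(path), store)
            second, _ = get_converter(exp_type, subtype)(
                read_source_file(path), store)
            assert render_bed(first, schema) == render_bed(second, schema)

    def test_mandatory_fields_are_the_only_universal_columns(self):
        field_sets = [set(s.field_names) for s in SCHEMAS.values()]
        intersection = set.intersection(*field_sets)
        assert intersection == set(MANDATORY_FIELDS)
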