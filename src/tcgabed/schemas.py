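"""Registry of free-BED column schemas, one per (experiment type, subtype).

Each schema lists the four mandatory fields followed by the attribute tail
carried over from the original TCGA level-2/3 layout for that data type,
plus the ad-hoc donor/acceptor decomposition added for splice junctions.
The registry is the single authority consulted by converters (to order
attributes), serializers (to type values) and the ``header.schema`` writer.
"""

from __future__ import annotations

from .core import DataTypeSchema, MANDATORY_FIELDS
from .errors import SchemaError

_MANDATORY = (
    ("chrom", "string"),
    ("chromStart", "integer"),
    ("chromEnd", "integer"),
    ("strand", "char"),
)


def _schema(experiment_type: str, subtype: str | None,
            *attributes: tuple[str, str]) -> DataTypeSchema:
    return DataTypeSchema(
        experiment_type=experiment_type,
        subtype=subtype,
        columns=_MANDATORY + attributes,
    )


#: Attribute tails, keyed by (experiment type, subtype); ``None`` subtype
#: marks the types that have a single layout.
SCHEMAS: dict[tuple[str, str | None], DataTypeSchema] = {}


def register(schema: DataTypeSchema) -> DataTypeSchema:
    key = schema.key
    if key in SCHEMAS:
        raise SchemaError(f"schema already registered for {key}")
    SCHEMAS[key] = schema
    return schema


register(_schema(
    "cnv", None,
    ("num_probes", "integer"),
    ("segment_mean", "float"),
))

register(_schema(
    "dnamethylation", None,
    ("composite_element_ref", "string"),
    ("beta_value", "float"),
    ("gene_symbol", "string"),
))

# The 13 MAF columns carried into BED, after the coordinate/strand fields.
register(_schema(
    "dnaseq", None,
    ("hugo_symbol", "string"),
    ("entrez_gene_id", "integer"),
    ("variant_classification", "string"),
    ("variant_type", "string"),
    ("reference_allele", "string"),
    ("tumor_seq_allele1", "string"),
    ("tumor_seq_allele2", "string"),
    ("dbsnp_rs", "string"),
    ("tumor_sample_barcode", "string"),
    ("matched_norm_sample_barcode", "string"),
    ("mutation_status", "string"),
    ("sequencer", "string"),
    ("validation_status", "string"),
))

register(_schema(
    "mirnaseq", None,
    ("mirna_id", "string"),
    ("read_count", "integer"),
    ("reads_per_million_mirna_mapped", "float"),
    ("cross_mapped", "char"),
))

register(_schema(
    "rnaseq", "gene",
    ("entrez_gene_id", "integer"),
    ("gene_symbol", "string"),
    ("raw_counts", "integer"),
    ("median_length_normalized", "float"),
    ("rpkm", "float"),
))

register(_schema(
    "rnaseq", "exon",
    ("exon", "string"),
    ("raw_counts", "integer"),
    ("median_length_normalized", "float"),
    ("rpkm", "float"),
))

# Splice junctions carry the ad-hoc donor/acceptor decomposition so the
# original orientation survives the start<=end normalization of the region.
_SPLJXN_ATTRS = (
    ("donor_chrom", "string"),
    ("donor_pos", "integer"),
    ("acceptor_chrom", "string"),
    ("acceptor_pos", "integer"),
    ("raw_counts", "integer"),
)

register(_schema("rnaseq", "spljxn", *_SPLJXN_ATTRS))

register(_schema(
    "rnaseqv2", "gene",
    ("entrez_gene_id", "integer"),
    ("gene_symbol", "string"),
    ("raw_count", "float"),
    ("scaled_estimate", "float"),
    ("normalized_count", "float"),
))

register(_schema(
    "rnaseqv2", "exon",
    ("exon", "string"),
    ("raw_counts", "integer"),
    ("median_length_normalized", "float"),
    ("rpkm", "float"),
))

register(_schema("rnaseqv2", "spljxn", *_SPLJXN_ATTRS))

register(_schema(
    "rnaseqv2", "isoform",
    ("isoform_id", "string"),
    ("entrez_gene_id", "integer"),
    ("raw_count", "float"),
    ("scaled_estimate", "float"),
    ("normalized_count", "float"),
))


#: Subtypes per experiment type, in conversion order.  ``(None,)`` marks a
#: single-layout type.
SUBTYPES: dict[str, tuple[str | None, ...]] = {
    "cnv": (None,),
    "dnamethylation": (None,),
    "dnaseq": (None,),
    "mirnaseq": (None,),
    "rnaseq": ("gene", "exon", "spljxn"),
    "rnaseqv2": ("gene", "exon", "spljxn", "isoform"),
}


def get_schema(experiment_type: str, subtype: str | None = None) -> DataTypeSchema:
    try:
        return SCHEMAS[(experiment_type, subtype)]
    except KeyError:
        raise SchemaError(
            f"no schema registered for type {experiment_type!r}, subtype {subtype!r}"
        ) from None


def mandatory_field_intersection() -> set[str]:
    """Intersection of all registered schemas' field names.

    By construction this is exactly the four mandatory free-BED fields;
    exposed so the property can be measured rather than assumed.
    """
    field_sets = [set(s.field_names) for s in SCHEMAS.values()]
    out = set(field_sets[0])
    for fs in field_sets[1:]:
        out &= fs
    assert out >= set(MANDATORY_FIELDS)
    return out
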