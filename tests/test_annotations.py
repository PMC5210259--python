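"""Annotation tables, lookup chains and the persistent cache."""

from __future__ import annotations

import copy
import csv
import logging
import random

import pytest

from tcgabed.annotations import (
    AnnotationMiss,
    AnnotationStore,
    coords_by_entrez,
    coords_by_mirna,
    coords_by_ucsc,
    load_cache,
    load_store,
    save_store,
    strand_by_symbol,
)
from tcgabed.core import GenomicRegion
from tcgabed.errors import TableFormatError


def _write_tables(tmp_path, entrez_rows=(), symbol_rows=(), ucsc_rows=(),
                  mirna_rows=()):
    paths = {}
    specs = {
        "entrez_coords": ("entrez_id\tchrom\tstart\tend\tstrand", entrez_rows),
        "symbol_to_entrez": ("symbol\tentrez_id", symbol_rows),
        "ucsc_to_entrez": ("ucsc_id\tentrez_id", ucsc_rows),
        "mirna_coords": ("mirna_id\tchrom\tstart\tend\tstrand", mirna_rows),
    }
    for name, (header, rows) in specs.items():
        p = tmp_path / f"{name}.tsv"
        p.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        paths[name] = p
    return paths


@pytest.fixture
def small_store(tmp_path):
    paths = _write_tables(
        tmp_path,
        entrez_rows=["100\tchr1\t1000\t2000\t+"],
        symbol_rows=["GENE1\t100", "ORPHAN\t999"],
        ucsc_rows=["uc001aaa\t100"],
        mirna_rows=["hsa-mir-21\tchr17\t59841266\t59841337\t+",
                    "hsa-mir-9\tchr1\t100\t180\t+",
                    "hsa-mir-9\tchr2\t500\t580\t-"],
    )
    return load_store(paths)


class TestDirectLookups:
    def test_entrez_hit(self, small_store):
        assert coords_by_entrez(small_store, 100) == GenomicRegion(
            "chr1", 1000, 2000, "+")

    def test_entrez_miss(self, small_store):
        miss = coords_by_entrez(small_store, 4242)
        assert miss == AnnotationMiss("entrez", "4242", "entrez_coords")

    def test_mirna_single_locus(self, small_store):
        loci = coords_by_mirna(small_store, "hsa-mir-21")
        assert loci == [GenomicRegion("chr17", 59841266, 59841337, "+")]

    def test_mirna_two_loci_in_store_order(self, small_store):
        loci = coords_by_mirna(small_store, "hsa-mir-9")
        assert [r.chrom for r in loci] == ["chr1", "chr2"]

    def test_mirna_case_insensitive(self, small_store):
        assert (coords_by_mirna(small_store, "HSA-MIR-21")
                == coords_by_mirna(small_store, "hsa-mir-21"))


class TestChains:
    def test_symbol_to_strand(self, small_store):
        assert strand_by_symbol(small_store, "GENE1") == "+"

    def test_symbol_absent(self, small_store):
        miss = strand_by_symbol(small_store, "NOSUCH")
        assert miss == AnnotationMiss("symbol", "NOSUCH", "symbol_to_entrez")

    def test_symbol_without_coordinates(self, small_store):
        miss = strand_by_symbol(small_store, "ORPHAN")
        assert miss == AnnotationMiss("symbol", "ORPHAN", "entrez_coords")

    def test_ucsc_chain(self, small_store):
        assert coords_by_ucsc(small_store, "uc001aaa") == GenomicRegion(
            "chr1", 1000, 2000, "+")

    def test_ucsc_version_fallback(self, small_store):
        # table only holds the unversioned id
        assert coords_by_ucsc(small_store, "uc001aaa.3") == GenomicRegion(
            "chr1", 1000, 2000, "+")

    def test_ucsc_unknown(self, small_store):
        miss = coords_by_ucsc(small_store, "uc999zzz.1")
        assert miss == AnnotationMiss("ucsc", "uc999zzz.1", "ucsc_to_entrez")


def _random_tables(rng, n_keys):
    entrez, symbols, ucscs = [], [], []
    for i in range(n_keys):
        eid = 1000 + i
        if rng.random() < 0.9:  # 10% of ids deliberately lack coordinates
            strand = rng.choice("+-")
            start = rng.randint(1, 10 ** 6)
            entrez.append(f"{eid}\tchr{rng.randint(1, 22)}\t{start}"
                          f"\t{start + rng.randint(0, 10 ** 4)}\t{strand}")
        symbols.append(f"SYM{i}\t{eid}")
        ucscs.append(f"uc{i:06d}.{rng.randint(1, 5)}\t{eid}")
    return entrez, symbols, ucscs


class TestChainEquivalence:
    def test_against_brute_force_composition(self, tmp_path):
        """Chains must equal a two-step composition computed independently
        from the raw table files, for 1000 symbols and transcripts."""
        rng = random.Random(42)
        entrez, symbols, ucscs = _random_tables(rng, 1000)
        paths = _write_tables(tmp_path, entrez_rows=entrez,
                              symbol_rows=symbols, ucsc_rows=ucscs)
        store = load_store(paths)

        # independent oracle: plain csv reads of the same files
        def read(name):
            with open(paths[name], newline="", encoding="utf-8") as fh:
                rows = list(csv.reader(fh, delimiter="\t"))
            return rows[1:]

        raw_coords = {r[0]: (r[1], int(r[2]), int(r[3]), r[4])
                      for r in read("entrez_coords")}
        raw_symbols = {r[0]: r[1] for r in read("symbol_to_entrez")}
        raw_ucsc = {r[0]: r[1] for r in read("ucsc_to_entrez")}

        for symbol, eid in raw_symbols.items():
            expected = raw_coords.get(eid)
            got = strand_by_symbol(store, symbol)
            if expected is None:
                assert isinstance(got, AnnotationMiss)
            else:
                assert got == expected[3]

        for ucsc_id, eid in raw_ucsc.items():
            expected = raw_coords.get(eid)
            got = coords_by_ucsc(store, ucsc_id)
            if expected is None:
                assert isinstance(got, AnnotationMiss)
            else:
                assert (got.chrom, got.start, got.end, got.strand) == expected


class TestLoading:
    def test_empty_tables_empty_store(self, tmp_path):
        paths = _write_tables(tmp_path)
        store = load_store(paths)
        assert isinstance(coords_by_entrez(store, 1), AnnotationMiss)
        assert isinstance(strand_by_symbol(store, "X"), AnnotationMiss)
        assert isinstance(coords_by_mirna(store, "hsa-mir-1"), AnnotationMiss)

    def test_short_line_cites_line_number(self, tmp_path):
        paths = _write_tables(tmp_path, entrez_rows=[
            "100\tchr1\t1000\t2000\t+",
            "101\tchr1\t5000",  # 3 of 5 columns
        ])
        with pytest.raises(TableFormatError, match="line 3"):
            load_store(paths)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "entrez_coords.tsv"
        p.write_text("gene\tchrom\tstart\tend\tstrand\n", encoding="utf-8")
        with pytest.raises(TableFormatError, match="line 1"):
            load_store({"entrez_coords": p})

    def test_duplicate_key_last_wins_with_warning(self, tmp_path, caplog):
        paths = _write_tables(tmp_path, entrez_rows=[
            "100\tchr1\t1000\t2000\t+",
            "100\tchr2\t10\t20\t-",
        ])
        with caplog.at_level(logging.WARNING, logger="tcgabed.annotations"):
            store = load_store(paths)
        assert coords_by_entrez(store, 100) == GenomicRegion("chr2", 10, 20, "-")
        assert any("duplicate" in r.message for r in caplog.records)


def _random_store(rng, n_keys) -> AnnotationStore:
    store = AnnotationStore()
    for i in range(n_keys):
        region = GenomicRegion(f"chr{rng.randint(1, 22)}",
                               (s := rng.randint(1, 10 ** 7)),
                               s + rng.randint(0, 10 ** 4),
                               rng.choice("+-"))
        store.entrez_coords[1000 + i] = region
        store.symbol_to_entrez[f"SYM{i}"] = 1000 + i
        store.ucsc_to_entrez[f"uc{i:06d}"] = 1000 + i
        store.mirna_coords.setdefault(f"hsa-mir-{i % 400}", []).append(region)
    return store


class TestCache:
    def test_round_trip_preserves_every_mapping(self, tmp_path):
        store = _random_store(random.Random(5), 1000)
        cache = tmp_path / "cache.tsv"
        save_store(store, cache)
        reloaded = load_cache(cache)
        assert reloaded.entrez_coords == store.entrez_coords
        assert reloaded.symbol_to_entrez == store.symbol_to_entrez
        assert reloaded.ucsc_to_entrez == store.ucsc_to_entrez
        assert reloaded.mirna_coords == store.mirna_coords

    def test_reload_is_bit_exact(self, tmp_path):
        store = _random_store(random.Random(6), 100)
        first, second = tmp_path / "a.tsv", tmp_path / "b.tsv"
        save_store(store, first)
        save_store(load_cache(first), second)
        assert first.read_bytes() == second.read_bytes()

    def test_lookups_equal_before_and_after_round_trip(self, small_store,
                                                       tmp_path):
        cache = tmp_path / "cache.tsv"
        save_store(small_store, cache)
        reloaded = load_cache(cache)
        for probe in ("GENE1", "ORPHAN", "NOSUCH"):
            assert (strand_by_symbol(small_store, probe)
                    == strand_by_symbol(reloaded, probe))


class TestPurity:
    def test_lookups_do_not_mutate_store(self, small_store):
        before = copy.deepcopy(small_store)
        coords_by_entrez(small_store, 100)
        coords_by_entrez(small_store, 31337)
        strand_by_symbol(small_store, "GENE1")
        strand_by_symbol(small_store, "NOSUCH")
        coords_by_ucsc(small_store, "uc001aaa.9")
        coords_by_mirna(small_store, "HSA-MIR-21")
        coords_by_mirna(small_store, "hsa-mir-404")
        assert small_store.entrez_coords == before.entrez_coords
        assert small_store.symbol_to_entrez == before.symbol_to_entrez
        assert small_store.ucsc_to_entrez == before.ucsc_to_entrez
        assert small_store.mirna_coords == before.mirna_coords
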