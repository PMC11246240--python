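import io

import pytest
from hypothesis import given, settings, strategies as st

from paleodup.genome_io import (
    GeneCatalog,
    HomologPair,
    ParseError,
    read_cds_sequences,
    read_gene_models,
    read_homolog_pairs,
    write_gff3,
    write_results_tables,
)

import pandas as pd


def gff3(lines):
    return io.StringIO("##gff-version 3\n" + "\n".join(lines) + "\n")


class TestReadGeneModels:
    def test_single_record_gets_rank_zero(self):
        cat = read_gene_models(gff3(["chr1\t.\tgene\t100\t500\t.\t+\t.\tID=g1"]))
        g = cat["g1"]
        assert (g.chromosome, g.start, g.end, g.rank) == ("chr1", 100, 500, 0)

    def test_ranks_follow_start_order_not_file_order(self):
        cat = read_gene_models(
            gff3(
                [
                    "chr1\t.\tgene\t500\t900\t.\t+\t.\tID=late",
                    "chr1\t.\tgene\t100\t300\t.\t-\t.\tID=early",
                ]
            )
        )
        assert cat["late"].rank == 1
        assert cat["early"].rank == 0

    def test_short_line_raises_with_line_number(self):
        with pytest.raises(ParseError, match="line 1"):
            read_gene_models(io.StringIO("chr1\t.\tgene\t1\t5\t.\t+\t."))

    def test_duplicate_id_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            read_gene_models(
                gff3(
                    [
                        "chr1\t.\tgene\t1\t5\t.\t+\t.\tID=g1",
                        "chr1\t.\tgene\t9\t12\t.\t+\t.\tID=g1",
                    ]
                )
            )

    def test_roundtrip_preserves_ranks_and_coordinates(self, tmp_path):
        cat = read_gene_models(
            gff3(
                [
                    "chr2\t.\tgene\t50\t80\t.\t-\t.\tID=b",
                    "chr1\t.\tgene\t10\t40\t.\t+\t.\tID=a",
                    "chr1\t.\tgene\t100\t130\t.\t+\t.\tID=c",
                ]
            )
        )
        path = tmp_path / "out.gff3"
        write_gff3(cat, path)
        again = read_gene_models(str(path))
        for g in cat:
            h = again[g.gene_id]
            assert (g.chromosome, g.start, g.end, g.strand, g.rank) == (
                h.chromosome, h.start, h.end, h.strand, h.rank,
            )

    @given(
        st.lists(
            st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(1, 10_000)),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_rank_multiset_is_complete_per_chromosome(self, placements):
        records = [
            (f"g{i}", chrom, start, start + 10, "+")
            for i, (chrom, start) in enumerate(placements)
        ]
        cat = GeneCatalog.from_unranked(records)
        for chrom in cat.chromosomes:
            ranks = [g.rank for g in cat.genes_on(chrom)]
            assert sorted(ranks) == list(range(len(ranks)))


def blast_row(q, s, evalue="1e-50", bits="200"):
    return f"{q}\t{s}\t95.0\t300\t10\t0\t1\t300\t1\t300\t{evalue}\t{bits}"


class TestReadHomologPairs:
    def test_reciprocal_rows_collapse_keeping_best_bitscore(self):
        pairs, dropped = read_homolog_pairs(
            io.StringIO(blast_row("a", "b", bits="100") + "\n" + blast_row("b", "a", bits="120"))
        )
        assert dropped == 0
        assert pairs == [HomologPair("a", "b", 120.0, 1e-50)]

    def test_self_hits_and_threshold_failures_dropped(self):
        stream = io.StringIO(
            "\n".join(
                [
                    blast_row("a", "a"),
                    blast_row("a", "b", evalue="1e-3"),
                    blast_row("a", "c"),
                ]
            )
        )
        pairs, dropped = read_homolog_pairs(stream, max_evalue=1e-5)
        assert [p.key for p in pairs] == [("a", "c")]
        assert dropped == 2

    def test_non_numeric_bitscore_names_line(self):
        with pytest.raises(ParseError, match="line 1"):
            read_homolog_pairs(io.StringIO(blast_row("a", "b", bits="high")))

    def test_canonicalization_is_idempotent(self):
        rows = [blast_row("b", "a"), blast_row("c", "a"), blast_row("a", "c", bits="90")]
        pairs, _ = read_homolog_pairs(io.StringIO("\n".join(rows)))
        rewritten = "\n".join(
            f"{p.gene_a}\t{p.gene_b}\t95.0\t300\t10\t0\t1\t300\t1\t300\t{p.evalue}\t{p.bitscore}"
            for p in pairs
        )
        again, _ = read_homolog_pairs(io.StringIO(rewritten))
        assert {p.key for p in again} == {p.key for p in pairs}


class TestReadCds:
    @pytest.mark.parametrize(
        "record,expected_flags",
        [
            (">g1\nATGAAATAA", []),
            (">g1\nATGAAAA", ["frame"]),
            (">g1\nATGTAAAAATAA", ["internal_stop"]),
        ],
    )
    def test_flagging(self, record, expected_flags):
        seqs, flags = read_cds_sequences(io.StringIO(record))
        assert "g1" in seqs
        assert flags.get("g1", []) == expected_flags

    def test_empty_stream_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            read_cds_sequences(io.StringIO(""))

    def test_sequences_are_uppercased(self):
        seqs, _ = read_cds_sequences(io.StringIO(">g1\natgaaataa"))
        assert seqs["g1"] == "ATGAAATAA"


class TestWriteResultsTables:
    def test_empty_gene_modes_yields_header_only(self, tmp_path):
        paths = write_results_tables({"gene_modes": pd.DataFrame()}, tmp_path)
        content = open(paths[0]).read()
        assert content == "gene_id\tmode\tepoch\tis_pathway\n"

    def test_same_input_twice_is_byte_identical(self, tmp_path):
        df = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "mode": ["WGD", "TD", "singleton"],
             "epoch": [1, "", ""], "is_pathway": [1, 0, 0]}
        )
        p1 = write_results_tables({"gene_modes": df}, tmp_path / "x")[0]
        p2 = write_results_tables({"gene_modes": df}, tmp_path / "y")[0]
        assert open(p1, "rb").read() == open(p2, "rb").read()
        assert open(p1).read().count("\n") == 4  # header + 3 data rows
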