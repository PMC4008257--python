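"""Supermatrix container, I/O, cleaning, codon handling, concatenation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phylotier.seqdata import (
    AlignmentError,
    Partition,
    PartitionedAlignment,
    check_reading_frame,
    clean_alignment,
    concatenate,
    extract_partition,
    missing_fraction,
    parse_partition_table,
    read_alignment,
    split_codon_positions,
    write_alignment,
    write_partition_table,
)


class TestIO:
    def test_fasta_identity_read(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">A\nACGT\n>B\nACGT\n")
        aln = read_alignment(p)
        assert aln.n_taxa == 2 and aln.n_sites == 4
        assert len(aln.partitions) == 1
        assert aln.row("A") == "ACGT"

    def test_nexus_charsets_converted_to_zero_based(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=10;\n"
            "FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n"
            "A ACGTACGTAC\nB ACGTACGTAC\n;\nEND;\n"
            "BEGIN SETS;\nCHARSET r12S = 1-4;\nCHARSET RAG1 = 5-10;\nEND;\n"
        )
        aln = read_alignment(p)
        by_name = {q.name: set(q.sites) for q in aln.partitions}
        assert by_name["r12S"] == set(range(0, 4))
        assert by_name["RAG1"] == set(range(4, 10))

    @pytest.mark.parametrize("fmt", ["fasta", "phylip", "nexus"])
    def test_round_trip(self, tmp_path, fmt):
        aln = PartitionedAlignment(
            ["tax1", "tax2", "tax3"],
            ["ACGT-?NA", "ACGTACGT", "AAAAAAAA"],
            [Partition("g1", tuple(range(4))), Partition("g2", tuple(range(4, 8)))],
        )
        p = tmp_path / f"x.{fmt}"
        write_alignment(aln, p, fmt)
        back = read_alignment(p, fmt)
        assert back.taxa == aln.taxa
        assert (back.matrix == aln.matrix).all()

    def test_ragged_rows_error_names_taxon(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">A\nACGT\n>B\nACG\n")
        with pytest.raises(AlignmentError, match="B"):
            read_alignment(p)

    def test_duplicate_taxon_error(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            PartitionedAlignment(["A", "A"], ["AC", "AC"])

    def test_partition_out_of_range(self):
        with pytest.raises(AlignmentError, match="out of range"):
            PartitionedAlignment(["A"], ["ACG"], [Partition("g", (0, 5))])

    def test_raxml_partition_table(self):
        parts = parse_partition_table(
            "DNA, RAG1_pos1 = 12-908\\3\nDNA, r16S = 1-11\n"
        )
        by_name = {p.name: p for p in parts}
        assert list(by_name["RAG1_pos1"].sites)[:3] == [11, 14, 17]
        assert set(by_name["r16S"].sites) == set(range(0, 11))
        assert by_name["r16S"].origin == "mitochondrial"

    def test_tabular_partition_table_round_trip(self):
        parts = [
            Partition("cytb", tuple(range(10)), origin="mitochondrial",
                      coding=True, frame=0, genetic_code="vertebrate-mitochondrial"),
            Partition("nuc1", tuple(range(10, 16)), origin="nuclear"),
        ]
        back = parse_partition_table(write_partition_table(parts))
        assert back == parts


class TestClean:
    def test_no_missing_unchanged(self):
        aln = PartitionedAlignment(["A", "B"], ["ACGT", "TGCA"])
        out, rep = clean_alignment(aln)
        assert out == aln and not rep.removed_taxa and rep.n_removed_columns == 0

    def test_removes_all_missing_row_and_column(self):
        aln = PartitionedAlignment(
            ["A", "B", "C"], ["AC-GTA", "AC-GTC", "??-???"]
        )
        out, rep = clean_alignment(aln)
        assert (out.n_taxa, out.n_sites) == (2, 5)
        assert rep.removed_taxa == ["C"] and rep.removed_columns == [2]

    def test_idempotent(self):
        aln = PartitionedAlignment(["A", "B", "C"], ["AC-GTA", "AC-GTC", "??????"])
        once, _ = clean_alignment(aln)
        twice, rep2 = clean_alignment(once)
        assert once == twice and not rep2.removed_taxa

    def test_never_removes_column_with_determinate_base(self):
        aln = PartitionedAlignment(["A", "B"], ["A???", "????"])
        out, rep = clean_alignment(aln)
        assert 0 not in rep.removed_columns and out.n_sites == 1

    def test_partitions_reindexed(self):
        aln = PartitionedAlignment(
            ["A", "B"], ["A-CG", "A-CG"],
            [Partition("g1", (0, 1)), Partition("g2", (2, 3))],
        )
        out, _ = clean_alignment(aln)
        assert [tuple(p.sites) for p in out.partitions] == [(0,), (1, 2)]

    def test_empty_after_cleaning_errors(self):
        aln = PartitionedAlignment(["A", "B"], ["??", "--"])
        with pytest.raises(AlignmentError, match="empty"):
            clean_alignment(aln)


class TestCodons:
    def test_frame0_six_sites(self):
        p = Partition("g", tuple(range(6)), coding=True, frame=0)
        aln = PartitionedAlignment(["A"], ["ACGTAC"], [p])
        out = split_codon_positions(aln, p)
        assert [set(q.sites) for q in out] == [{0, 3}, {1, 4}, {2, 5}]

    def test_frame1_seven_sites(self):
        p = Partition("g", tuple(range(7)), coding=True, frame=1)
        aln = PartitionedAlignment(["A"], ["ACGTACG"], [p])
        out = {q.name[-1]: set(q.sites) for q in split_codon_positions(aln, p)}
        # positions per site 0..6 are 3,1,2,3,1,2,3
        assert out == {"1": {1, 4}, "2": {2, 5}, "3": {0, 3, 6}}

    @given(length=st.integers(1, 30), frame=st.integers(0, 2))
    def test_positions_partition_parent_sites(self, length, frame):
        p = Partition("g", tuple(range(length)), coding=True, frame=frame)
        aln = PartitionedAlignment(["A"], ["A" * length], [p])
        out = split_codon_positions(aln, p)
        union = [s for q in out for s in q.sites]
        assert sorted(union) == list(range(length))
        assert len(union) == len(set(union))

    def test_noncoding_rejected(self):
        p = Partition("g", (0, 1, 2))
        aln = PartitionedAlignment(["A"], ["ACG"], [p])
        with pytest.raises(AlignmentError, match="not coding"):
            split_codon_positions(aln, p)

    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGAAACCC", 0), ("ATGTAAATG", 1), ("AT?TAAATG", 1)],
    )
    def test_stop_codon_scan(self, seq, expected):
        p = Partition("g", tuple(range(9)), coding=True, frame=0)
        aln = PartitionedAlignment(["A"], [seq], [p])
        assert check_reading_frame(aln, p)["A"] == expected

    def test_mitochondrial_stops(self):
        p = Partition("g", tuple(range(6)), coding=True, frame=0,
                      genetic_code="vertebrate-mitochondrial")
        aln = PartitionedAlignment(["A"], ["AGAAGG"], [p])
        assert check_reading_frame(aln, p)["A"] == 2


class TestMissingAndConcat:
    def test_missing_fraction_examples(self):
        assert missing_fraction(PartitionedAlignment(["A", "B"], ["???", "???"])) == 1.0
        aln = PartitionedAlignment(["A", "B"], ["AC?T", "-CGT"])
        assert missing_fraction(aln) == 0.25

    def test_missing_symbols_configurable(self):
        aln = PartitionedAlignment(["A"], ["N-?A"])
        assert missing_fraction(aln, missing={"?"}) == 0.25

    def test_concat_identical_taxa_no_fill(self):
        g1 = PartitionedAlignment(["A", "B"], ["ACG", "TGC"],
                                  [Partition("g1", (0, 1, 2))])
        g2 = PartitionedAlignment(["A", "B"], ["TT", "AA"],
                                  [Partition("g2", (0, 1))])
        out = concatenate([g1, g2])
        assert out.n_sites == 5 and missing_fraction(out) == 0.0
        assert out.row("A") == "ACGTT"

    def test_concat_fills_absent_taxa(self):
        g1 = PartitionedAlignment(["t1", "t2"], ["ACG", "TGC"],
                                  [Partition("gA", (0, 1, 2))])
        g2 = PartitionedAlignment(["t2", "t3"], ["TT", "AA"],
                                  [Partition("gB", (0, 1))])
        out = concatenate([g1, g2])
        assert out.taxa == ["t1", "t2", "t3"]
        assert out.row("t1") == "ACG??"
        assert out.row("t3") == "???AA"
        assert missing_fraction(out) >= max(
            missing_fraction(g1), missing_fraction(g2)
        )

    def test_concat_conflict_error(self):
        g1 = PartitionedAlignment(["A"], ["ACG"], [Partition("g", (0, 1, 2))])
        g2 = PartitionedAlignment(["A"], ["TTT"], [Partition("g", (0, 1, 2))])
        with pytest.raises(AlignmentError, match="conflicting"):
            concatenate([g1, g2])

    def test_concat_then_extract_recovers_inputs(self):
        rng = np.random.default_rng(3)
        genes = []
        for name, taxa in [("gA", ["t1", "t2", "t3"]), ("gB", ["t2", "t3", "t4"])]:
            mat = rng.choice(list("ACGT"), size=(3, 7))
            genes.append(PartitionedAlignment(taxa, ["".join(r) for r in mat],
                                              [Partition(name, tuple(range(7)))]))
        out = concatenate(genes)
        for g in genes:
            sub = extract_partition(out, g.partitions[0].name)
            for t in g.taxa:
                assert sub.row(t) == g.row(t)
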