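"""CDS extraction: FASTA/GFF3 reading, transcript choice, assembly,
filtering, and the split-codon rule."""

import pytest

from scubkit import genome_io
from scubkit.genome_io import (
    CdsRecord,
    FastaParseError,
    TranscriptModel,
    assemble_cds,
    assign_codons_to_exons,
    assign_subgenome,
    filter_cds,
    read_annotation,
    read_genome,
    select_primary_transcript,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGenome:
    def test_reads_records_and_uppercases(self, tmp_path):
        p = write(tmp_path, "g.fa", ">chr1A\nACGTACGTACGTacgtACGTACGTACGTAC\n>chr1B\n" + "A" * 30 + "\n")
        genome = read_genome(p)
        assert set(genome) == {"chr1A", "chr1B"}
        assert genome["chr1A"][12:16] == "ACGT"
        assert genome["chr1A"] == genome["chr1A"].upper()

    def test_duplicate_identifier_is_error(self, tmp_path):
        p = write(tmp_path, "g.fa", ">c1\nACGT\n>c1\nACGT\n")
        with pytest.raises(FastaParseError, match="c1"):
            read_genome(p)

    def test_non_iupac_character_names_record(self, tmp_path):
        p = write(tmp_path, "g.fa", ">weird\nAC-GT\n")
        with pytest.raises(FastaParseError, match="weird"):
            read_genome(p)


GFF_HEADER = "##gff-version 3\n"


class TestReadAnnotation:
    def test_plus_strand_two_cds(self, tmp_path):
        p = write(
            tmp_path, "a.gff3",
            GFF_HEADER
            + "c\tsrc\tgene\t100\t220\t.\t+\t.\tID=g1\n"
            + "c\tsrc\tmRNA\t100\t220\t.\t+\t.\tID=t1;Parent=g1\n"
            + "c\tsrc\tCDS\t100\t111\t.\t+\t0\tParent=t1\n"
            + "c\tsrc\tCDS\t200\t211\t.\t+\t0\tParent=t1\n",
        )
        genes = read_annotation(p)
        (t,) = genes["g1"]
        assert t.cds_segments == [(100, 111), (200, 211)]
        assert t.strand == "+"

    def test_minus_strand_orders_five_prime_first(self, tmp_path):
        p = write(
            tmp_path, "a.gff3",
            GFF_HEADER
            + "c\tsrc\tgene\t100\t220\t.\t-\t.\tID=g1\n"
            + "c\tsrc\tmRNA\t100\t220\t.\t-\t.\tID=t1;Parent=g1\n"
            + "c\tsrc\tCDS\t100\t111\t.\t-\t0\tParent=t1\n"
            + "c\tsrc\tCDS\t200\t211\t.\t-\t0\tParent=t1\n",
        )
        (t,) = read_annotation(p)["g1"]
        assert t.cds_segments == [(200, 211), (100, 111)]

    def test_cds_with_unresolvable_parent_is_skipped(self, tmp_path):
        p = write(
            tmp_path, "a.gff3",
            GFF_HEADER
            + "c\tsrc\tgene\t1\t50\t.\t+\t.\tID=g1\n"
            + "c\tsrc\tmRNA\t1\t50\t.\t+\t.\tID=t1;Parent=g1\n"
            + "c\tsrc\tCDS\t1\t12\t.\t+\t0\tParent=t1\n"
            + "c\tsrc\tCDS\t20\t31\t.\t+\t0\tParent=ghost\n",
        )
        (t,) = read_annotation(p)["g1"]
        assert t.cds_segments == [(1, 12)]

    def test_gene_level_cds_becomes_single_transcript(self, tmp_path):
        p = write(
            tmp_path, "a.gff3",
            GFF_HEADER
            + "c\tsrc\tgene\t1\t50\t.\t+\t.\tID=g1\n"
            + "c\tsrc\tCDS\t1\t12\t.\t+\t0\tParent=g1\n",
        )
        (t,) = read_annotation(p)["g1"]
        assert t.transcript_id == "g1"
        assert t.cds_segments == [(1, 12)]


class TestSelectPrimaryTranscript:
    @staticmethod
    def model(tid, rank):
        return TranscriptModel("g", tid, "c", "+", [(1, 3)], rank)

    def test_smallest_file_rank_wins(self):
        chosen = select_primary_transcript([self.model("t7", 7), self.model("t3", 3)])
        assert chosen.transcript_id == "t3"

    def test_single_transcript_identity(self):
        t = self.model("only", 5)
        assert select_primary_transcript([t]) is t

    def test_tie_broken_lexicographically(self):
        chosen = select_primary_transcript([self.model("tB", 1), self.model("tA", 1)])
        assert chosen.transcript_id == "tA"


class TestAssembleCds:
    def test_plus_strand_identity_slice(self):
        t = TranscriptModel("g", "t", "c", "+", [(1, 9)], 0)
        rec = assemble_cds(t, {"c": "ATGAAATAGCCC"})
        assert rec.cds_sequence == "ATGAAATAG"
        assert rec.segment_lengths == [9]

    def test_minus_strand_reverse_complement(self):
        t = TranscriptModel("g", "t", "c", "-", [(1, 9)], 0)
        rec = assemble_cds(t, {"c": "CTATTTCAT"})
        assert rec.cds_sequence == "ATGAAATAG"

    def test_two_segment_concatenation(self):
        t = TranscriptModel("g", "t", "c", "+", [(1, 4), (6, 10)], 0)
        rec = assemble_cds(t, {"c": "ATGGCAAATAG"})
        assert rec.cds_sequence == "ATGG" + "AAATA"
        assert rec.segment_lengths == [4, 5]

    def test_out_of_bounds_segment_rejected(self):
        t = TranscriptModel("g", "t", "c", "+", [(1, 99)], 0)
        rec = assemble_cds(t, {"c": "ATGAAATAG"})
        assert rec.status == "rejected"
        assert rec.reason == "coords"


def make_record(seq, lengths=None):
    return CdsRecord(
        gene_id="g", transcript_id="t", chromosome="c",
        cds_sequence=seq, segment_lengths=lengths or [len(seq)],
    )


class TestFilterCds:
    @pytest.mark.parametrize(
        "seq,status,reason",
        [
            ("ATGGCTTAA", "accepted", None),
            ("ATGGCTTA", "rejected", "length"),
            ("ATGGNTTAA", "rejected", "ambiguous_base"),
            ("ATGGRTTAA", "rejected", "ambiguous_base"),
            ("TTGGCTTAA", "rejected", "start_codon"),
            ("ATGGCTTGC", "rejected", "stop_codon"),
        ],
    )
    def test_four_rules(self, seq, status, reason):
        rec = filter_cds(make_record(seq))
        assert (rec.status, rec.reason) == (status, reason)

    def test_idempotent(self):
        rec = filter_cds(make_record("ATGGCTTA"))
        again = filter_cds(rec)
        assert (again.status, again.reason) == ("rejected", "length")

    def test_internal_stop_not_rejected(self):
        # internal stops are not one of the four filters
        rec = filter_cds(make_record("ATGTAAGCTTAA"))
        assert rec.accepted


class TestAssignCodonsToExons:
    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ([4, 8], [1, 2, 2, 2]),   # split after 1st nt -> downstream
            ([5, 7], [1, 1, 2, 2]),   # split after 2nd nt -> upstream
            ([6, 6], [1, 1, 2, 2]),   # clean boundary
        ],
    )
    def test_split_rule(self, lengths, expected):
        rec = make_record("ATGGCTGCTTAA", lengths)
        filter_cds(rec)
        assert assign_codons_to_exons(rec) == expected

    def test_inconsistent_lengths_is_internal_error(self):
        rec = make_record("ATGGCTGCTTAA", [4, 4])
        filter_cds(rec)
        rec.segment_lengths = [4, 4]
        with pytest.raises(RuntimeError):
            assign_codons_to_exons(rec)


class TestAssignSubgenome:
    @pytest.mark.parametrize(
        "name,expected",
        [("3B", "B"), ("chr1A", "A"), ("chr7D", "D"), ("scaffold_1172", "unassigned")],
    )
    def test_default_rule(self, name, expected):
        assert assign_subgenome(name) == expected

    def test_custom_rule_takes_precedence(self):
        assert assign_subgenome("LG04", rule={r"^LG0[1-7]": "A"}) == "A"


class TestExtractionAgainstTruth:
    def test_every_gene_recovered_exactly(self, extracted):
        """Both strands round-trip through FASTA + GFF3 to the exact CDS."""
        genome, records = extracted
        accepted = {r.gene_id: r for r in records if r.accepted}
        assert len(accepted) == len(genome.genes)
        for gene in genome.genes:
            rec = accepted[gene.gene_id]
            assert rec.cds_sequence == gene.cds_sequence
            assert rec.segment_lengths == gene.segment_lengths
            assert rec.codon_exon_index == gene.codon_exon_index

    def test_conservation_invariants(self, extracted):
        _, records = extracted
        for rec in records:
            if rec.accepted:
                assert sum(rec.segment_lengths) == len(rec.cds_sequence)
                assert len(rec.codon_exon_index) == len(rec.cds_sequence) // 3
                assert rec.codon_exon_index == sorted(rec.codon_exon_index)

    def test_exon_pooling_preserves_codon_content(self, extracted):
        """Assignment never alters codon content: pooling codons over exons
        reproduces the codon sequence of the whole CDS as a multiset."""
        from collections import Counter

        _, records = extracted
        for rec in records:
            if not rec.accepted:
                continue
            pooled = Counter()
            for codon, exon in zip(rec.codons, rec.codon_exon_index):
                assert 1 <= exon <= rec.n_exons
                pooled[codon] += 1
            assert pooled == Counter(rec.codons)
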