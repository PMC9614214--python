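"""Codon counting, SCUB frequencies, RSCU, CAI and ENC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scubkit import codon_core as cc
from scubkit.codon_core import CodonCountTable
from scubkit.genetic_code import AA_TO_CODONS, SC_AMINO_ACIDS, SC_CODONS
from scubkit.genome_io import CdsRecord, filter_cds


def record(seq):
    rec = CdsRecord("g", "t", "c", seq, [len(seq)])
    return filter_cds(rec)


class TestCountCodons:
    def test_direct_tally_and_additivity(self):
        rec = record("ATGGCTTAA")
        one = cc.count_codons([rec])
        assert (one["ATG"], one["GCT"], one["TAA"]) == (1, 1, 1)
        assert one.sc_total == 1
        two = cc.count_codons([rec, rec])
        assert all(two[c] == 2 * one[c] for c in one.counts)
        assert (one + one).counts == two.counts

    def test_empty_stream_gives_zero_table(self):
        table = cc.count_codons([])
        assert table.total == 0

    def test_unaccepted_record_is_error(self):
        rec = CdsRecord("g", "t", "c", "ATGTA", [5])
        with pytest.raises(ValueError):
            cc.count_codons([rec])


class TestCodonFrequencies:
    def test_sc59_single_codon(self):
        table = cc.count_codons([record("ATGGCTTAA")])
        assert cc.codon_frequencies(table, "sc59")["GCT"] == 1.0

    def test_nonstop61_denominator_is_all_codons(self):
        table = cc.count_codons([record("ATGGCTTAA")])
        freqs = cc.codon_frequencies(table, "nonstop61")
        assert freqs["ATG"] == pytest.approx(1 / 3)
        assert freqs["GCT"] == pytest.approx(1 / 3)
        assert "TAA" not in freqs

    def test_all64_sums_to_one(self):
        table = cc.count_codons([record("ATGGCTGCAGGTTAA")])
        assert sum(cc.codon_frequencies(table, "all64").values()) == pytest.approx(1.0)

    def test_zero_table_is_undefined(self):
        freqs = cc.codon_frequencies(CodonCountTable(), "sc59")
        assert all(math.isnan(v) for v in freqs.values())


class TestPerAaScubRatio:
    def test_ala_ratio(self):
        t = CodonCountTable(counts={"GCA": 1, "GCT": 1, "GCC": 2, "GCG": 2})
        assert cc.per_aa_scub_ratio(t)["A"] == pytest.approx(2.0)

    def test_ile_ratio(self):
        t = CodonCountTable(counts={"ATT": 2, "ATA": 2, "ATC": 1})
        assert cc.per_aa_scub_ratio(t)["I"] == pytest.approx(0.25)

    def test_zero_denominator_is_undefined(self):
        t = CodonCountTable(counts={"GCC": 3})
        assert math.isnan(cc.per_aa_scub_ratio(t)["A"])


class TestScubProfile:
    def test_hand_tally(self):
        t = CodonCountTable(counts={"GCA": 1, "GCT": 2, "GCC": 3, "GCG": 4})
        p = cc.scub_profile(t)
        assert p.ending_freq == pytest.approx({"A": 0.1, "T": 0.2, "C": 0.3, "G": 0.4})
        assert p.at_cg_ratio == pytest.approx(3 / 7)
        assert sum(p.ending_freq.values()) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_counts_reflect_code_composition(self):
        """Uniform usage over the 59 SCs: ending frequencies equal the
        genetic code's own third-base composition of the SC set."""
        t = CodonCountTable(counts={c: 7 for c in SC_CODONS})
        p = cc.scub_profile(t)
        for b in "ATCG":
            expected = sum(1 for c in SC_CODONS if c[2] == b) / 59
            assert p.ending_freq[b] == pytest.approx(expected)

    def test_degenerate_single_codon(self):
        p = cc.scub_profile(CodonCountTable(counts={"GAG": 5}))
        assert p.ending_freq["G"] == 1.0
        assert p.at_cg_ratio == 0.0

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            cc.scub_profile(CodonCountTable())


class TestRscu:
    def test_hand_formula(self):
        t = CodonCountTable(counts={"GCA": 10, "GCT": 20, "GCC": 30, "GCG": 40})
        values = cc.rscu(t)
        assert values["GCG"] == pytest.approx(40 / 25)
        assert values["GCA"] == pytest.approx(10 / 25)

    def test_equal_counts_give_unity(self):
        t = CodonCountTable(counts={c: 5 for c in AA_TO_CODONS["L"]})
        assert all(cc.rscu(t)[c] == pytest.approx(1.0) for c in AA_TO_CODONS["L"])

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=59, max_size=59))
    def test_family_mean_is_one(self, counts):
        t = CodonCountTable(counts=dict(zip(SC_CODONS, counts)))
        values = cc.rscu(t)
        for aa in SC_AMINO_ACIDS:
            codons = AA_TO_CODONS[aa]
            if sum(t[c] for c in codons) > 0:
                assert np.mean([values[c] for c in codons]) == pytest.approx(
                    1.0, abs=1e-9
                )


class TestReferenceWeightsAndCai:
    def test_weights_normalized_by_family_max(self):
        t = CodonCountTable(counts={"TTT": 1, "TTC": 4})
        w = cc.reference_weights(t)
        assert w["TTC"] == pytest.approx(1.0)
        assert w["TTT"] == pytest.approx(0.25)

    def test_uniform_family_all_one(self):
        t = CodonCountTable(counts={"GGT": 3, "GGC": 3, "GGA": 3, "GGG": 3})
        w = cc.reference_weights(t)
        assert all(w[c] == pytest.approx(1.0) for c in AA_TO_CODONS["G"])

    def test_unobserved_codon_gets_floor(self):
        t = CodonCountTable(counts={"GGT": 5})
        w = cc.reference_weights(t)
        assert w["GGT"] == pytest.approx(1.0)
        assert w["GGC"] == pytest.approx(0.01)

    def test_cai_hand_values(self):
        gene = CodonCountTable(counts={"GCA": 1, "GCG": 1})
        res = cc.cai(gene, {"GCA": 0.25, "GCG": 1.0})
        assert res.value == pytest.approx(0.5)
        assert res.codons_used == 2

    def test_cai_skips_undefined_weights(self):
        gene = CodonCountTable(counts={"GCA": 1, "TTT": 1})
        res = cc.cai(gene, {"GCA": 1.0, "TTT": math.nan})
        assert res.value == pytest.approx(1.0)
        assert res.codons_used == 1

    def test_cai_scale_invariant(self):
        w = {"GCA": 0.3, "GCG": 0.9, "TTT": 0.5}
        g1 = CodonCountTable(counts={"GCA": 2, "GCG": 3, "TTT": 1})
        g2 = CodonCountTable(counts={"GCA": 4, "GCG": 6, "TTT": 2})
        assert cc.cai(g1, w).value == pytest.approx(cc.cai(g2, w).value)

    def test_cai_without_usable_codons_is_error(self):
        with pytest.raises(ValueError):
            cc.cai(CodonCountTable(counts={"ATG": 3}), {})


class TestEnc:
    def test_uniform_usage_is_61(self):
        counts = {c: 100 for c in SC_CODONS}
        counts.update({"ATG": 100, "TGG": 100})
        assert cc.enc(CodonCountTable(counts=counts)) == pytest.approx(61.0)

    def test_maximal_bias_is_20(self):
        counts = {codons[0]: 100 for codons in AA_TO_CODONS.values()}
        assert cc.enc(CodonCountTable(counts=counts)) == pytest.approx(20.0)

    def test_single_family_f_and_fallback(self):
        """Two-codon family with counts (3,1): Wright's
        F = (4*(9/16+1/16)-1)/3 = 0.5; with only that family observed every
        degeneracy class borrows it, so ENC = 2 + (9+1+5+3)/0.5 = 38."""
        t = CodonCountTable(counts={"TTT": 3, "TTC": 1})
        assert cc.enc(t) == pytest.approx(38.0)

    def test_monotone_in_bias(self):
        """Tilting every two-fold family toward one codon lowers ENC."""
        values = []
        for a in (5, 7, 9):
            counts = {c: 10 for c in SC_CODONS}
            for aa, codons in AA_TO_CODONS.items():
                if len(codons) == 2:
                    counts[codons[0]] = 10 + a
                    counts[codons[1]] = 10 - a
            values.append(cc.enc(CodonCountTable(counts=counts)))
        assert values[0] > values[1] > values[2]


@settings(max_examples=20, derandomize=True)
@given(
    st.lists(st.integers(0, 30), min_size=59, max_size=59),
    st.lists(st.integers(0, 30), min_size=59, max_size=59),
)
def test_count_table_additivity(a, b):
    ta = CodonCountTable(counts=dict(zip(SC_CODONS, a)))
    tb = CodonCountTable(counts=dict(zip(SC_CODONS, b)))
    union = ta + tb
    assert union.total == ta.total + tb.total
    assert all(union[c] == ta[c] + tb[c] for c in union.counts)
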