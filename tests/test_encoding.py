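"""Strand construction: complements, input runs, stickers, FASTA I/O.

The golden values here are the bench encodings printed for the three
codebooks (3-nt codewords for the until-dual and interval schemes, 4-nt for
the projection scheme) and must match byte-for-byte.
"""

import io

import pytest
from hypothesis import given, settings, strategies as st

from stickermc import (Codebook, CodebookError, EncodingError, automaton_for,
                       build_sticker_set, encode_acceptance, encode_initial,
                       encode_input_run, encode_transition, export_fasta,
                       read_fasta, trim_to_core, validate_codebook,
                       wc_complement)

D_PHI1 = "TTGCAAGGCAGCGAATTGCAAGGCGCGGAATTGCAAGGCCCCGAATTGCAA"
D_PHI3 = "ATCGGAATGTATCGAATCGGAATGTGACGAATCGGA"

TABLE_A1 = {
    "s0-initial": "CGGTCTT",
    "s2-acceptance": "CCGGCAG",
    "t0s0": "AACGTTCCGTCGCTT",
    "t0u1": "AACGTTCCGCGCCTTAAC",
    "t0s2": "AACGTTCCGTCGCTTAACGTT",
    "t1s1": "GTTCCGTCGCTTAAC",
    "t1q2": "GTTCCGGGGCTTAACGTT",
}

TABLE_A5 = {
    "s0-initial": "GCGAGCT",
    "s2-acceptance": "TACGCCG",
    "t0p10": "TAGCCTTACCTAGCT",
    "t0p0": "TAGCCTTACATAGCT",
    "t0q11": "TAGCCTTACTATGCTTAG",
    "t0q2": "TAGCCTTACACTGCTTAGCCT",
    "t1p21": "CCTTACCTTGCTTAG",
    "t1q22": "CCTTACAAGGCTTAGCCT",
    "t2p0": "TACATAGCT",
    "t2q2": "TACACTGCTTAGCCT",
}

TABLE_A4 = {
    "s0-initial": "CGTC AGCC",
    "s4-acceptance": "ACGT ACCT GCAT TTGG",
    "t0m11": "GCGT AGTA CACC AGAA ACGT ACCT GCAT CACT AGCC GCGT",
    "t0m22": "GCGT AGTA CACC AGAA ACGT ACCT GCAT CTGG AGCC GCGT AGTA",
    "t1p11": "AGTA CACC AGAA ACGT ACCT GCAT GGCG AGCC GCGT",
    "t1q12": "AGTA CACC AGAA ACGT ACCT GCAT TAGG AGCC GCGT AGTA",
    "t2m33": "CACC AGAA ACGT ACCT GCAT TTGC AGCC GCGT AGTA CACC",
    "t2m44": "CACC AGAA ACGT ACCT GCAT CTGC AGCC GCGT AGTA CACC AGAA",
    "t3p23": "AGAA ACGT ACCT GCAT GTTT AGCC GCGT AGTA CACC",
    "t3q24": "AGAA ACGT ACCT GCAT CCCT AGCC GCGT AGTA CACC AGAA",
}


class TestComplement:
    def test_initial_sticker_complement(self):
        assert wc_complement("GCCAGAA") == "CGGTCTT"

    def test_single_base(self):
        assert wc_complement("A") == "T"

    @given(st.text(alphabet="ACGT", max_size=64))
    @settings(derandomize=True, max_examples=100)
    def test_involution(self, seq):
        assert wc_complement(wc_complement(seq)) == seq

    def test_rejects_non_acgt(self):
        with pytest.raises(EncodingError):
            wc_complement("ACGU")


class TestInputRun:
    def test_suq_golden(self, cb_phi1):
        strand = encode_input_run(["s", "u", "q"], cb_phi1)
        assert strand.seq == ("GCCAGAATTGCAAGGCAGCGAATTGCAAGGCGCG"
                              "GAATTGCAAGGCCCCGAATTGCAAGGCCGTC")
        assert len(strand) == 65

    def test_itl_pq_golden(self, cb_itl):
        strand = encode_input_run(["p", "q"], cb_itl)
        assert strand.seq == ("CGCT" + "CGAATCGGAATG" + "TAT"
                              + "CGAATCGGAATG" + "TGA" + "CGAATCGGAATG" + "CGGC")

    def test_empty_word(self, cb_phi1):
        strand = encode_input_run([], cb_phi1)
        assert strand.seq == "GCCA" + "GAATTGCAAGGC" + "CGTC"

    def test_missing_codeword(self, cb_phi1):
        with pytest.raises(CodebookError):
            encode_input_run(["z"], cb_phi1)

    @given(st.lists(st.sampled_from("pqrsu"), max_size=12))
    @settings(derandomize=True, max_examples=100)
    def test_length_law(self, word):
        cb = Codebook(letters={"p": "CGA", "q": "CCC", "r": "CGC",
                               "s": "AGC", "u": "GCG"},
                      spacers=["GAA", "TTG", "CAA", "GGC"],
                      i1="GCCA", i2="CGTC")
        n = len(word)
        strand = encode_input_run(word, cb)
        assert len(strand) == 8 + (n + 1) * 12 + n * 3


class TestTrim:
    def test_phi1_core_golden(self, cb_phi1):
        run = encode_input_run(["s", "u", "q"], cb_phi1)
        assert trim_to_core(run, cb_phi1, 0, 2).seq == D_PHI1

    def test_itl_core_golden(self, cb_itl):
        run = encode_input_run(["p", "q"], cb_itl)
        assert trim_to_core(run, cb_itl, 0, 2).seq == D_PHI3

    def test_nothing_remains(self, cb_phi1):
        run = encode_input_run([], cb_phi1)
        assert trim_to_core(run, cb_phi1, 0, 0).seq == ""

    def test_mismatched_context(self, cb_phi1, cb_itl):
        run = encode_input_run(["p", "q"], cb_itl)
        with pytest.raises(EncodingError):
            trim_to_core(run, cb_phi1, 0, 2)


class TestStickers:
    @pytest.mark.parametrize("args,expected", [
        ((0, "s", 0), "AACGTTCCGTCGCTT"),
        ((1, "q", 2), "GTTCCGGGGCTTAACGTT"),
    ])
    def test_transition_golden_phi1(self, cb_phi1, args, expected):
        strand = encode_transition(*args, cb_phi1)
        assert strand.written == expected
        assert strand.written_orientation == "3'->5'"

    def test_transition_golden_itl(self, cb_itl):
        assert encode_transition(2, "q", 2, cb_itl).written == "TACACTGCTTAGCCT"

    def test_initial_and_acceptance(self, cb_phi1, cb_phi4):
        assert encode_initial(0, cb_phi1).written == "CGGTCTT"
        assert encode_acceptance(2, cb_phi1).written == "CCGGCAG"
        acc4 = encode_acceptance(4, cb_phi4)
        assert acc4.written == "ACGTACCTGCATTTGG" and len(acc4) == 16

    def test_acceptance_needs_spare_spacer(self, cb_phi1):
        with pytest.raises(CodebookError):
            encode_acceptance(3, cb_phi1)  # m = 3: index 3 leaves no spacer

    def test_sticker_set_matches_a1_table(self, stickers_a1):
        strands = {s.name: s.written for s in stickers_a1.strands}
        assert strands == TABLE_A1

    def test_sticker_set_matches_merged_interval_table(self, cb_itl):
        ss = build_sticker_set(automaton_for("A5"), cb_itl)
        assert {s.name: s.written for s in ss.strands} == TABLE_A5

    def test_sticker_set_matches_a4_table(self, stickers_a4):
        # printed with grouping whitespace, ignored on comparison
        expected = {k: v.replace(" ", "") for k, v in TABLE_A4.items()}
        assert {s.name: s.written for s in stickers_a4.strands} == expected

    def test_single_state_accepting_initial(self):
        from stickermc import FSA
        fsa = FSA.build({"a"}, 1, set(), 0, {0})
        cb = Codebook(letters={"a": "ACA"}, spacers=["GGG", "TTT"],
                      i1="GCCA", i2="CGTC")
        ss = build_sticker_set(fsa, cb)
        assert len(ss.strands) == 2
        assert {s.role for s in ss.strands} == {"initial", "acceptance"}

    def test_reconstruction_along_accepting_run(self, cb_phi1):
        # initial + transitions along an accepted run + acceptance segments
        # concatenate to exactly the input strand
        word = ["s", "u", "q"]
        path = [(0, "s", 0), (0, "u", 1), (1, "q", 2)]
        segments = [encode_initial(0, cb_phi1).meta["segment"]]
        segments += [encode_transition(i, a, j, cb_phi1).meta["segment"]
                     for (i, a, j) in path]
        segments.append(encode_acceptance(2, cb_phi1).meta["segment"])
        assert "".join(segments) == encode_input_run(word, cb_phi1).seq


class TestValidateCodebook:
    def test_phi1_valid(self, cb_phi1):
        report = validate_codebook(cb_phi1, automaton_for("phi1"))
        assert report["valid"] and not report["violations"]

    def test_phi4_valid(self, cb_phi4):
        assert validate_codebook(cb_phi4, automaton_for("phi4"))["valid"]

    def test_duplicate_codewords_flagged(self):
        cb = Codebook(letters={"p": "CGA", "q": "CGA"},
                      spacers=["GAA", "TTG"], i1="GCCA", i2="CGTC")
        report = validate_codebook(cb)
        assert not report["valid"]
        assert any("duplicate" in v for v in report["violations"])

    def test_insufficient_spacers_flagged(self, cb_phi1):
        report = validate_codebook(cb_phi1, automaton_for("phi4"))
        assert not report["valid"]


class TestFasta:
    def test_round_trip(self, stickers_a1):
        buf = io.StringIO()
        n = export_fasta(stickers_a1.strands, buf)
        assert n == 7
        buf.seek(0)
        back = read_fasta(buf)
        assert [(s.name, s.seq, s.written_orientation) for s in back] == \
            [(s.name, s.seq, s.written_orientation) for s in stickers_a1.strands]

    def test_empty_refused_unless_flagged(self):
        with pytest.raises(ValueError):
            export_fasta([], io.StringIO())
        assert export_fasta([], io.StringIO(), allow_empty=True) == 0
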