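import numpy as np
import pytest

from auxfam import promoter_scan as ps
from auxfam.io_core import GeneModel, IoError, SequenceSet


def _rand_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestIupacMatch:
    def test_degenerate_expansion_example(self):
        assert ps.iupac_match("TGTVYS", "TGTACC") == [0]

    def test_overlapping_matches(self):
        assert ps.iupac_match("GGWTW", "GGTTAGGATA") == [0, 5]

    def test_text_shorter_than_word(self):
        assert ps.iupac_match("TGTCTC", "TGT") == []

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            ps.iupac_match("TGTZ", "ACGT")

    def test_n_in_text_matches_nothing(self):
        assert ps.iupac_match("TGTCTC", "TGTCTN") == []
        assert ps.iupac_match("NNNN", "ACNG") == []

    def test_matches_brute_force_on_random_text(self):
        rng = np.random.default_rng(11)
        for word in ("TGTVYS", "BACGTV", "GGWTW", "AMCWAMC"):
            words = set(ps.expand_iupac(word))
            text = _rand_dna(rng, 300)
            brute = [
                i for i in range(len(text) - len(word) + 1)
                if text[i:i + len(word)] in words
            ]
            assert ps.iupac_match(word, text) == brute

    def test_reverse_complement_degenerate(self):
        assert ps.reverse_complement("TGTCTC") == "GAGACA"
        assert ps.reverse_complement("TGTVYS") == "SRBACA"
        # involution on every IUPAC letter
        word = "ACGTRYSWKMBDHVN"
        assert ps.reverse_complement(ps.reverse_complement(word)) == word


class TestExtractPromoter:
    def _genome(self, seq="A" * 3000):
        return SequenceSet([("chr1", seq)])

    def test_plus_strand_window(self):
        seq = _rand_dna(np.random.default_rng(1), 3000)
        genome = self._genome(seq)
        gene = GeneModel(
            name="g", chromosome="chr1", strand="+", start=2001, end=2600,
            exons=[(2001, 2600)], orf_length_nt=600,
        )
        assert ps.extract_promoter(genome, gene) == seq[1000:2000]

    def test_minus_strand_abuts_atg(self):
        seq = _rand_dna(np.random.default_rng(2), 3000)
        genome = self._genome(seq)
        gene = GeneModel(
            name="g", chromosome="chr1", strand="-", start=401, end=1000,
            exons=[(401, 1000)], orf_length_nt=600,
        )
        prom = ps.extract_promoter(genome, gene)
        # last promoter base pairs with the base just 3' of the CDS end
        assert prom[-1] == ps.reverse_complement(seq[1000])
        assert prom == ps.reverse_complement(seq[1000:2000])

    def test_truncation_warns(self):
        genome = self._genome()
        gene = GeneModel(
            name="g", chromosome="chr1", strand="+", start=500, end=1100,
            exons=[(500, 1100)], orf_length_nt=601,
        )
        with pytest.warns(UserWarning, match="truncated"):
            prom = ps.extract_promoter(genome, gene)
        assert len(prom) == 499

    def test_no_cds_is_error(self):
        genome = self._genome()
        gene = GeneModel(
            name="g", chromosome="chr1", strand="+", start=2001, end=2600,
            exons=[], orf_length_nt=0,
        )
        with pytest.raises(IoError, match="CDS"):
            ps.extract_promoter(genome, gene)


class TestScanPromoters:
    def _prom(self, text):
        return SequenceSet([("p", text)])

    def test_forward_aux1(self):
        text = "A" * 40 + "TGTCTC" + "A" * 54
        hits = ps.scan_promoters(self._prom(text),
                                 (ps.MOTIFS_BY_NAME["AUX1"],))
        assert [(h.strand, h.offset, h.word) for h in hits] == [
            ("+", 40 - 100, "TGTCTC")
        ]

    def test_reverse_aux1(self):
        text = "A" * 40 + "GAGACA" + "A" * 54
        hits = ps.scan_promoters(self._prom(text),
                                 (ps.MOTIFS_BY_NAME["AUX1"],))
        assert [(h.strand, h.word) for h in hits] == [("-", "GAGACA")]

    def test_offset_is_five_prime_most_position(self):
        text = "TGTCTC" + "A" * 14
        hits = ps.scan_promoters(self._prom(text),
                                 (ps.MOTIFS_BY_NAME["AUX1"],))
        assert hits[0].offset == -20

    def test_strand_symmetry(self):
        rng = np.random.default_rng(21)
        text = _rand_dna(rng, 200)
        fwd = ps.scan_promoters(self._prom(text))
        rev = ps.scan_promoters(self._prom(ps.reverse_complement(text)))
        flip = {"+": "-", "-": "+"}

        def key(hits, flipped):
            out = set()
            for h in hits:
                if flipped:
                    # window at offset o spans o..o+L-1; mirrored start
                    out.add((h.motif, flip[h.strand],
                             -(h.offset + len(h.word)) - 200))
                else:
                    out.add((h.motif, h.strand, h.offset))
            return out

        assert key(fwd, False) == key(rev, True)

    def test_aux2_superset_of_aux1(self):
        rng = np.random.default_rng(22)
        motifs = (ps.MOTIFS_BY_NAME["AUX1"], ps.MOTIFS_BY_NAME["AUX2"])
        for _ in range(50):
            text = _rand_dna(rng, 120)
            counts = ps.count_table(
                ps.scan_promoters(self._prom(text), motifs), motifs=motifs
            )
            assert counts["AUX2"] >= counts["AUX1"]

    def test_palindromic_collapse_flag(self):
        # CACGTG is its own reverse complement and matches GRE both ways
        text = "T" * 50 + "CACGTG" + "T" * 44
        motifs = (ps.MOTIFS_BY_NAME["GRE"],)
        both = ps.scan_promoters(self._prom(text), motifs)
        one = ps.scan_promoters(self._prom(text), motifs,
                                collapse_palindromes=True)
        assert len(both) == 2 and len(one) == 1


class TestCountTable:
    def test_empty_hits_all_zeros(self):
        counts = ps.count_table([])
        assert set(counts) == {m.name for m in ps.DEFAULT_MOTIFS}
        assert set(counts.values()) == {0}

    def test_aux1_word_counts_in_both_classes_by_default(self):
        text = "A" * 50 + "TGTCTC" + "A" * 44
        hits = ps.scan_promoters(SequenceSet([("p", text)]))
        counts = ps.count_table(hits)
        assert counts["AUX1"] == 1 and counts["AUX2"] == 1

    def test_exclusion_flag_drops_aux1_words_from_aux2(self):
        text = "A" * 30 + "TGTCTC" + "A" * 20 + "TGTACC" + "A" * 38
        hits = ps.scan_promoters(SequenceSet([("p", text)]))
        strict = ps.count_table(hits, exclude_aux1_from_aux2=True)
        assert strict["AUX1"] == 1 and strict["AUX2"] == 1  # TGTACC only

    def test_per_promoter_counts(self):
        text = "A" * 50 + "TGACG" + "A" * 45
        hits = ps.scan_promoters(SequenceSet([("p1", text), ("p2", "A" * 40)]))
        by_prom = ps.count_table(hits, per="promoter")
        assert by_prom["p1"]["TGA"] == 1
        assert "p2" not in by_prom  # no hits at all

    def test_scanner_equals_exhaustive_oracle_short_promoters(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            n = int(rng.integers(8, 51))
            text = _rand_dna(rng, n)
            fast = ps.scan_promoters(SequenceSet([("p", text)]))
            brute = ps.brute_force_scan("p", text)
            assert fast == brute
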