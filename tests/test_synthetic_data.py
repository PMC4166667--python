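import numpy as np
import pytest

from auxfam import domain_grammar as dg
from auxfam import promoter_scan as ps
from auxfam import synthetic_data as sd
from auxfam.io_core import IoError


class TestGenerateGenome:
    def test_layout_and_empty_chromosome(self, toy_genome):
        genome, ann, truth = toy_genome
        assert len(ann) == 17
        per_chrom = {f"chr{i}": 0 for i in range(1, 9)}
        for g in ann.genes:
            per_chrom[g.chromosome] += 1
        assert [per_chrom[f"chr{i}"] for i in range(1, 9)] == [
            3, 3, 1, 4, 2, 0, 1, 3
        ]

    def test_determinism(self):
        a = sd.generate_genome(3, [1, 2, 0], seed=7)
        b = sd.generate_genome(3, [1, 2, 0], seed=7)
        assert a[0].records == b[0].records
        assert [g.exons for g in a[1].genes] == [g.exons for g in b[1].genes]

    def test_flanks_allow_full_promoters(self, toy_genome):
        genome, ann, _ = toy_genome
        lengths = {r: len(s) for r, s in genome.records}
        prev_end = {}
        for g in sorted(ann.genes, key=lambda g: (g.chromosome, g.start)):
            assert g.start > 1500
            assert lengths[g.chromosome] - g.end >= 1500
            if g.chromosome in prev_end:
                assert g.start - prev_end[g.chromosome] > 1500
            prev_end[g.chromosome] = g.end

    def test_intron_counts_within_configured_range(self, toy_genome):
        _, ann, _ = toy_genome
        counts = {len(g.exons) - 1 for g in ann.genes}
        assert counts <= set(range(1, 8))

    def test_orf_is_codon_multiple(self, toy_genome):
        _, ann, _ = toy_genome
        for g in ann.genes:
            assert g.orf_length_nt % 3 == 0
            assert g.orf_length_nt == sum(e - s + 1 for s, e in g.exons)

    def test_too_short_chromosome_is_error(self):
        with pytest.raises(IoError, match="too short"):
            sd.generate_genome(
                1, [3], seed=1, chromosome_lengths=[4000]
            )

    def test_bad_counts_rejected(self):
        with pytest.raises(IoError):
            sd.generate_genome(2, [1], seed=1)
        with pytest.raises(IoError):
            sd.generate_genome(1, [-1], seed=1)


class TestGenerateProteins:
    def test_canonical_classifies_canonical(self, family_proteins):
        proteins, truth = family_proteins
        for name in [f"SynIAA{i}" for i in (1, 5, 17)]:
            anno = dg.annotate(name, proteins[name])
            assert dg.classify_architecture(anno).canonical
            assert anno.degron_state == "canonical"

    def test_pb1_only_reports_missing_I_II(self):
        arch = sd.ProteinArchitecture(
            name="p", domains=("III", "IV"), nls_bipartite=False
        )
        proteins, _ = sd.generate_proteins([arch], seed=5)
        anno = dg.annotate("p", proteins["p"])
        missing = dg.classify_architecture(anno).missing
        assert missing == frozenset({"I", "II"})

    def test_empty_architecture_has_no_domains(self):
        arch = sd.ProteinArchitecture(
            name="bare", domains=(), nls_bipartite=False, nls_typical=False
        )
        proteins, _ = sd.generate_proteins([arch], seed=6)
        anno = dg.annotate("bare", proteins["bare"])
        assert dg.classify_architecture(anno).missing == frozenset(
            dg.DOMAIN_ORDER
        )
        assert anno.lxlxlx is None and anno.degron_state == "absent"

    def test_degron_variant_carried(self):
        arch = sd.ProteinArchitecture(name="v", degron="DWPPV")
        proteins, _ = sd.generate_proteins([arch], seed=7)
        state, word, _ = dg.find_degron(proteins["v"])
        assert (state, word) == ("modified", "DWPPV")

    def test_determinism(self):
        archs = sd.canonical_family_architectures(3)
        a, _ = sd.generate_proteins(archs, seed=9)
        b, _ = sd.generate_proteins(
            sd.canonical_family_architectures(3), seed=9
        )
        assert a.records == b.records


class TestPlantMotifs:
    VOCAB = tuple(m for m in ps.DEFAULT_MOTIFS if m.name != "AUX2")

    def _small(self, seed=11):
        return sd.generate_genome(2, [1, 1], seed=seed)

    def test_planted_offset_recovered(self):
        genome, ann, _ = self._small()
        g = ann.genes[0].name
        genome2, truth = sd.plant_motifs(
            ann, genome, [(g, "AUX1", -500, "+")], seed=1
        )
        hits = ps.scan_promoters(
            ps.extract_promoters(genome2, ann), (ps.MOTIFS_BY_NAME["AUX1"],)
        )
        assert any(
            h.promoter_id == g and h.offset == -500 and h.strand == "+"
            for h in hits
        )

    def test_minus_strand_word_is_reverse_complement(self):
        genome, ann, _ = self._small()
        g = ann.genes[0].name
        genome2, _ = sd.plant_motifs(
            ann, genome, [(g, "AUX1", -300, "-")], seed=2
        )
        prom = ps.extract_promoter(genome2, ann[g])
        assert prom[1000 - 300:1000 - 300 + 6] == "GAGACA"

    def test_motif_free_background_zero_hits(self):
        genome, ann, _ = self._small(seed=13)
        genome2, _ = sd.plant_motifs(
            ann, genome, [], seed=3, motif_free_background=True,
            vocabulary=self.VOCAB,
        )
        hits = ps.scan_promoters(
            ps.extract_promoters(genome2, ann), self.VOCAB
        )
        assert hits == []

    def test_overlapping_plants_rejected(self):
        genome, ann, _ = self._small()
        g = ann.genes[0].name
        with pytest.raises(IoError, match="overlap"):
            sd.plant_motifs(
                ann, genome,
                [(g, "AUX1", -500, "+"), (g, "TGA", -498, "+")],
                seed=4,
            )

    def test_offset_outside_window_rejected(self):
        genome, ann, _ = self._small()
        g = ann.genes[0].name
        with pytest.raises(IoError, match="window"):
            sd.plant_motifs(ann, genome, [(g, "AUX1", -3, "+")], seed=5)

    def test_planting_respects_gene_strand(self):
        # same plan on a minus-strand gene still recovered by the scanner
        genome, ann, _ = self._small(seed=17)
        minus = [g for g in ann.genes if g.strand == "-"]
        if not minus:  # force one
            ann.genes[0].strand = "-"
            minus = [ann.genes[0]]
        g = minus[0].name
        genome2, _ = sd.plant_motifs(
            ann, genome, [(g, "MRE1", -250, "+")], seed=6
        )
        hits = ps.scan_promoters(
            ps.extract_promoters(genome2, ann), (ps.MOTIFS_BY_NAME["MRE1"],)
        )
        assert any(
            h.promoter_id == g and h.offset == -250 and h.strand == "+"
            for h in hits
        )


class TestCtTable:
    def test_zero_noise_closed_form(self):
        design = sd.ExperimentDesign(
            organs=("root",), conditions=("mock", "trt"), timepoints=(3,),
        )
        effects = {("g", "root", "trt", 3): -2.0}
        ct = sd.generate_ct_table(["g"], design, effects, 0.0, seed=21)
        from auxfam import expression as ex

        fcm = ex.timecourse_contrast(ct, "trt", "mock")
        assert fcm["fold"].iloc[0] == pytest.approx(0.25)

    def test_zero_effect_means_fold_one(self):
        design = sd.ExperimentDesign(
            organs=("root",), conditions=("mock", "trt"), timepoints=(3,),
        )
        ct = sd.generate_ct_table(["g"], design, {}, 0.0, seed=22)
        from auxfam import expression as ex

        fcm = ex.timecourse_contrast(ct, "trt", "mock")
        assert (fcm["fold"] == 1.0).all()

    def test_determinism_and_reference_row(self):
        design = sd.ExperimentDesign()
        a = sd.generate_ct_table(["g"], design, {}, 0.3, seed=23)
        b = sd.generate_ct_table(["g"], design, {}, 0.3, seed=23)
        assert a.equals(b)
        assert sd.REFERENCE_GENE in set(a["gene"])

    def test_negative_noise_rejected(self):
        with pytest.raises(IoError):
            sd.generate_ct_table(["g"], sd.ExperimentDesign(), {}, -0.1, 1)


class TestAdditiveMatrix:
    def test_matrix_is_valid_and_additive(self):
        dm, bips = sd.random_additive_matrix(6, seed=31)
        m = dm.matrix
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)
        # four-point condition on a few quartets
        ids = range(len(dm.ids))
        for (i, j, k, l) in [(0, 1, 2, 3), (1, 2, 4, 5), (0, 3, 4, 5)]:
            sums = sorted(
                [m[i, j] + m[k, l], m[i, k] + m[j, l], m[i, l] + m[j, k]]
            )
            assert sums[1] == pytest.approx(sums[2])
        assert all(len(b) == 2 for b in bips)
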