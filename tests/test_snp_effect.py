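import pytest

from pomedev import snp_effect as se
from pomedev import synthetic_data as sd
from pomedev.formats_io import GeneModel, GenomeSequence, Variant

from oracle import classify_oracle


def toy_genome(seq_5prime_pad=10_000, cds="ATGGCTTGGAAGTAA", pad_char_seed=7):
    """Single-exon plus-strand gene at 10001.. with a hand-chosen CDS."""
    import numpy as np

    rng = np.random.default_rng(pad_char_seed)
    bases = "ACGT"
    pad = "".join(rng.choice(list(bases), size=seq_5prime_pad))
    tail = "".join(rng.choice(list(bases), size=5000))
    seq = pad + cds + tail
    gene = GeneModel(
        gene_id="gA", mrna_id="gA.m1", chrom="c1", strand="+",
        exons=[(10_001, 10_000 + len(cds))], cds=[(10_001, 10_000 + len(cds))],
    )
    return GenomeSequence({"c1": seq}), gene


class TestIndexGeometry:
    def test_plus_strand_upstream_window(self):
        genome, gene = toy_genome()
        idx = se.build_transcript_index([gene], genome)
        ctx = idx.contexts[0]
        assert ctx.upstream == (8_001, 10_000)
        assert ctx.downstream == (10_016, 12_015)

    def test_minus_strand_upstream_mirrored(self):
        genome, gene = toy_genome()
        gene2 = GeneModel(
            gene_id="gA", mrna_id="gA.m1", chrom="c1", strand="-",
            exons=gene.exons, cds=gene.cds,
        )
        idx = se.build_transcript_index([gene2], genome)
        ctx = idx.contexts[0]
        assert ctx.upstream == (10_016, 12_015)
        assert ctx.downstream == (8_001, 10_000)

    def test_two_exon_gene_has_four_splice_bases_per_intron(self, small_fixture):
        genome, models = small_fixture
        multi = next(m for m in models if len(m.exons) >= 2)
        idx = se.build_transcript_index([multi], genome)
        ctx = idx.contexts[0]
        assert len(ctx.splice_positions) == 4 * len(multi.introns)
        for s, e in multi.introns:
            assert {s, s + 1, e - 1, e} <= ctx.splice_positions


def classify_one(genome, gene, pos, alt):
    idx = se.build_transcript_index([gene], genome)
    ref = genome.base("c1", pos)
    v = Variant("c1", pos, ref, alt, "cv")
    (rec,) = se.primary_records([se.classify_variant(v, idx, genome)])
    return rec


class TestClassRules:
    def test_intron_boundary_vs_interior(self):
        genome, _ = toy_genome()
        gene = GeneModel(
            gene_id="gB", mrna_id="gB.m1", chrom="c1", strand="+",
            exons=[(10_001, 10_060), (10_161, 10_220)],
            cds=[(10_001, 10_060), (10_161, 10_220)],
        )
        # intron is 10061..10160
        assert classify_one(genome, gene, 10_061, _other(genome, 10_061)).effect_class == 3
        assert classify_one(genome, gene, 10_062, _other(genome, 10_062)).effect_class == 3
        assert classify_one(genome, gene, 10_063, _other(genome, 10_063)).effect_class == 4
        assert classify_one(genome, gene, 10_160, _other(genome, 10_160)).effect_class == 3
        assert classify_one(genome, gene, 10_158, _other(genome, 10_158)).effect_class == 4

    def test_genome_n_trumps_codon_context(self):
        genome, gene = toy_genome(cds="ATGGCTTGGAAGTAA")
        seq = genome.records["c1"]
        # put an N inside the CDS
        seq = seq[:10_004] + "N" + seq[10_005:]
        genome = GenomeSequence({"c1": seq})
        rec = classify_one(genome, gene, 10_005, "A")
        assert rec.effect_class == 12
        assert rec.gene_id is None

    def test_synonymous_third_position(self):
        # GCT -> GCC is Ala -> Ala at codon 2
        genome, gene = toy_genome(cds="ATGGCTTGGAAGTAA")
        rec = classify_one(genome, gene, 10_006, "C")
        assert rec.effect_class == 7
        assert (rec.ref_codon, rec.alt_codon) == ("GCT", "GCC")
        assert rec.ref_aa == rec.alt_aa == "A"

    def test_premature_stop_internal_tgg(self):
        # TGG (Trp) -> TGA at codon 3
        genome, gene = toy_genome(cds="ATGGCTTGGAAGTAA")
        rec = classify_one(genome, gene, 10_009, "A")
        assert rec.effect_class == 8
        assert rec.alt_codon == "TGA"

    def test_minus_strand_premature_stop_via_plus_c_to_t(self):
        # minus-strand CDS ATG GCT TGG AAG TAA; genomic plus strand holds its
        # reverse complement; the TGG codon mutates through the mirrored base
        cds = "ATGGCTTGGAAGTAA"
        from Bio.Seq import Seq

        rc = str(Seq(cds).reverse_complement())
        genome, _ = toy_genome(cds=rc)
        gene = GeneModel(
            gene_id="gC", mrna_id="gC.m1", chrom="c1", strand="-",
            exons=[(10_001, 10_015)], cds=[(10_001, 10_015)],
        )
        # coding offset 8 (third base of TGG codon) maps to genomic 10_015 - 8
        pos = 10_015 - 8
        assert genome.base("c1", pos) == "C"
        rec = classify_one(genome, gene, pos, "T")
        assert rec.effect_class == 8
        # independent oracle agrees
        v = Variant("c1", pos, "C", "T", "cv")
        assert classify_oracle(v, [gene], genome) == 8

    def test_start_codon_change_and_silent(self):
        genome, gene = toy_genome(cds="ATGGCTTGGAAGTAA")
        assert classify_one(genome, gene, 10_001, "C").effect_class == 5
        # GTG-start transcript: G->A restores ATG, a silent initiator change
        genome2, _ = toy_genome(cds="GTGGCTTGGAAGTAA")
        gene2 = GeneModel(
            gene_id="gA", mrna_id="gA.m1", chrom="c1", strand="+",
            exons=gene.exons, cds=gene.cds,
        )
        rec = classify_one(genome2, gene2, 10_001, "A")
        assert rec.effect_class == 11
        rec5 = classify_one(genome2, gene2, 10_001, "T")
        assert rec5.effect_class == 5

    def test_stop_codon_change_and_silent(self):
        genome, gene = toy_genome(cds="ATGGCTTGGAAGTAA")
        # TAA -> CAA: no longer a stop
        assert classify_one(genome, gene, 10_013, "C").effect_class == 6
        # TAA -> TGA: still a stop
        assert classify_one(genome, gene, 10_014, "G").effect_class == 10

    def test_ref_mismatch_rejected(self):
        genome, gene = toy_genome()
        idx = se.build_transcript_index([gene], genome)
        base = genome.base("c1", 500)
        wrong = {"A": "C", "C": "A", "G": "A", "T": "A", "N": "A"}[base]
        alt = next(b for b in "ACGT" if b not in (base, wrong))
        with pytest.raises(ValueError, match="REF mismatch"):
            se.classify_variant(Variant("c1", 500, wrong, alt, "cv"), idx, genome)


def _other(genome, pos):
    base = genome.base("c1", pos)
    return next(b for b in "ACGT" if b != base)


class TestOracleEquivalence:
    def test_planted_variants_match_truth_and_oracle(self, planted_fixture):
        genome, models, variants, truths = planted_fixture
        idx = se.build_transcript_index(models, genome)
        prim = se.primary_records(se.classify_variants(variants, idx, genome))
        for rec, truth in zip(prim, truths):
            assert rec.effect_class == truth.intended_class
            assert classify_oracle(truth.variant, models, genome) == truth.intended_class

    def test_strand_symmetry(self, planted_fixture):
        genome, models, variants, _ = planted_fixture
        idx = se.build_transcript_index(models, genome)
        prim = se.primary_records(se.classify_variants(variants, idx, genome))
        g2, m2, v2 = sd.reverse_complement_fixture(genome, models, variants)
        idx2 = se.build_transcript_index(m2, g2)
        prim2 = se.primary_records(se.classify_variants(v2, idx2, g2))
        assert [r.effect_class for r in prim] == [r.effect_class for r in prim2]

    def test_every_variant_has_one_primary_record(self, planted_fixture):
        genome, models, variants, _ = planted_fixture
        idx = se.build_transcript_index(models, genome)
        prim = se.primary_records(se.classify_variants(variants, idx, genome))
        assert len(prim) == len(variants)
        summary = se.effect_summary(prim)
        assert summary.to_numpy().sum() == len(variants)


class TestSummaries:
    def test_effect_summary_matches_planting_spec(self, planted_fixture):
        genome, models, variants, truths = planted_fixture
        idx = se.build_transcript_index(models, genome)
        prim = se.primary_records(se.classify_variants(variants, idx, genome))
        summary = se.effect_summary(prim)
        from collections import Counter

        want = Counter(t.intended_class for t in truths)
        for cls, n in want.items():
            assert summary.loc[se.CLASS_NAMES[cls], "synthetic"] == n

    def test_crosstab_counts_distinct_genes(self):
        v = Variant("c1", 5, "A", "G", "cv")
        recs = [
            se.EffectRecord(v, "g1", "g1.m1", 9),
            se.EffectRecord(v, "g1", "g1.m1", 9),  # second variant, same gene
            se.EffectRecord(v, "g2", "g2.m1", 8),
        ]
        ann = {"g1": {"t1", "t2"}, "g2": {"t1"}}
        tab = se.go_effect_crosstab(recs, ann)
        assert tab.loc["t1", "nonsynonymous"] == 1
        assert tab.loc["t2", "nonsynonymous"] == 1  # multi-term gene counts per row
        assert tab.loc["t1", "premature_stop"] == 1

    def test_crosstab_brute_force_on_planted(self, planted_fixture, small_fixture):
        genome, models, variants, truths = planted_fixture
        ann = sd.generate_annotation(models, seed=5)
        idx = se.build_transcript_index(models, genome)
        prim = se.primary_records(se.classify_variants(variants, idx, genome))
        tab = se.go_effect_crosstab(prim, ann)
        # enumeration: for each class, genes with >=1 primary variant
        for cls in (5, 6, 8, 9):
            genes = {r.gene_id for r in prim if r.effect_class == cls and r.gene_id}
            for term in tab.index:
                want = sum(term in ann.get(g, ()) for g in genes)
                assert tab.loc[term, se.CLASS_NAMES[cls]] == want
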