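import numpy as np
import pytest
from Bio.Seq import Seq

from pomedev import expression_quant as eq
from pomedev import synthetic_data as sd


class TestGenome:
    def test_shape_and_no_n(self):
        g = sd.generate_genome(1, 10_000, 0, seed=1)
        assert list(g.records) == ["chr1"]
        assert len(g.records["chr1"]) == 10_000
        assert "N" not in g.records["chr1"]

    def test_n_fraction_expectation(self):
        g = sd.generate_genome(1, 10_000, 0.01, seed=1)
        n = g.records["chr1"].count("N")
        assert 50 <= n <= 160  # ~100 expected

    def test_deterministic(self):
        assert sd.generate_genome(2, 12_000, 0.01, seed=9) == sd.generate_genome(
            2, 12_000, 0.01, seed=9
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="10 kb"):
            sd.generate_genome(1, 500, 0, seed=0)


class TestGeneModels:
    def test_plus_strand_starts_atg(self, small_fixture):
        genome, models = small_fixture
        # the first two fixture genes carry the deliberate GTG start; skip them
        m = next(m for m in models if m.strand == "+" and m.gene_id > "g0002")
        s = m.cds[0][0]
        assert genome.records[m.chrom][s - 1 : s + 2] == "ATG"

    def test_minus_strand_revcomp_starts_atg(self, small_fixture):
        genome, models = small_fixture
        m = next(m for m in models if m.strand == "-" and m.mrna_id > "g0002")
        e = m.cds[-1][1]
        last3 = genome.records[m.chrom][e - 3 : e]
        assert str(Seq(last3).reverse_complement()) == "ATG"

    def test_cds_clean_orf_both_strands(self, small_fixture):
        genome, models = small_fixture
        for m in models[:8]:
            parts = "".join(genome.records[m.chrom][s - 1 : e] for s, e in m.cds)
            cds = parts if m.strand == "+" else str(Seq(parts).reverse_complement())
            assert len(cds) % 3 == 0
            prot = str(Seq(cds).translate())
            assert prot.endswith("*") and "*" not in prot[:-1]

    def test_intergenic_gap_respected(self, small_fixture):
        _, models = small_fixture
        by_chrom = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append(m.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 - e1 - 1 >= 4001

    def test_both_strands_used(self, small_fixture):
        _, models = small_fixture
        strands = {m.strand for m in models}
        assert strands == {"+", "-"}

    def test_genome_too_short(self):
        g = sd.generate_genome(1, 10_000, 0, seed=0)
        with pytest.raises(ValueError, match="too short"):
            sd.generate_gene_models(g, n_genes=10, seed=0)


class TestPlanting:
    def test_intron_interior_distance(self, small_fixture):
        genome, models = small_fixture
        variants, truths = sd.plant_variants(genome, models, {4: 10}, seed=5)
        introns = {
            m.gene_id: m.introns for m in models
        }
        for t in truths:
            assert t.intended_class == 4
            ivs = introns[t.gene_id]
            dist = max(
                min(t.variant.pos - s, e - t.variant.pos)
                for s, e in ivs
                if s <= t.variant.pos <= e
            )
            inside = [iv for iv in ivs if iv[0] <= t.variant.pos <= iv[1]]
            assert inside
            s, e = inside[0]
            assert t.variant.pos - s >= 2 and e - t.variant.pos >= 2

    def test_class12_sites_are_n(self, small_fixture):
        genome, models = small_fixture
        variants, truths = sd.plant_variants(genome, models, {12: 3}, seed=5)
        assert all(genome.base(v.chrom, v.pos) == "N" for v in variants)
        assert all(v.ref_allele == "N" for v in variants)

    def test_class7_wobble_preserves_amino_acid(self, small_fixture):
        """Verified against the codon table via translation."""
        genome, models = small_fixture
        variants, truths = sd.plant_variants(genome, models, {7: 8}, seed=6)
        by_id = {m.gene_id: m for m in models}
        for t in truths:
            m = by_id[t.gene_id]
            parts = "".join(genome.records[m.chrom][s - 1 : e] for s, e in m.cds)
            cds = parts if m.strand == "+" else str(Seq(parts).reverse_complement())
            # apply the substitution and retranslate the whole protein
            chrom = genome.records[m.chrom]
            mut = chrom[: t.variant.pos - 1] + t.variant.alt_allele + chrom[t.variant.pos :]
            parts2 = "".join(mut[s - 1 : e] for s, e in m.cds)
            cds2 = parts2 if m.strand == "+" else str(Seq(parts2).reverse_complement())
            assert str(Seq(cds).translate()) == str(Seq(cds2).translate())
            assert cds != cds2

    def test_unplantable_class_errors_with_name(self, small_fixture):
        genome, models = small_fixture
        with pytest.raises(sd.UnplantableClassError, match="class 11"):
            sd.plant_variants(genome, models, {11: 99}, seed=0)

    def test_deterministic(self, small_fixture):
        genome, models = small_fixture
        v1, _ = sd.plant_variants(genome, models, {7: 5, 9: 5}, seed=8)
        v2, _ = sd.plant_variants(genome, models, {7: 5, 9: 5}, seed=8)
        assert v1 == v2


class TestCounts:
    def test_flat_zero_noise_identical_rpkm(self, small_fixture, sample_sheet):
        _, models = small_fixture
        em, _ = sd.simulate_counts(
            models, sample_sheet, profile_spec={"flat": 1.0},
            maturation_spec={"post_ripening": 0.0, "non_post_ripening": 0.0},
            down_fraction=0.0, noise=0, seed=1,
        )
        rpkm = eq.compute_rpkm(em)
        series = rpkm.cultivar_series("HS")
        assert (series.nunique(axis=1) == 1).all()

    def test_steady_decrease_zero_noise_strictly_decreasing(self, small_fixture, sample_sheet):
        _, models = small_fixture
        em, truth = sd.simulate_counts(
            models, sample_sheet, profile_spec={"steady_decrease": 1.0},
            maturation_spec={"post_ripening": 0.0, "non_post_ripening": 0.0},
            down_fraction=0.0, noise=0, seed=1,
        )
        rpkm = eq.compute_rpkm(em).cultivar_series("YL")
        diffs = rpkm.to_numpy()[:, 1:] - rpkm.to_numpy()[:, :-1]
        assert (diffs < 0).all()

    def test_extreme_maturation_spec(self, small_fixture, sample_sheet):
        from pomedev import maturation_contrast as mc

        _, models = small_fixture
        em, _ = sd.simulate_counts(
            models, sample_sheet, noise=0,
            maturation_spec={"post_ripening": 1.0, "non_post_ripening": 0.0},
            down_fraction=0.0, seed=2,
        )
        rpkm = eq.compute_rpkm(em)
        assert mc.classify_updown(rpkm, "NG").up_proportion == 100.0
        assert mc.classify_updown(rpkm, "HS").up_proportion == 0.0

    def test_bad_fraction_rejected(self, small_fixture, sample_sheet):
        _, models = small_fixture
        with pytest.raises(ValueError, match="fraction"):
            sd.simulate_counts(models, sample_sheet, profile_spec={"flat": 1.4})

    def test_reproducible(self, small_fixture, sample_sheet):
        _, models = small_fixture
        em1, _ = sd.simulate_counts(models, sample_sheet, seed=4)
        em2, _ = sd.simulate_counts(models, sample_sheet, seed=4)
        assert em1.values.equals(em2.values)


class TestAnnotation:
    def test_deterministic(self, small_fixture):
        _, models = small_fixture
        assert sd.generate_annotation(models, seed=2) == sd.generate_annotation(models, seed=2)

    def test_no_enrichment_uniform(self, small_fixture):
        _, models = small_fixture
        freqs = []
        for seed in range(20):
            ann = sd.generate_annotation(models, n_terms=10, background_p=0.2, seed=seed)
            freqs.append(np.mean([("T000" in ts) for ts in ann.values()]))
        assert np.mean(freqs) == pytest.approx(0.2, abs=0.05)

    def test_odds_ratio_one_matches_background(self, small_fixture):
        _, models = small_fixture
        genes = [m.gene_id for m in models]
        inside = outside = in_n = out_n = 0
        for seed in range(30):
            ann = sd.generate_annotation(
                models, n_terms=5, background_p=0.2,
                enrichment_spec=("T000", set(genes[:8]), 1.0), seed=seed,
            )
            for g in genes[:8]:
                inside += "T000" in ann[g]
                in_n += 1
            for g in genes[8:]:
                outside += "T000" in ann[g]
                out_n += 1
        assert inside / in_n == pytest.approx(outside / out_n, abs=0.08)


def test_reverse_complement_round_trip(planted_fixture):
    genome, models, variants, _ = planted_fixture
    g2, m2, v2 = sd.reverse_complement_fixture(genome, models, variants)
    g3, m3, v3 = sd.reverse_complement_fixture(g2, m2, v2)
    assert g3 == genome
    assert [m.exons for m in m3] == [m.exons for m in models]
    assert v3 == variants
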