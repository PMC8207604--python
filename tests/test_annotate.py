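"""GFF3 loading, deletion consequence calling, and severity ranking."""

from __future__ import annotations

import pytest

from fnbfind import (
    Effect,
    FeatureIndex,
    RegionClass,
    Variant,
    classify_deletion,
    load_annotation,
    prioritize,
)
from fnbfind.annotate import GeneModel, Transcript
from tests._oracles import oracle_cds_overlap
from tests.conftest import make_variant


def _gene(gene_id, chrom, strand, span, exons, cds, utrs=()):
    t = Transcript(f"{gene_id}.1", exons=list(exons), cds=list(cds), utrs=list(utrs))
    return GeneModel(gene_id, chrom, strand, span, [t])


@pytest.fixture
def toy_index():
    """One plus-strand gene on chr1: two exons with a 100 bp 5'UTR, CDS of
    150+150 bp split by a 200 bp intron, and a 100 bp 3'UTR.

    layout (0-based): gene [1000, 1700); exon1 [1000,1250) = UTR5 [1000,1100)
    + CDS [1100,1250); intron [1250,1450); exon2 [1450,1700) =
    CDS [1450,1600) + UTR3 [1600,1700).
    """
    g = _gene(
        "geneA", "chr1", "+", (1000, 1700),
        exons=[(1000, 1250), (1450, 1700)],
        cds=[(1100, 1250), (1450, 1600)],
        utrs=[(1000, 1100), (1600, 1700)],
    )
    return FeatureIndex([g])


def _deletion(start0, length, chrom="chr1"):
    """Deletion whose deleted 0-based half-open interval is [start0, start0+length)."""
    ref = "A" * (length + 1)
    return Variant(chrom, start0, ref, "A", 500.0)


TOY_CDS = [(1100, 1250), (1450, 1600)]


class TestFeatureIndex:
    def test_point_and_interval_queries(self, toy_index):
        assert [g.gene_id for g in toy_index.query("chr1", 1100, 1101)] == ["geneA"]
        assert toy_index.query("chr1", 100, 200) == []
        assert toy_index.query("chr2", 1100, 1101) == []

    def test_overlapping_genes_on_opposite_strands_both_returned(self):
        ga = _gene("ga", "chr1", "+", (100, 500), [(100, 500)], [(100, 400)])
        gb = _gene("gb", "chr1", "-", (300, 900), [(300, 900)], [(400, 880)])
        idx = FeatureIndex([ga, gb])
        # brute-force scan oracle over every 50 bp probe
        for s in range(0, 1000, 50):
            e = s + 50
            expected = sorted(
                g.gene_id for g in (ga, gb) if g.span[0] < e and s < g.span[1]
            )
            assert sorted(g.gene_id for g in idx.query("chr1", s, e)) == expected


class TestClassifyDeletion:
    def test_1bp_cds_deletion_is_frameshift(self, toy_index):
        c = classify_deletion(_deletion(1150, 1), toy_index)
        assert c.region_class is RegionClass.CDS
        assert c.effect is Effect.FRAMESHIFT
        assert c.cds_bases_deleted == 1
        assert c.gene_ids == ["geneA"]

    def test_7bp_deletion_in_second_exon_cds_is_frameshift(self, toy_index):
        c = classify_deletion(_deletion(1500, 7), toy_index)
        assert c.effect is Effect.FRAMESHIFT
        assert c.cds_bases_deleted == 7

    def test_3bp_cds_deletion_is_in_frame(self, toy_index):
        c = classify_deletion(_deletion(1150, 3), toy_index)
        assert c.effect is Effect.IN_FRAME_DELETION

    def test_utr_deletion_is_noncoding(self, toy_index):
        c = classify_deletion(_deletion(1020, 10), toy_index)
        assert c.region_class is RegionClass.UTR
        assert c.effect is Effect.NONCODING

    def test_intronic_and_intergenic(self, toy_index):
        assert classify_deletion(_deletion(1300, 20), toy_index).region_class is RegionClass.INTRONIC
        assert classify_deletion(_deletion(5000, 20), toy_index).region_class is RegionClass.INTERGENIC

    def test_cds_utr_spanning_deletion_is_mixed_with_severe_effect(self, toy_index):
        # removes the last 4 CDS bases and the first 6 UTR3 bases
        c = classify_deletion(_deletion(1596, 10), toy_index)
        assert c.region_class is RegionClass.MIXED
        assert c.effect is Effect.FRAMESHIFT
        assert c.cds_bases_deleted == 4

    def test_whole_gene_loss(self, toy_index):
        c = classify_deletion(_deletion(900, 1000), toy_index)
        assert c.effect is Effect.WHOLE_OR_PARTIAL_GENE_LOSS
        assert c.region_class is RegionClass.MIXED

    def test_unknown_chromosome_is_intergenic(self, toy_index):
        c = classify_deletion(_deletion(1150, 5, chrom="chrZ"), toy_index)
        assert c.region_class is RegionClass.INTERGENIC
        assert c.effect is Effect.NONCODING

    def test_non_deletion_rejected(self, toy_index):
        with pytest.raises(ValueError):
            classify_deletion(Variant("chr1", 10, "A", "T", 1.0), toy_index)

    def test_frameshift_oracle_all_lengths_and_offsets(self, toy_index):
        """Effect equals the per-base oracle (CDS overlap mod 3) for every
        deletion length 1..30 at every offset across the toy gene."""
        for length in range(1, 31):
            for start in range(1050, 1700 - length):
                c = classify_deletion(_deletion(start, length), toy_index)
                want = oracle_cds_overlap(start, start + length, TOY_CDS)
                assert c.cds_bases_deleted == want, (start, length)
                assert c.cds_bases_deleted <= length
                if want > 0:
                    expected = Effect.FRAMESHIFT if want % 3 else Effect.IN_FRAME_DELETION
                    assert c.effect is expected, (start, length)
                else:
                    assert c.effect is Effect.NONCODING

    def test_strand_invariance(self, toy_index):
        """Reversing gene strand never changes overlap or effect: a deletion
        removes the same coding bases either way."""
        minus = _gene(
            "geneA", "chr1", "-", (1000, 1700),
            exons=[(1000, 1250), (1450, 1700)],
            cds=[(1100, 1250), (1450, 1600)],
            utrs=[(1000, 1100), (1600, 1700)],
        )
        idx_minus = FeatureIndex([minus])
        for start, length in [(1150, 1), (1150, 3), (1500, 7), (1240, 20), (1300, 10)]:
            a = classify_deletion(_deletion(start, length), toy_index)
            b = classify_deletion(_deletion(start, length), idx_minus)
            assert a.cds_bases_deleted == b.cds_bases_deleted
            assert a.effect is b.effect

    def test_deletion_spanning_two_genes_reports_both(self):
        ga = _gene("ga", "chr1", "+", (100, 400), [(100, 400)], [(150, 390)])
        gb = _gene("gb", "chr1", "+", (600, 900), [(600, 900)], [(610, 850)])
        idx = FeatureIndex([ga, gb])
        c = classify_deletion(_deletion(380, 250), idx)  # tail of ga CDS + head of gb CDS
        assert c.gene_ids == ["ga", "gb"]
        assert set(c.gene_effects) == {"ga", "gb"}
        assert c.effect in (Effect.FRAMESHIFT, Effect.IN_FRAME_DELETION)


class TestPrioritize:
    def test_coding_hit_outranks_noncoding(self, toy_index):
        """Sixteen intergenic + two UTR + one CDS frameshift: the frameshift
        ranks first."""
        calls = [classify_deletion(_deletion(3000 + 40 * i, 2), toy_index) for i in range(16)]
        calls += [
            classify_deletion(_deletion(1010, 2), toy_index),
            classify_deletion(_deletion(1610, 2), toy_index),
        ]
        calls.append(classify_deletion(_deletion(1150, 1), toy_index))
        ranked = prioritize(calls)
        assert ranked[0].effect is Effect.FRAMESHIFT
        assert {c.region_class for c in ranked[1:3]} == {RegionClass.UTR}
        assert all(c.region_class is RegionClass.INTERGENIC for c in ranked[3:])

    def test_all_intergenic_keeps_genomic_order(self, toy_index):
        calls = [classify_deletion(_deletion(p, 2), toy_index) for p in (4000, 3000, 5000)]
        ranked = prioritize(calls)
        assert [c.variant.pos for c in ranked] == [3000, 4000, 5000]

    def test_two_frameshifts_rank_above_noncoding_in_genomic_order(self, toy_index):
        fs_chr7a = classify_deletion(_deletion(1150, 1, chrom="chr1"), toy_index)
        # second coding gene on another chromosome
        g7 = _gene("g7", "chr7", "+", (100, 400), [(100, 400)], [(150, 390)])
        idx7 = FeatureIndex([g7])
        fs_chr7b = classify_deletion(_deletion(200, 7, chrom="chr7"), idx7)
        utr = classify_deletion(_deletion(1010, 2), toy_index)
        ranked = prioritize([utr, fs_chr7b, fs_chr7a])
        assert [c.effect for c in ranked[:2]] == [Effect.FRAMESHIFT, Effect.FRAMESHIFT]
        assert [c.variant.chrom for c in ranked[:2]] == ["chr1", "chr7"]
        assert ranked[2] is utr


def test_load_annotation_from_simulated_gff3(default_sim, default_sim_paths):
    """The GFF3 writer/loader round-trips the simulator's gene models."""
    idx = load_annotation(default_sim_paths["gff3"])
    assert len(idx.genes) == len(default_sim.genes)
    for g in default_sim.genes:
        gm = idx.genes[g.gene_id]
        assert gm.span == (g.start, g.end)
        rep = gm.representative
        assert sorted(rep.cds) == sorted(g.cds)
        assert sorted(rep.exons) == sorted(g.exons)
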