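"""Three-track intersection, location labelling and candidate ranking."""

import random

import pytest

from gwascore import (
    CnvRegion,
    Gene,
    GenomeAnnotation,
    QtlRecord,
    ScoreConfig,
    annotate_candidates,
    classify_location,
    high_confidence_regions,
    intersect_three_tracks,
    location_distribution,
)
from gwascore.core import ScoreWindow

from conftest import brute_force_intersect


def region(rid, chrom, start, end):
    return CnvRegion(rid, chrom, start, end)


def qtl(qid, chrom, start, end):
    return QtlRecord(qid, "trait", chrom, start, end)


def win(chrom, start, end, score):
    return ScoreWindow(chrom, start, end, 1, 1, score)


def random_tracks(rng, n=40, chroms=("chr1", "chr2")):
    def iv(length_max=5_000):
        chrom = rng.choice(chroms)
        s = rng.randrange(0, 100_000)
        return chrom, s, s + rng.randrange(100, length_max)

    cnvrs = [region(f"c{i}", *iv()) for i in range(n)]
    qtls = [qtl(f"q{i}", *iv(20_000)) for i in range(n)]
    wins = [win(*iv(10_000), score=rng.uniform(0.1, 20)) for i in range(n)]
    return cnvrs, qtls, wins


class TestIntersectThreeTracks:
    def test_requires_both_other_tracks(self):
        c = [region("c1", "chr1", 100, 200)]
        q = [qtl("q1", "chr1", 150, 400)]
        w = [win("chr1", 5_000, 6_000, 3.0)]
        assert intersect_three_tracks(c, q, w) == []  # QTL yes, score no
        assert intersect_three_tracks(c, [], [win("chr1", 0, 300, 3.0)]) == []

    def test_max_score_and_distinct_qtl_count(self):
        c = [region("c1", "chr1", 100, 500)]
        q = [
            qtl("q1", "chr1", 0, 200),
            qtl("q2", "chr1", 150, 300),
            qtl("q3", "chr1", 400, 900),
        ]
        w = [win("chr1", 0, 250, 5.0), win("chr1", 250, 600, 7.0)]
        (hit,) = intersect_three_tracks(c, q, w)
        assert hit.gwascore == 7.0
        assert hit.n_qtl == 3

    def test_empty_score_track_yields_nothing(self):
        c = [region("c1", "chr1", 100, 500)]
        q = [qtl("q1", "chr1", 0, 200)]
        assert intersect_three_tracks(c, q, []) == []

    def test_bookended_intervals_do_not_overlap(self):
        c = [region("c1", "chr1", 100, 200)]
        q = [qtl("q1", "chr1", 200, 300)]
        w = [win("chr1", 0, 1_000, 2.0)]
        assert intersect_three_tracks(c, q, w) == []

    def test_matches_all_pairs_brute_force(self):
        rng = random.Random(23)
        for _ in range(30):
            cnvrs, qtls, wins = random_tracks(rng)
            got = sorted(
                (c.region.region_id, c.gwascore, c.n_qtl)
                for c in intersect_three_tracks(cnvrs, qtls, wins)
            )
            assert got == brute_force_intersect(cnvrs, qtls, wins)

    def test_candidates_are_a_subset_of_input(self):
        rng = random.Random(31)
        cnvrs, qtls, wins = random_tracks(rng)
        ids = {c.region_id for c in cnvrs}
        for cand in intersect_three_tracks(cnvrs, qtls, wins):
            assert cand.region.region_id in ids
            assert cand.n_qtl <= len(qtls)

    def test_adding_a_qtl_never_removes_a_candidate(self):
        rng = random.Random(37)
        cnvrs, qtls, wins = random_tracks(rng)
        before = {c.region.region_id for c in intersect_three_tracks(cnvrs, qtls, wins)}
        more = qtls + [qtl("extra", "chr1", 0, 100_000)]
        after = {c.region.region_id for c in intersect_three_tracks(cnvrs, more, wins)}
        assert before <= after

    def test_raising_threshold_never_adds_a_candidate(self):
        rng = random.Random(41)
        cnvrs, qtls, wins = random_tracks(rng)
        lo = high_confidence_regions(wins, ScoreConfig(score_threshold=1.0))
        hi = high_confidence_regions(wins, ScoreConfig(score_threshold=10.0))
        set_lo = {c.region.region_id for c in intersect_three_tracks(cnvrs, qtls, lo)}
        set_hi = {c.region.region_id for c in intersect_three_tracks(cnvrs, qtls, hi)}
        assert set_hi <= set_lo


# gene on + strand: UTR5 1000-1200, coding 1200-1600 & 3600-4000 around one
# intron, UTR3 4000-4300
PLUS_GENE = Gene(
    gene_id="G1",
    symbol="G1",
    chrom="chr1",
    start=1_000,
    end=4_300,
    strand="+",
    exons=((1_000, 1_600), (3_600, 4_300)),
    utr5=((1_000, 1_200),),
    utr3=((4_000, 4_300),),
    biotype="protein_coding",
)
MINUS_GENE = Gene(
    gene_id="G2",
    symbol="G2",
    chrom="chr2",
    start=10_000,
    end=13_300,
    strand="-",
    exons=((10_000, 10_600), (12_600, 13_300)),
    utr5=((13_100, 13_300),),
    utr3=((10_000, 10_300),),
    biotype="protein_coding",
)
ANN = GenomeAnnotation([PLUS_GENE, MINUS_GENE])


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "start,end,label",
        [
            (1_300, 1_400, "exonic"),       # inside coding exon
            (1_500, 3_700, "exonic"),       # spans exon-intron boundary
            (1_050, 1_150, "UTR5"),         # confined to the 5' UTR
            (4_050, 4_200, "UTR3"),
            (2_000, 3_000, "intronic"),
            (500, 900, "upstream"),         # 100-500 bp 5' of gene start
            (4_400, 4_800, "downstream"),
            (6_000, 7_000, "intergenic"),   # 1.7 kb past the gene
        ],
    )
    def test_plus_strand_labels(self, start, end, label):
        cnvr = region("c", "chr1", start, end)
        assert classify_location(cnvr, ANN, upstream_bp=1_000) == label

    def test_upstream_window_is_bounded(self):
        near = region("c", "chr1", 1_000 - 500, 1_000 - 450)
        far = region("c", "chr1", 1_000 - 1_600, 1_000 - 1_500)
        assert classify_location(near, ANN, upstream_bp=1_000) == "upstream"
        assert classify_location(far, ANN, upstream_bp=1_000) == "intergenic"

    def test_minus_strand_flanks_follow_strand(self):
        right_of_gene = region("c", "chr2", 13_400, 13_500)
        left_of_gene = region("c", "chr2", 9_400, 9_500)
        assert classify_location(right_of_gene, ANN) == "upstream"
        assert classify_location(left_of_gene, ANN) == "downstream"

    def test_utr_of_minus_gene(self):
        cnvr = region("c", "chr2", 13_150, 13_250)
        assert classify_location(cnvr, ANN) == "UTR5"

    def test_no_annotation_means_intergenic(self):
        empty = GenomeAnnotation([])
        assert classify_location(region("c", "chr1", 0, 100), empty) == "intergenic"


class TestAnnotateCandidates:
    def _cand(self, cnvr, score=5.0, n_qtl=2):
        from gwascore.integrate import CandidateRegion

        return CandidateRegion(region=cnvr, gwascore=score, n_qtl=n_qtl, qtl_ids=())

    def test_single_intronic_hit_gives_one_row(self):
        rows = annotate_candidates([self._cand(region("c", "chr1", 2_000, 2_500))], ANN)
        assert len(rows) == 1
        assert rows[0].gene_symbol == "G1"
        assert rows[0].location == "intronic"

    def test_cnvr_spanning_two_genes_gives_two_rows(self):
        g1 = Gene("GA", "GA", "chr3", 0, 1_000, "+", exons=((0, 1_000),))
        g2 = Gene("GB", "GB", "chr3", 1_500, 2_500, "+", exons=((1_500, 2_500),))
        ann = GenomeAnnotation([g1, g2])
        rows = annotate_candidates(
            [self._cand(region("c", "chr3", 500, 2_000), score=4.0, n_qtl=3)], ann
        )
        assert [(r.gene_symbol, r.gwascore, r.n_qtl) for r in rows] == [
            ("GA", 4.0, 3),
            ("GB", 4.0, 3),
        ]

    def test_equal_scores_rank_deterministically(self):
        c1 = self._cand(region("c1", "chr1", 2_000, 2_100), score=6.88)
        c2 = self._cand(region("c2", "chr2", 12_700, 12_800), score=6.88)
        rows1 = annotate_candidates([c1, c2], ANN)
        rows2 = annotate_candidates([c2, c1], ANN)
        assert rows1 == rows2
        assert [r.chrom for r in rows1] == ["chr1", "chr2"]

    def test_gene_free_candidate_reported_as_intergenic(self):
        rows = annotate_candidates([self._cand(region("c", "chr1", 50_000, 51_000))], ANN)
        assert rows[0].gene_symbol is None
        assert rows[0].location == "intergenic"

    def test_noncoding_genes_excluded_by_default(self):
        nc = Gene("N1", "N1", "chr4", 0, 1_000, "+", exons=((0, 1_000),),
                  biotype="lncRNA")
        ann = GenomeAnnotation([nc])
        rows = annotate_candidates([self._cand(region("c", "chr4", 100, 200))], ann)
        assert rows[0].gene_symbol is None
        rows = annotate_candidates(
            [self._cand(region("c", "chr4", 100, 200))], ann, coding_only=False
        )
        assert rows[0].gene_symbol == "N1"


class TestLocationDistribution:
    def test_gene_desert_is_all_intergenic(self):
        cnvrs = [region(f"c{i}", "chr1", 50_000 + i * 1_000, 50_500 + i * 1_000)
                 for i in range(5)]
        dist = location_distribution(cnvrs, ANN)
        assert dist["intergenic"] == 1.0

    def test_planted_quarters(self):
        cnvrs = [
            region("exon", "chr1", 1_300, 1_400),
            region("intron", "chr1", 2_000, 2_500),
            region("up", "chr1", 500, 900),
            region("desert", "chr1", 50_000, 51_000),
        ]
        dist = location_distribution(cnvrs, ANN)
        assert dist["exonic"] == dist["intronic"] == 0.25
        assert dist["upstream"] == dist["intergenic"] == 0.25

    def test_fractions_sum_to_one(self):
        rng = random.Random(7)
        cnvrs = [
            region(f"c{i}", "chr1", s := rng.randrange(0, 50_000), s + 500)
            for i in range(50)
        ]
        dist = location_distribution(cnvrs, ANN)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_all_zero(self):
        dist = location_distribution([], ANN)
        assert set(dist.values()) == {0.0}
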