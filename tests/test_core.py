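"""Window assignment and score computation."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwascore import (
    GwasAssociation,
    ScoreConfig,
    ValidationError,
    assign_windows,
    compute_gwascore,
    high_confidence_regions,
    score_genome,
)
from gwascore.core import ScoreWindow

from conftest import assoc, brute_force_score

CFG = ScoreConfig()


class TestWindowAssignment:
    @pytest.mark.parametrize(
        "pos,expected_index",
        [(1, 0), (100_000, 0), (100_001, 1), (250_000, 2), (200_001, 2)],
    )
    def test_tiling_is_one_based_inclusive(self, pos, expected_index):
        groups = assign_windows([assoc(pos=pos)], CFG)
        assert list(groups) == [("chr1", expected_index)]

    def test_one_group_per_window(self):
        assocs = [assoc(pos=p) for p in range(10_000, 60_000, 10_000)]
        groups = assign_windows(assocs, CFG)
        assert list(groups) == [("chr1", 0)]
        assert len(groups[("chr1", 0)]) == 5

    def test_every_association_lands_exactly_once(self):
        rng = random.Random(5)
        assocs = [
            assoc(study=f"S{rng.randrange(4)}", pos=rng.randrange(1, 10**6))
            for _ in range(300)
        ]
        groups = assign_windows(assocs, CFG)
        assert sum(len(g) for g in groups.values()) == len(assocs)
        for (chrom, widx), group in groups.items():
            for a in group:
                assert a.chrom == chrom
                assert (a.pos - 1) // CFG.window_size == widx

    @pytest.mark.parametrize(
        "bad",
        [
            assoc(pos=0),
            assoc(p=0.0),
            assoc(p=1.5),
            assoc(p=-0.1),
            GwasAssociation("S1", "t", "", 10, 0.5),
        ],
    )
    def test_invalid_records_rejected(self, bad):
        with pytest.raises(ValidationError):
            assign_windows([bad], CFG)

    def test_p_max_filter_drops_weak_hits(self):
        cfg = ScoreConfig(p_max=0.05)
        groups = assign_windows([assoc(p=0.01), assoc(p=0.2)], cfg)
        assert len(groups[("chr1", 0)]) == 1


class TestComputeGwascore:
    def test_single_snp_at_p_one_scores_zero(self):
        w = compute_gwascore([assoc(p=1.0)], CFG)
        assert w.score == 0.0
        assert (w.n_gwas, w.n_snp) == (1, 1)

    def test_printed_normalization_hand_value(self):
        group = [assoc(pos=10, p=1e-4), assoc(pos=20, p=1e-6)]
        w = compute_gwascore(group, CFG)
        # -1 * (-4 - 6) / (0.1 * 2)
        assert w.score == pytest.approx(50.0, rel=1e-12)
        mean_cfg = ScoreConfig(normalization="per_window_mean")
        assert compute_gwascore(group, mean_cfg).score == pytest.approx(5.0)

    def test_second_study_doubles_the_score(self):
        one = [assoc(study="S1", pos=10, p=1e-4), assoc(study="S1", pos=20, p=1e-6)]
        two = one + [
            assoc(study="S2", pos=10, p=1e-4),
            assoc(study="S2", pos=20, p=1e-6),
        ]
        w = compute_gwascore(two, CFG)
        assert (w.n_gwas, w.n_snp) == (2, 4)
        assert w.score == pytest.approx(100.0, rel=1e-12)

    def test_natural_log_base_rescales(self):
        cfg = ScoreConfig(log_base=math.e)
        w = compute_gwascore([assoc(p=1e-4)], cfg)
        assert w.score == pytest.approx(4 * math.log(10) / 0.1)

    def test_mixed_windows_rejected(self):
        with pytest.raises(ValidationError):
            compute_gwascore([assoc(pos=1), assoc(pos=100_001)], CFG)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compute_gwascore([], CFG)

    def test_matches_brute_force_on_random_windows(self):
        rng = random.Random(42)
        for _ in range(200):
            n = rng.randrange(1, 12)
            group = [
                assoc(
                    study=f"S{rng.randrange(4)}",
                    pos=rng.randrange(1, 100_001),
                    p=10 ** rng.uniform(-8, 0),
                )
                for _ in range(n)
            ]
            cfg = ScoreConfig(
                normalization=rng.choice(["as_printed", "per_window_mean"])
            )
            expected = brute_force_score(
                [a.p_value for a in group], [a.study_id for a in group], cfg
            )
            assert compute_gwascore(group, cfg).score == pytest.approx(
                expected, rel=1e-9
            )


class TestScoreGenome:
    def test_empty_input(self):
        assert score_genome([], CFG) == []

    def test_one_window_per_occupied_tile(self):
        assocs = [
            assoc(chrom="chr1", pos=50),
            assoc(chrom="chr1", pos=250_000),
            assoc(chrom="chr2", pos=99),
        ]
        windows = score_genome(assocs, CFG)
        assert [(w.chrom, w.start) for w in windows] == [
            ("chr1", 0),
            ("chr1", 200_000),
            ("chr2", 0),
        ]

    def test_shuffle_invariance(self):
        rng = random.Random(3)
        assocs = [
            assoc(study=f"S{rng.randrange(3)}", chrom=f"chr{rng.randrange(1, 4)}",
                  pos=rng.randrange(1, 10**6), p=10 ** rng.uniform(-6, 0))
            for _ in range(120)
        ]
        base = score_genome(assocs, CFG)
        shuffled = assocs[:]
        rng.shuffle(shuffled)
        assert score_genome(shuffled, CFG) == base

    def test_snp_counts_partition_the_input(self):
        rng = random.Random(9)
        assocs = [assoc(pos=rng.randrange(1, 10**6)) for _ in range(77)]
        assert sum(w.n_snp for w in score_genome(assocs, CFG)) == 77

    def test_terminal_window_truncated_by_chrom_length(self):
        windows = score_genome([assoc(pos=250_000)], CFG, {"chr1": 260_000})
        assert windows[0].end == 260_000
        untouched = score_genome([assoc(pos=250_000)], CFG)
        assert untouched[0].end == 300_000


class TestHighConfidenceRegions:
    def _win(self, score, start=0):
        return ScoreWindow("chr1", start, start + 100_000, 1, 1, score)

    def test_zero_scores_yield_nothing(self):
        assert high_confidence_regions([self._win(0.0)], CFG) == []

    def test_threshold_comparison_is_strict(self):
        cfg = ScoreConfig(score_threshold=6.0)
        wins = [self._win(s, i * 100_000) for i, s in enumerate([5.9, 6.0, 6.1])]
        kept = high_confidence_regions(wins, cfg)
        assert [w.score for w in kept] == [6.1]

    def test_regions_are_single_windows_with_additive_coverage(self):
        wins = [self._win(1.0 + i, i * 100_000) for i in range(190)]
        regions = high_confidence_regions(wins, CFG)
        assert len(regions) == 190
        assert sum(r.end - r.start for r in regions) == 19_000_000


# ---------------------------------------------------------------------------
# score invariants

p_values = st.floats(min_value=1e-30, max_value=1.0, exclude_min=True)
windows = st.lists(
    st.tuples(st.sampled_from(["S1", "S2", "S3"]), p_values), min_size=1, max_size=20
)


def _group(pairs):
    return [assoc(study=s, pos=i + 1, p=p) for i, (s, p) in enumerate(pairs)]


@given(windows)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_algebraic_identity_with_mean_neg_log10(pairs):
    """as-printed score == 10 * n_gwas * mean(-log10 P) for base 10."""
    group = _group(pairs)
    w = compute_gwascore(group, CFG)
    mean_nl = sum(-math.log10(p) for _s, p in pairs) / len(pairs)
    assert w.score == pytest.approx(10 * w.n_gwas * mean_nl, rel=1e-9, abs=1e-12)


@given(windows)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_duplicating_under_new_study_doubles_score(pairs):
    group = _group(pairs)
    clone = [
        assoc(study=a.study_id + "_dup", pos=a.pos, p=a.p_value) for a in group
    ]
    doubled = compute_gwascore(group + clone, CFG)
    base = compute_gwascore(group, CFG)
    assert doubled.n_gwas == 2 * base.n_gwas
    assert doubled.score == pytest.approx(2 * base.score, rel=1e-9, abs=1e-12)


@given(p_values, st.integers(min_value=1, max_value=30))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_equal_p_values_make_score_independent_of_snp_count(p, n):
    """Mean invariance: n identical SNPs score like one."""
    one = compute_gwascore(_group([("S1", p)]), CFG)
    many = compute_gwascore(_group([("S1", p)] * n), CFG)
    assert many.score == pytest.approx(one.score, rel=1e-9, abs=1e-12)


@given(windows, st.data())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_decreasing_any_p_never_decreases_score(pairs, data):
    group = _group(pairs)
    idx = data.draw(st.integers(min_value=0, max_value=len(pairs) - 1))
    factor = data.draw(st.floats(min_value=0.01, max_value=1.0))
    target = group[idx]
    lowered = group[:idx] + [
        assoc(study=target.study_id, pos=target.pos, p=target.p_value * factor)
    ] + group[idx + 1:]
    assert compute_gwascore(lowered, CFG).score >= compute_gwascore(
        group, CFG
    ).score - 1e-12
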