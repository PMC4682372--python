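import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subsetq.scoring import min_quality
from subsetq.selection import (
    SelectionReport,
    ThresholdSpec,
    filter_minq,
    filter_pe,
    filter_productq,
    filter_random,
    fraction_for_depth,
    threshold_for_fraction,
)
from subsetq.simulate import QualityModel, generate_read_pairs, generate_reads
from subsetq.stats import ScoreHistogram, chunked_stats, histogram

from .conftest import make_pair, make_read


def enumerate_best_threshold(bins, target):
    """Oracle: try every integer threshold, take the largest keeping >= target."""
    total = sum(bins.values())
    best = None
    for t in range(min(bins), max(bins) + 2):
        kept = sum(c for b, c in bins.items() if b >= t) / total
        if kept >= target:
            best = t
    return best


class TestThresholdSpec:
    def test_valid_modes(self):
        ThresholdSpec("minq", 10)
        ThresholdSpec("productq", 0.5, k=21)
        ThresholdSpec("pe_minq", 21)
        ThresholdSpec("random", 0.3, seed=1)

    @pytest.mark.parametrize(
        "mode,threshold",
        [("minq", 94), ("minq", -1), ("productq", 1.5), ("random", 0.0), ("nope", 1)],
    )
    def test_invalid(self, mode, threshold):
        with pytest.raises(ValueError):
            ThresholdSpec(mode, threshold)


class TestThresholdForFraction:
    def test_exact_half(self):
        bins = {2: 50, 10: 30, 30: 20}
        assert threshold_for_fraction(ScoreHistogram("mqv", bins), 0.5) == 10
        assert enumerate_best_threshold(bins, 0.5) == 10

    def test_keep_all(self):
        bins = {2: 50, 10: 30, 30: 20}
        assert threshold_for_fraction(bins, 1.0) == 2

    def test_single_bin_overshoots(self):
        bins = {30: 100}
        assert threshold_for_fraction(bins, 0.2) == 30
        assert enumerate_best_threshold(bins, 0.2) == 30

    @pytest.mark.parametrize("target", [0.0, -0.5, 1.5])
    def test_bad_target(self, target):
        with pytest.raises(ValueError):
            threshold_for_fraction({2: 1}, target)

    def test_empty_histogram(self):
        with pytest.raises(ValueError):
            threshold_for_fraction({}, 0.5)

    @given(
        st.dictionaries(
            st.integers(0, 93), st.integers(1, 1000), min_size=1, max_size=20
        ),
        st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, bins, target):
        assert threshold_for_fraction(bins, target) == enumerate_best_threshold(
            bins, target
        )


class TestFractionForDepth:
    def test_grouper_style_arithmetic(self):
        assert fraction_for_depth(60, 1.1e9, 125e9) == pytest.approx(0.528)

    def test_clamped_to_one(self):
        assert fraction_for_depth(100, 1000, 1000) == 1.0

    def test_half(self):
        assert fraction_for_depth(0.5, 1000, 1000) == pytest.approx(0.5)

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-1, 1, 1)])
    def test_nonpositive_rejected(self, args):
        with pytest.raises(ValueError):
            fraction_for_depth(*args)


class TestFilterMinq:
    def _reads(self):
        return [make_read(f"r{i}", [q, 40]) for i, q in enumerate([2, 9, 10, 40])]

    def test_threshold_10(self):
        kept, report = filter_minq(self._reads(), 10)
        kept = list(kept)
        assert [r.read_id for r in kept] == ["r2", "r3"]
        assert report.n_in == 4 and report.n_kept == 2
        assert report.kept_fraction == pytest.approx(0.5)

    def test_threshold_0_keeps_all(self):
        kept, report = filter_minq(self._reads(), 0)
        assert len(list(kept)) == 4
        assert report.kept_fraction == 1.0

    def test_order_preserved(self):
        kept, _ = filter_minq(self._reads(), 0)
        assert [r.read_id for r in kept] == ["r0", "r1", "r2", "r3"]

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            filter_minq([], 94)


class TestFilterProductQ:
    def test_boundary_inclusive(self):
        # products: Q10 single base -> 0.9; Q0 -> 0.0
        reads = [
            make_read("low", [0]),       # 0.0
            make_read("edge", [10]),     # 0.9
            make_read("high", [40, 40]),
        ]
        kept, report = filter_productq(reads, 0.9)
        assert [r.read_id for r in kept] == ["edge", "high"]
        assert report.n_kept == 2

    def test_zero_threshold_keeps_all(self):
        reads = [make_read("a", [0]), make_read("b", [40])]
        kept, _ = filter_productq(reads, 0.0)
        assert len(list(kept)) == 2

    def test_threshold_one_keeps_none_with_finite_q(self):
        reads = [make_read("a", [93] * 5)]
        kept, _ = filter_productq(reads, 1.0)
        assert list(kept) == []

    def test_kmer_variant(self):
        # k=1 window on the worst base: Q5 -> 1 - 10**-0.5 ~= 0.6838
        reads = [make_read("a", [40, 5, 40])]
        kept_loose, _ = filter_productq(reads, 0.68, k=1)
        assert len(list(kept_loose)) == 1
        kept_tight, _ = filter_productq([make_read("a", [40, 5, 40])], 0.69, k=1)
        assert list(kept_tight) == []

    def test_bad_k(self):
        with pytest.raises(ValueError):
            filter_productq([], 0.5, k=0)


class TestFilterPe:
    def _pairs(self):
        return [
            make_pair("p0", [20, 40], [30, 40]),
            make_pair("p1", [21, 40], [25, 40]),
            make_pair("p2", [35, 40], [35, 40]),
        ]

    def test_inclusive_threshold(self):
        kept, report = filter_pe(self._pairs(), 21)
        assert [p.pair_id for p in kept] == ["p1", "p2"]
        assert report.n_kept == 2

    def test_strict_threshold(self):
        kept, _ = filter_pe(self._pairs(), 21, strict=True)
        assert [p.pair_id for p in kept] == ["p2"]

    def test_zero_keeps_all(self):
        kept, _ = filter_pe(self._pairs(), 0)
        assert len(list(kept)) == 3

    def test_worst_mate_decides(self):
        pairs = [make_pair("p", [40, 40], [5, 40])]
        kept, _ = filter_pe(pairs, 21)
        assert list(kept) == []

    def test_pair_kept_iff_both_mates_pass_se_filter(self):
        pairs = list(generate_read_pairs(200, 25, QualityModel.low_spike(0.05), seed=9))
        t = 10
        kept_pe, _ = filter_pe(pairs, t)
        kept_ids = {p.pair_id for p in kept_pe}
        for pair in pairs:
            both = min_quality(pair.mate1) >= t and min_quality(pair.mate2) >= t
            assert (pair.pair_id in kept_ids) == both


class TestFilterRandom:
    def test_fraction_one_keeps_all(self):
        reads = [make_read(f"r{i}", [30]) for i in range(10)]
        kept, report = filter_random(reads, 1.0, seed=1)
        assert len(list(kept)) == 10
        assert report.kept_fraction == 1.0

    def test_deterministic_for_seed(self):
        reads = [make_read(f"r{i}", [30]) for i in range(500)]
        a, _ = filter_random(list(reads), 0.4, seed=42)
        b, _ = filter_random(list(reads), 0.4, seed=42)
        assert [r.read_id for r in a] == [r.read_id for r in b]

    def test_different_seeds_differ(self):
        reads = [make_read(f"r{i}", [30]) for i in range(500)]
        a, _ = filter_random(list(reads), 0.4, seed=1)
        b, _ = filter_random(list(reads), 0.4, seed=2)
        assert [r.read_id for r in a] != [r.read_id for r in b]

    def test_fraction_within_binomial_ci(self):
        n, fraction = 20000, 0.3
        reads = (make_read(f"r{i}", [30]) for i in range(n))
        kept, report = filter_random(reads, fraction, seed=5)
        for _ in kept:
            pass
        band = 2.576 * math.sqrt(fraction * (1 - fraction) / n)
        assert abs(report.kept_fraction - fraction) <= band

    @pytest.mark.parametrize("fraction", [0.0, 1.0001, -0.2])
    def test_bad_fraction(self, fraction):
        with pytest.raises(ValueError):
            filter_random([], fraction, seed=0)


class TestReportSerialization:
    def test_as_dict(self):
        report = SelectionReport(mode="minq", threshold=10, n_in=4, n_kept=2)
        d = report.as_dict()
        assert d["kept_fraction"] == 0.5
        assert d["mode"] == "minq"
        assert "seed" not in d


# ---- cross-module consistency --------------------------------------------


def test_filter_counts_match_cumulative_counts():
    reads = list(
        generate_reads(2000, 30, QualityModel.categorical([2, 9, 21, 40], [0.1, 0.3, 0.3, 0.3]), seed=3)
    )
    h, _ = chunked_stats(reads, "mqv")
    for t in range(0, 45):
        expected = sum(c for b, c in h.bins.items() if b >= t)
        kept, report = filter_minq(reads, t)
        for _ in kept:
            pass
        assert report.n_kept == expected, f"t={t}"


def test_monotone_nesting_of_kept_sets():
    reads = list(generate_reads(500, 20, QualityModel.low_spike(0.05), seed=8))
    previous = None
    for t in range(0, 45):
        kept, _ = filter_minq(reads, t)
        ids = {r.read_id for r in kept}
        if previous is not None:
            assert ids <= previous
        previous = ids


def test_threshold_roundtrip_minimal_overshoot():
    reads = list(
        generate_reads(3000, 25, QualityModel.categorical([2, 9, 21, 40], [0.05, 0.45, 0.3, 0.2]), seed=12)
    )
    h, _ = chunked_stats(reads, "mqv")
    for target in (0.1, 0.25, 0.5, 0.9):
        t = threshold_for_fraction(h, target)
        kept, report = filter_minq(reads, t)
        for _ in kept:
            pass
        assert report.kept_fraction >= target
        kept2, report2 = filter_minq(reads, t + 1)
        for _ in kept2:
            pass
        assert report2.kept_fraction < target
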