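import numpy as np
import pytest

from peakreg.formats_io import CoverageTrack, GeneModel, GenomicInterval
from peakreg.super_enhancers import (
    StitchedEnhancer,
    call_supers,
    distal_filter,
    score_stitched,
    stitch,
)

from .conftest import make_peak
from .oracles import brute_call_supers, brute_distal_filter, brute_stitch


def gene(gene_id, chrom, tss):
    return GeneModel(gene_id, GenomicInterval(chrom, tss, tss + 2000, "+"))


class TestDistalFilter:
    def test_threshold_is_strict(self):
        genes = [gene("g", "chr1", 10000)]
        near = make_peak("chr1", 11900, 12100, "near")    # anchor 12000, d=2000
        edge = make_peak("chr1", 12400, 12602, "edge")    # anchor 12501, d=2501
        kept = distal_filter([near, edge], genes)
        assert [p.name for p in kept] == ["edge"]

    def test_matches_brute_force_min_distance(self):
        rng = np.random.default_rng(19)
        genes = [gene(f"g{i}", "chr1", int(t))
                 for i, t in enumerate(rng.integers(0, 80000, size=12))]
        peaks = [make_peak("chr1", int(s), int(s) + 200, f"p{i}")
                 for i, s in enumerate(rng.integers(0, 85000, size=60))]
        kept = {p.name for p in distal_filter(peaks, genes)}
        anchors = [(p.chrom, (p.start + p.end) // 2) for p in peaks]
        tss = [(g.chrom, g.tss) for g in genes]
        expected = {peaks[i].name for i in brute_distal_filter(anchors, tss, 2500)}
        assert kept == expected


class TestStitch:
    def test_hand_chained_example(self):
        peaks = [make_peak("chr1", 0, 100, "a"), make_peak("chr1", 5000, 5100, "b"),
                 make_peak("chr1", 20000, 20100, "c")]
        regions = stitch(peaks)  # gaps 4,900 and 14,900 vs 12,500
        assert [r.constituent_peak_ids for r in regions] == [("a", "b"), ("c",)]
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 5100)

    def test_single_peak_is_its_own_region(self):
        (region,) = stitch([make_peak("chr1", 10, 20, "only")])
        assert region.constituent_peak_ids == ("only",)

    def test_one_chain(self):
        peaks = [make_peak("chr1", i * 1000, i * 1000 + 100, f"p{i}")
                 for i in range(10)]
        assert len(stitch(peaks)) == 1

    def test_idempotent_on_own_spans(self):
        rng = np.random.default_rng(23)
        peaks = [make_peak("chr1", int(s), int(s) + int(rng.integers(50, 500)),
                           f"p{i}")
                 for i, s in enumerate(rng.integers(0, 200000, size=40))]
        once = stitch(peaks)
        spans = [make_peak(r.interval.chrom, r.interval.start, r.interval.end,
                           f"s{i}") for i, r in enumerate(once)]
        twice = stitch(spans)
        assert [(r.interval.start, r.interval.end) for r in twice] == \
            [(r.interval.start, r.interval.end) for r in once]

    def test_region_count_non_increasing_in_distance(self):
        rng = np.random.default_rng(29)
        peaks = [make_peak("chr1", int(s), int(s) + 100, f"p{i}")
                 for i, s in enumerate(rng.integers(0, 300000, size=50))]
        counts = [len(stitch(peaks, d)) for d in (0, 1000, 5000, 12500, 50000)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_chaining(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            peaks = [
                make_peak(str(rng.choice(["chr1", "chr2"])), int(s),
                          int(s) + int(rng.integers(1, 400)), f"p{i}")
                for i, s in enumerate(rng.integers(0, 60000,
                                                   size=int(rng.integers(1, 30))))
            ]
            distance = int(rng.integers(0, 15000))
            got = [set(r.constituent_peak_ids) for r in stitch(peaks, distance)]
            intervals = [(p.chrom, p.start, p.end) for p in peaks]
            expected = [
                {peaks[i].name for i in group}
                for group in brute_stitch(intervals, distance)
            ]
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


class TestScoreStitched:
    def test_input_subtraction_and_floor(self):
        region = StitchedEnhancer(
            GenomicInterval("chr1", 0, 1000), ("p",),
            (GenomicInterval("chr1", 0, 1000),))
        chip = CoverageTrack({"chr1": [(0, 1000, 10.0)]}, 1e6)
        weak = CoverageTrack({"chr1": [(0, 1000, 2.0)]}, 1e6)
        strong = CoverageTrack({"chr1": [(0, 1000, 50.0)]}, 1e6)
        (scored,) = score_stitched([region], chip, weak)
        chip_rpkm = 10.0 * 1000 / ((1000 / 1000) * (1e6 / 1e6))
        assert scored.signal == pytest.approx(chip_rpkm - 2.0 * 1000)
        (floored,) = score_stitched([region], chip, strong)
        assert floored.signal == 0.0

    def test_extensive_in_constituents(self):
        # two constituents of equal density outrank one of the same density
        single = StitchedEnhancer(GenomicInterval("chr1", 0, 500), ("a",),
                                  (GenomicInterval("chr1", 0, 500),))
        double = StitchedEnhancer(
            GenomicInterval("chr1", 2000, 4500), ("b", "c"),
            (GenomicInterval("chr1", 2000, 2500),
             GenomicInterval("chr1", 4000, 4500)))
        chip = CoverageTrack({"chr1": [(0, 10000, 4.0)]}, 1e6)
        inp = CoverageTrack({"chr1": [(0, 10000, 1.0)]}, 1e6)
        one, two = score_stitched([single, double], chip, inp)
        assert two.signal == pytest.approx(2 * one.signal)


class TestCallSupers:
    def _regions(self, signals):
        return [
            StitchedEnhancer(GenomicInterval("chr1", 1000 * i, 1000 * i + 100),
                             (f"p{i}",), signal=float(s))
            for i, s in enumerate(signals)
        ]

    def test_single_outlier_is_the_super(self):
        ranked, cutoff = call_supers(self._regions([1, 2, 3, 4, 100]))
        assert [r.is_super for r in ranked] == [False] * 4 + [True]
        assert cutoff == 100.0

    def test_constant_signals_give_no_supers(self):
        ranked, cutoff = call_supers(self._regions([5, 5, 5, 5]))
        assert not any(r.is_super for r in ranked)
        assert np.isnan(cutoff)

    def test_empty_and_singleton(self):
        assert call_supers([]) == ([], pytest.approx(float("nan"), nan_ok=True))
        ranked, _ = call_supers(self._regions([3]))
        assert len(ranked) == 1 and not ranked[0].is_super

    def test_super_set_upward_closed(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            signals = rng.uniform(0, 100, size=int(rng.integers(2, 30)))
            ranked, _ = call_supers(self._regions(signals))
            super_signals = [r.signal for r in ranked if r.is_super]
            if super_signals:
                threshold = min(super_signals)
                assert all(r.is_super for r in ranked if r.signal >= threshold)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(47)
        for _ in range(300):
            n = int(rng.integers(2, 40))
            signals = np.round(rng.uniform(0, 50, size=n), 3)
            ranked, cutoff = call_supers(self._regions(signals))
            expected_flags, expected_cutoff = brute_call_supers(list(signals))
            assert [r.is_super for r in ranked] == expected_flags
            if np.isnan(expected_cutoff):
                assert np.isnan(cutoff)
            else:
                assert cutoff == pytest.approx(expected_cutoff)

    def test_ranks_are_unique_and_ascending(self):
        ranked, _ = call_supers(self._regions([5, 1, 3, 3, 2]))
        assert [r.rank for r in ranked] == [0, 1, 2, 3, 4]
        assert all(ranked[i].signal <= ranked[i + 1].signal for i in range(4))
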