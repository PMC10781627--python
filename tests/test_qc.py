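import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ibdstruct import (IBDSegment, compute_pileup, detect_excess_regions,
                       filter_segments, remove_excess, sharing_matrix,
                       uniform_map)
from ibdstruct.qc import ExcessRegion, PileupProfile, merge_intervals


def toy_map(n_bp=10_000, cm=100.0):
    return uniform_map(1, n_bp, cm)


def toy_seg(start, end, gmap, a="s1", b="s2", lod=10.0):
    return IBDSegment(a, b, "1", start, end, gmap.segment_cm("1", start, end), lod)


def brute_force_pileup(segments, gmap, long_cm=10.0):
    """Per-base oracle: count qualifying segments covering every base."""
    counts = np.zeros(gmap.chrom_bp("1"), dtype=int)
    for s in segments:
        if s.length_cm > long_cm:
            counts[s.start_bp:s.end_bp] += 1
    return counts


class TestFilterSegments:
    def test_boundary_inclusive(self, unimap, seg_factory):
        seg = seg_factory(start=0, end=2_000_000, lod=3.0)  # exactly 2 cM, LOD 3
        assert filter_segments([seg]) == [seg]

    def test_low_lod_removed_despite_length(self, unimap, seg_factory):
        seg = seg_factory(start=0, end=10_000_000, lod=2.9)
        assert filter_segments([seg]) == []

    def test_counts_on_mixed_fixture(self, seg_factory):
        segs = [
            seg_factory(start=0, end=2_000_000, lod=3.0),    # keep (both at bound)
            seg_factory(start=0, end=1_999_999, lod=9.0),    # too short
            seg_factory(start=0, end=30_000_000, lod=2.99),  # low LOD
            seg_factory(start=0, end=5_000_000, lod=4.0),    # keep
            seg_factory(start=0, end=1_000_000, lod=2.0),    # fails both
        ]
        assert len(filter_segments(segs)) == 2

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            filter_segments([], min_lod=-1.0)


class TestPileup:
    def test_no_long_segments_all_zero(self):
        gmap = toy_map()
        segs = [toy_seg(0, 500, gmap)]  # 5 cM, below the long class
        pileup = compute_pileup(segs, gmap)
        assert all((c == 0).all() for c in pileup.counts.values())

    def test_three_identical_segments_stack(self):
        gmap = toy_map()
        segs = [toy_seg(2000, 4000, gmap, a=f"a{i}", b=f"b{i}") for i in range(3)]
        pileup = compute_pileup(segs, gmap)
        assert pileup.count_at("1", 3000) == 3
        assert pileup.count_at("1", 1999) == 0
        assert pileup.count_at("1", 4000) == 0  # half-open end

    def test_matches_per_base_oracle_on_staircase(self):
        gmap = toy_map()
        segs = [toy_seg(i * 500, i * 500 + 3000, gmap, a=f"a{i}", b=f"b{i}")
                for i in range(4)]
        pileup = compute_pileup(segs, gmap)
        oracle = brute_force_pileup(segs, gmap)
        for pos in range(0, 10_000, 7):
            assert pileup.count_at("1", pos) == oracle[pos]

    def test_unknown_chromosome_rejected(self):
        gmap = toy_map()
        stray = IBDSegment("s1", "s2", "2", 0, 2000, 20.0, 10.0)
        with pytest.raises(ValueError):
            compute_pileup([stray], gmap)


class TestExcessRegions:
    def test_constant_profile_yields_nothing(self):
        pileup = PileupProfile(
            breakpoints={"1": np.array([0, 10_000])},
            counts={"1": np.array([1])},
        )
        assert detect_excess_regions(pileup) == []

    def test_two_level_spike_flagged_exactly(self):
        # count 1 everywhere except a 200 bp window (2% of mass) at 100:
        # trimming 3% per tail removes the whole spike from the statistic,
        # so m = 1, s = 0 and only the window exceeds m + 10 s
        pileup = PileupProfile(
            breakpoints={"1": np.array([0, 4000, 4200, 10_000])},
            counts={"1": np.array([1, 100, 1])},
        )
        (region,) = detect_excess_regions(pileup)
        assert (region.start_bp, region.end_bp) == (4000, 4200)
        assert region.peak_count == 100
        assert region.threshold == pytest.approx(1.0)

    def test_separated_spikes_stay_separate(self):
        pileup = PileupProfile(
            breakpoints={"1": np.array([0, 1000, 1100, 5000, 5100, 10_000])},
            counts={"1": np.array([1, 100, 1, 100, 1])},
        )
        regions = detect_excess_regions(pileup)
        assert len(regions) == 2

    def test_empty_pileup_rejected(self):
        pileup = PileupProfile(breakpoints={"1": np.array([0, 100])},
                               counts={"1": np.array([0])})
        detect_excess_regions(pileup)  # zero counts are fine ...
        with pytest.raises(ValueError):
            detect_excess_regions(PileupProfile(breakpoints={}, counts={}))


class TestRemoveExcess:
    REGION = ExcessRegion("1", 4000, 4200, peak_count=50, threshold=10.0)

    def test_segment_inside_region_removed(self):
        gmap = toy_map()
        assert remove_excess([toy_seg(4050, 4100, gmap)], [self.REGION]) == []

    def test_abutting_segment_kept(self):
        gmap = toy_map()
        segs = [toy_seg(3000, 4000, gmap), toy_seg(4200, 5000, gmap)]
        assert remove_excess(segs, [self.REGION]) == segs

    def test_one_bp_overlap_removes(self):
        gmap = toy_map()
        assert remove_excess([toy_seg(3000, 4001, gmap)], [self.REGION]) == []

    def test_hand_enumerated_mix(self):
        gmap = toy_map()
        overlapping = [toy_seg(4000 + 10 * i, 4300 + 10 * i, gmap) for i in range(4)]
        clean = [toy_seg(i * 100, i * 100 + 50, gmap) for i in range(6)]
        kept = remove_excess(clean + overlapping, [self.REGION])
        assert kept == clean

    def test_idempotent(self):
        gmap = toy_map()
        segs = [toy_seg(0, 3000, gmap), toy_seg(4100, 6000, gmap)]
        once = remove_excess(segs, [self.REGION])
        assert remove_excess(once, [self.REGION]) == once


class TestSharingMatrix:
    def test_simple_fraction(self):
        gmap = uniform_map(35, 100_000_000, 100.0)  # 3,500 cM genome
        seg = IBDSegment("s1", "s2", "1", 0, 35_000_000,
                         gmap.segment_cm("1", 0, 35_000_000), 10.0)
        m = sharing_matrix([seg], gmap, ["s1", "s2"])
        assert m.values[0, 1] == pytest.approx(0.01)
        assert m.values[1, 0] == m.values[0, 1]
        assert m.values[0, 0] == 0.0

    def test_overlapping_same_pair_segments_are_unioned(self):
        gmap = toy_map(10_000, 100.0)
        segs = [toy_seg(0, 1000, gmap), toy_seg(500, 1500, gmap)]
        m = sharing_matrix(segs, gmap, ["s1", "s2"])
        assert m.values[0, 1] == pytest.approx(15.0 / 100.0)  # union, not 20

    def test_full_genome_duplicate_caps_at_one(self):
        gmap = toy_map()
        m = sharing_matrix([toy_seg(0, 10_000, gmap)], gmap, ["s1", "s2"])
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_hbd_segments_excluded(self):
        gmap = toy_map()
        m = sharing_matrix([toy_seg(0, 5000, gmap, a="s1", b="s1")],
                           gmap, ["s1", "s2"])
        assert m.values.sum() == 0.0

    def test_unknown_sample_rejected(self):
        gmap = toy_map()
        with pytest.raises(ValueError):
            sharing_matrix([toy_seg(0, 5000, gmap)], gmap, ["s1"])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(start=st.integers(0, 8000), span=st.integers(2, 2000),
           cut=st.floats(0.1, 0.9))
    def test_invariant_to_splitting_a_segment(self, start, span, cut):
        gmap = toy_map()
        end = start + span
        mid = min(max(start + 1, start + int(span * cut)), end - 1)
        whole = sharing_matrix([toy_seg(start, end, gmap)], gmap, ["s1", "s2"])
        split = sharing_matrix(
            [toy_seg(start, mid, gmap), toy_seg(mid, end, gmap)],
            gmap, ["s1", "s2"])
        assert split.values[0, 1] == pytest.approx(whole.values[0, 1], abs=1e-12)


def test_full_qc_chain_is_idempotent():
    gmap = toy_map()
    rng = np.random.default_rng(7)
    segs = []
    for i in range(40):
        start = int(rng.integers(0, 9000))
        end = start + int(rng.integers(1, 1000))
        segs.append(toy_seg(start, end, gmap, a=f"a{i % 5}", b=f"b{i % 5}",
                            lod=float(rng.uniform(1, 10))))
    def chain(s):
        f = filter_segments(s, min_cm=1.0)
        regions = detect_excess_regions(compute_pileup(f, gmap))
        return remove_excess(f, regions)
    once = chain(segs)
    assert chain(once) == once


def test_merge_intervals_unions_half_open():
    assert merge_intervals([(0, 10), (10, 20), (25, 30), (26, 28)]) == \
        [(0, 20), (25, 30)]
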