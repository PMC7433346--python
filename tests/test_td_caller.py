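import math

import numpy as np
import pytest

from tdscan.alignment_io import POST_ALIGNMENT, PRE_ALIGNMENT, SplitSignal
from tdscan.profile_prep import BinProfile
from tdscan.td_caller import (
    TDRegion,
    filter_duplication_like,
    merge_noise_bins,
    read_calls,
    refine_breakpoints,
    write_calls,
    write_vcf,
)


def make_profile(n_bins=20, len_bin=2000, invalid=(), rd_smooth=None):
    starts = np.arange(n_bins) * len_bin
    valid = np.ones(n_bins, bool)
    valid[list(invalid)] = False
    rd = np.full(n_bins, 30.0) if rd_smooth is None else np.asarray(rd_smooth, float)
    return BinProfile(chrom="c", len_bin=len_bin, bin_start=starts,
                      bin_end=starts + len_bin, rd=rd, mq=np.full(n_bins, 60.0),
                      gc=np.full(n_bins, 0.5), valid=valid, rd_smooth=rd)


def split(kind, pos, matched=50, L=100):
    return SplitSignal(chrom="c", pos=pos, kind=kind, matched_len=matched, read_len=L)


class TestMergeNoiseBins:
    def test_coordinate_arithmetic(self):
        regions = merge_noise_bins([5, 6, 7, 12], make_profile())
        assert [(r.start, r.end) for r in regions] == [(10000, 16000), (24000, 26000)]
        assert [r.n_bins for r in regions] == [3, 1]

    def test_empty_and_single(self):
        assert merge_noise_bins([], make_profile()) == []
        (r,) = merge_noise_bins([3], make_profile())
        assert (r.start, r.end) == (6000, 8000) and r.length == 2000

    def test_invalid_gap_bridged(self):
        prof = make_profile(invalid=[6])
        (r,) = merge_noise_bins([5, 7], prof)
        assert (r.start, r.end) == (10000, 16000) and r.n_bins == 2

    def test_valid_gap_not_bridged(self):
        regions = merge_noise_bins([5, 7], make_profile())
        assert len(regions) == 2

    def test_bridging_can_be_disabled(self):
        prof = make_profile(invalid=[6])
        assert len(merge_noise_bins([5, 7], prof, bridge_invalid=False)) == 2

    def test_regions_disjoint_and_sorted(self, rng):
        idx = np.unique(rng.integers(0, 100, 30))
        regions = merge_noise_bins(idx, make_profile(n_bins=100))
        for a, b in zip(regions[:-1], regions[1:]):
            assert a.end <= b.start

    def test_mean_rd_over_member_bins(self):
        rd = np.arange(20, dtype=float)
        (r,) = merge_noise_bins([4, 5], make_profile(rd_smooth=rd))
        assert r.mean_rd == 4.5


class TestRefineBreakpoints:
    def test_post_alignment_sets_low_boundary(self):
        (r,) = refine_breakpoints([TDRegion("c", 10000, 20000)],
                                  [split(POST_ALIGNMENT, 10050)], search_pad=2000)
        assert r.start == 10050 and r.left_support == 1
        assert r.stage == "refined"

    def test_pre_alignment_sets_high_boundary(self):
        # matched segment [15000, 15050): half-open end 15050 = 1-based
        # inclusive position 15049 + 1
        (r,) = refine_breakpoints([TDRegion("c", 10000, 16000)],
                                  [split(PRE_ALIGNMENT, 15000, matched=50)], search_pad=2000)
        assert r.end == 15050 and r.right_support == 1

    def test_no_signals_region_unchanged(self):
        (r,) = refine_breakpoints([TDRegion("c", 10000, 20000)], [], search_pad=2000)
        assert (r.start, r.end) == (10000, 20000)
        assert r.stage == "rough" and r.left_support == 0 and r.right_support == 0

    def test_majority_support_wins(self):
        sigs = [split(POST_ALIGNMENT, 10300)] + [split(POST_ALIGNMENT, 10100)] * 3
        (r,) = refine_breakpoints([TDRegion("c", 10000, 20000)], sigs, search_pad=1000)
        assert r.start == 10100 and r.left_support == 3

    def test_tie_broken_by_proximity_then_coordinate(self):
        sigs = [split(POST_ALIGNMENT, 9900), split(POST_ALIGNMENT, 10100)]
        (r,) = refine_breakpoints([TDRegion("c", 10000, 20000)], sigs, search_pad=1000)
        assert r.start == 9900  # equal support, equal distance -> smaller coord
        sigs = [split(POST_ALIGNMENT, 9900), split(POST_ALIGNMENT, 10050)]
        (r,) = refine_breakpoints([TDRegion("c", 10000, 20000)], sigs, search_pad=1000)
        assert r.start == 10050  # closer candidate wins

    def test_signals_outside_pad_ignored(self):
        sigs = [split(POST_ALIGNMENT, 14000)]
        (r,) = refine_breakpoints([TDRegion("c", 10000, 20000)], sigs, search_pad=1000)
        assert r.start == 10000 and r.left_support == 0

    def test_boundary_never_moves_past_pad(self, rng):
        region = TDRegion("c", 50_000, 70_000)
        sigs = [split(POST_ALIGNMENT, int(p)) for p in rng.integers(48_000, 52_001, 40)]
        sigs += [split(PRE_ALIGNMENT, int(p), matched=60) for p in rng.integers(67_940, 72_001, 40)]
        pad = 2000
        (r,) = refine_breakpoints([region], sorted(sigs, key=lambda s: s.pos), search_pad=pad)
        assert abs(r.start - region.start) <= pad
        assert abs(r.end - region.end) <= pad


class TestFilter:
    def test_disabled_is_identity(self):
        prof = make_profile()
        regions = [TDRegion("c", 0, 2000, mean_rd=1.0)]
        assert filter_duplication_like(regions, prof, enabled=False) == regions

    def test_enabled_keeps_elevated_drops_depressed(self):
        prof = make_profile()  # median rd_smooth = 30
        hi = TDRegion("c", 0, 2000, mean_rd=60.0)
        lo = TDRegion("c", 4000, 6000, mean_rd=15.0)
        assert filter_duplication_like([hi, lo], prof, enabled=True) == [hi]


class TestCallsIO:
    def test_round_trip(self, tmp_path):
        regions = [
            TDRegion("c", 100, 900, stage="refined", n_bins=2, left_support=3,
                     right_support=1, mean_rd=61.25),
            TDRegion("c", 5000, 9000, stage="rough", n_bins=2, mean_rd=45.5),
        ]
        path = tmp_path / "calls.bed"
        write_calls(regions, path)
        assert read_calls(path) == regions

    def test_empty_writes_header_only(self, tmp_path):
        path = tmp_path / "calls.bed"
        write_calls([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")
        assert read_calls(path) == []

    def test_deterministic_ordering(self, tmp_path):
        r1 = TDRegion("c", 5000, 6000, mean_rd=1.0)
        r2 = TDRegion("c", 100, 900, mean_rd=1.0)
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_calls([r1, r2], p1)
        write_calls([r2, r1], p2)
        assert p1.read_text() == p2.read_text()

    def test_vcf_minimal(self, tmp_path):
        path = tmp_path / "calls.vcf"
        write_vcf([TDRegion("c", 99, 200, mean_rd=2.0)], path, contig_lengths={"c": 1000})
        text = path.read_text()
        assert "##fileformat=VCFv4.2" in text
        assert "c\t100\tTD1\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=200" in text


def test_region_validates_span():
    with pytest.raises(ValueError):
        TDRegion("c", 10, 10)
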