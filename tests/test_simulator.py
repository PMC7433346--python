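import numpy as np
import pysam
import pytest

from tdscan.alignment_io import extract_position_signals, extract_split_signals, load_reference
from tdscan.simulator import (
    SimConfig,
    TDEvent,
    TruthSet,
    embed_tds,
    read_truth_bed,
    render_bam,
    simulate_dataset,
    simulate_reference,
    write_truth_bed,
)

SMALL = dict(ref_length=300_000, n_td=2, td_len_range=(3000, 6000),
             telomere_n=2000, edge_margin=5000, min_gap=8000)


class TestReference:
    def test_deterministic_under_seed(self):
        s1, _ = simulate_reference(100_000, seed=7)
        s2, _ = simulate_reference(100_000, seed=7)
        assert np.array_equal(s1, s2)

    def test_gc_target_realized(self):
        seq, track = simulate_reference(100_000, seed=3, gc_target=0.6)
        assert abs(track.base_is_gc.mean() - 0.6) < 0.02

    def test_n_runs_masked_exactly(self):
        _, track = simulate_reference(10_000, seed=0, n_runs=[(100, 50)])
        assert track.n_mask[100:150].all()
        assert track.n_mask.sum() == 50


class TestEmbed:
    def test_donor_length_identity(self):
        ref, _ = simulate_reference(100_000, seed=1)
        cfg = SimConfig(ref_length=100_000, n_td=1, td_len_range=(1000, 1000),
                        dup_count_range=(2, 2), edge_margin=5000, min_gap=1000, seed=5)
        donor, truth = embed_tds(ref, cfg)
        assert donor.size == 100_000 + 2 * 1000
        (ev,) = truth
        assert ev.length == 1000 and ev.n_copies == 2

    def test_event_count_and_copy_range(self):
        ref, _ = simulate_reference(500_000, seed=2)
        cfg = SimConfig(ref_length=500_000, n_td=10, td_len_range=(2000, 5000),
                        edge_margin=5000, min_gap=5000, seed=9)
        _, truth = embed_tds(ref, cfg)
        assert len(truth) == 10
        assert all(1 <= ev.n_copies <= 6 for ev in truth)
        events = list(truth)
        assert all(a.end <= b.start for a, b in zip(events[:-1], events[1:]))

    def test_impossible_placement_errors(self):
        ref, _ = simulate_reference(50_000, seed=0)
        cfg = SimConfig(ref_length=50_000, n_td=30, td_len_range=(2000, 2000),
                        edge_margin=2000, min_gap=2000, seed=0)
        with pytest.raises(RuntimeError):
            embed_tds(ref, cfg, max_tries=200)


class TestTruthBed:
    def test_round_trip(self, tmp_path):
        truth = TruthSet([TDEvent("c", 100, 600, 3), TDEvent("c", 1000, 1400, 1)])
        path = tmp_path / "t.bed"
        write_truth_bed(truth, path)
        assert list(read_truth_bed(path)) == list(truth)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TruthSet([TDEvent("c", 100, 600, 1), TDEvent("c", 500, 900, 1)])


class TestRenderBam:
    @pytest.fixture(scope="class")
    def dataset(self, tmp_path_factory):
        d = tmp_path_factory.mktemp("sim")
        cfg = SimConfig(seed=42, **SMALL)
        return cfg, simulate_dataset(cfg, d)

    def test_deterministic_under_seed(self, tmp_path):
        cfg = SimConfig(seed=11, **SMALL)
        p1 = simulate_dataset(cfg, tmp_path / "a")
        p2 = simulate_dataset(cfg, tmp_path / "b")
        assert list(read_truth_bed(p1["truth"])) == list(read_truth_bed(p2["truth"]))
        with pysam.AlignmentFile(p1["bam"]) as a, pysam.AlignmentFile(p2["bam"]) as b:
            recs_a = [(r.query_name, r.reference_start, r.cigarstring, r.mapping_quality) for r in a]
            recs_b = [(r.query_name, r.reference_start, r.cigarstring, r.mapping_quality) for r in b]
        assert recs_a == recs_b

    def test_depth_conservation(self, dataset):
        cfg, paths = dataset
        ref = load_reference(paths["fasta"], cfg.chrom)
        ps = extract_position_signals(paths["bam"], cfg.chrom, ref)
        aligned = np.nansum(ps.read_count)
        assert abs(aligned - cfg.coverage * cfg.ref_length) / (cfg.coverage * cfg.ref_length) < 0.05

    def test_pure_tumor_single_copy_doubles_depth(self, tmp_path):
        cfg = SimConfig(ref_length=200_000, n_td=1, td_len_range=(10_000, 10_000),
                        dup_count_range=(1, 1), purity=1.0, telomere_n=2000,
                        edge_margin=20_000, min_gap=1000, seed=1)
        paths = simulate_dataset(cfg, tmp_path)
        (ev,) = read_truth_bed(paths["truth"])
        ref = load_reference(paths["fasta"], cfg.chrom)
        ps = extract_position_signals(paths["bam"], cfg.chrom, ref)
        inside = np.nanmean(ps.read_count[ev.start : ev.end])
        mask = np.ones(cfg.ref_length, bool)
        mask[ev.start - 2000 : ev.end + 2000] = False
        mask[ps.read_count != ps.read_count] = False  # NaN telomeres
        outside = ps.read_count[mask].mean()
        assert inside / outside == pytest.approx(2.0, rel=0.1)

    def test_junction_reads_clip_at_true_breakpoints(self, dataset):
        cfg, paths = dataset
        truth = list(read_truth_bed(paths["truth"]))
        splits = extract_split_signals(paths["bam"], cfg.chrom, min_clip_len=10)
        assert splits, "junction reads expected"
        starts = {ev.start for ev in truth}
        ends = {ev.end for ev in truth}
        for sig in splits:
            if sig.kind == "post_alignment":
                assert sig.breakpoint in starts
            else:
                assert sig.breakpoint in ends

    def test_junction_reads_have_single_clip(self, dataset):
        cfg, paths = dataset
        with pysam.AlignmentFile(paths["bam"]) as af:
            for read in af:
                ops = [op for op, _ in read.cigartuples]
                assert ops.count(4) <= 1
                if len(ops) == 2:
                    assert set(ops) == {0, 4}

    def test_purity_zero_has_no_junction_reads(self, tmp_path):
        cfg = SimConfig(seed=5, purity=0.0, **SMALL)
        paths = simulate_dataset(cfg, tmp_path)
        assert extract_split_signals(paths["bam"], cfg.chrom, min_clip_len=1) == []

    def test_fastq_escape_hatch(self, tmp_path):
        cfg = SimConfig(ref_length=50_000, n_td=1, td_len_range=(2000, 2000),
                        coverage=2, telomere_n=1000, edge_margin=5000,
                        min_gap=1000, seed=3)
        paths = simulate_dataset(cfg, tmp_path, fastq=True)
        with open(paths["fastq"]) as fh:
            lines = fh.read().splitlines()
        assert len(lines) % 4 == 0 and len(lines) > 0
        assert lines[0].startswith("@") and set(lines[1]) <= set("ACGTN")
        assert len(lines[1]) == cfg.read_len
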