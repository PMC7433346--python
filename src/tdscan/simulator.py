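"""Synthetic tandem-duplication sequencing data.

Generates a random reference chromosome, a donor genome carrying tandem
duplications, and a coordinate-sorted indexed BAM of single-end reads
whose alignments are rendered analytically — emulating what a short-read
aligner would report without running one:

* reads wholly inside an extra tandem copy map back onto the source
  segment, raising its read depth in proportion to copy count;
* reads spanning a copy junction are written with a clip+match CIGAR
  (yM(L-y)S when the matched prefix is longer, xS(L-x)M otherwise)
  anchored at the true breakpoints;
* mapping quality is degraded inside duplicated spans (multi-mapping
  ambiguity) and high elsewhere.

Tumor purity mixes reads from the donor genome (fraction ``purity``)
with reads from the unmutated reference.  Everything is deterministic
under the configured seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pysam

from .alignment_io import ReferenceTrack

__all__ = [
    "SimConfig",
    "TDEvent",
    "TruthSet",
    "simulate_reference",
    "embed_tds",
    "render_bam",
    "simulate_dataset",
    "write_fasta",
    "write_truth_bed",
    "read_truth_bed",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TDEvent:
    """One embedded tandem duplication: the source segment [start, end)
    on the reference plus the number of extra copies inserted after it."""

    chrom: str
    start: int
    end: int
    n_copies: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Ground-truth TD events, sorted and disjoint."""

    events: list[TDEvent]

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.chrom, e.start))
        for a, b in zip(self.events[:-1], self.events[1:]):
            if a.chrom == b.chrom and a.end > b.start:
                raise ValueError("truth events overlap")

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults describe a desk-scale experiment: a 2 Mb chromosome with 5
    tandem duplications of 2–10 kb and 1–6 extra copies, sequenced to
    30x with 100 bp single-end reads at tumor purity 0.9.  MAPQ is 60
    outside duplicated spans and uniform on [0, 30] inside them.
    """

    ref_length: int = 2_000_000
    chrom: str = "chr1"
    n_td: int = 5
    dup_count_range: tuple[int, int] = (1, 6)
    td_len_range: tuple[int, int] = (2_000, 10_000)
    coverage: float = 30.0
    purity: float = 0.9
    read_len: int = 100
    gc_target: float = 0.5
    telomere_n: int = 10_000                   # N-masked stretch at each end
    n_runs: tuple[tuple[int, int], ...] = ()   # extra (start, length) N stretches
    edge_margin: int = 20_000                  # keep TDs >= telomere + margin from ends
    min_gap: int = 10_000                      # min spacing between TDs
    mapq_normal: int = 60
    mapq_dup_max: int = 30
    with_seq: bool = False                     # write SEQ/QUAL into the BAM
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must lie in [0, 1]")
        if self.td_len_range[0] > self.td_len_range[1] or self.td_len_range[0] < 1:
            raise ValueError("invalid td_len_range")
        if self.dup_count_range[0] > self.dup_count_range[1] or self.dup_count_range[0] < 1:
            raise ValueError("invalid dup_count_range")


def simulate_reference(length: int, seed=None, gc_target: float = 0.5,
                       n_runs: Sequence[tuple[int, int]] = (), chrom: str = "chr1",
                       rng: np.random.Generator | None = None):
    """Random i.i.d. reference sequence with a target GC fraction.

    Returns (sequence as a uint8 byte array, ReferenceTrack).  Optional
    ``n_runs`` inserts stretches of N (unknown bases).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p_gc = gc_target / 2.0
    p_at = (1.0 - gc_target) / 2.0
    seq = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    for start, ln in n_runs:
        if not (0 <= start and start + ln <= length):
            raise ValueError(f"N run ({start}, {ln}) outside the sequence")
        seq[start : start + ln] = ord("N")
    n_mask = seq == ord("N")
    base_is_gc = (seq == ord("G")) | (seq == ord("C"))
    track = ReferenceTrack(chrom=chrom, sequence_length=length,
                           n_mask=n_mask, base_is_gc=base_is_gc)
    return seq, track


def embed_tds(ref_seq: np.ndarray, config: SimConfig,
              rng: np.random.Generator | None = None,
              max_tries: int = 10_000):
    """Place disjoint TDs and build the donor genome.

    Each event duplicates its source segment ``n_copies`` extra times
    immediately after the original, so the donor length is
    ref_length + sum(n_copies_i * length_i).  Returns (donor, truth).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    length = ref_seq.size
    events: list[TDEvent] = []
    lo_len, hi_len = config.td_len_range
    lo_k, hi_k = config.dup_count_range
    margin = config.edge_margin
    tries = 0
    while len(events) < config.n_td:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_td} disjoint TDs after {max_tries} tries; "
                "reduce n_td or td_len_range"
            )
        ln = int(rng.integers(lo_len, hi_len + 1))
        if length - margin - ln <= margin:
            raise RuntimeError("reference too short for the requested TD length")
        s = int(rng.integers(margin, length - margin - ln + 1))
        e = s + ln
        if any(s - config.min_gap < ev.end and e + config.min_gap > ev.start
               for ev in events):
            continue
        k = int(rng.integers(lo_k, hi_k + 1))
        events.append(TDEvent(chrom=config.chrom, start=s, end=e, n_copies=k))
    truth = TruthSet(events)
    parts = []
    prev = 0
    for ev in truth:
        parts.append(ref_seq[prev : ev.end])
        for _ in range(ev.n_copies):
            parts.append(ref_seq[ev.start : ev.end])
        prev = ev.end
    parts.append(ref_seq[prev:])
    donor = np.concatenate(parts)
    return donor, truth


def _donor_segments(truth: TruthSet, ref_length: int):
    """Donor layout as maximal reference-contiguous segments.

    Returns (seg_ref_start, seg_ref_end, donor_offsets) where donor
    coordinates in [offsets[t], offsets[t+1]) map linearly onto
    reference [seg_ref_start[t], seg_ref_end[t]).  Boundaries between
    consecutive segments are the discordant copy junctions: on the
    reference they jump from seg_ref_end[t] back to seg_ref_start[t+1].
    """
    starts, ends = [], []
    prev = 0
    for ev in truth:
        # run ending at this event's end, then (k-1) whole extra copies;
        # the k-th copy is contiguous with the following reference
        starts.append(prev)
        ends.append(ev.end)
        for _ in range(ev.n_copies - 1):
            starts.append(ev.start)
            ends.append(ev.end)
        prev = ev.start
    starts.append(prev)
    ends.append(ref_length)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(ends - starts)])
    return starts, ends, offsets


def render_bam(ref_seq: np.ndarray, truth: TruthSet, config: SimConfig, out_bam,
               rng: np.random.Generator | None = None,
               donor_seq: np.ndarray | None = None,
               fastq_out=None) -> str:
    """Render reads from the reference/donor mixture to a sorted BAM.

    Read count is coverage * ref_length / read_len; a Binomial(purity)
    share comes from the donor genome.  Junction-spanning donor reads
    get the clip+match CIGAR of the longer matched side, anchored at the
    true breakpoint.  Writes ``out_bam`` plus its .bai index and returns
    the path.  ``fastq_out`` additionally emits the raw reads (requires
    sequences, so it implies building them).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.read_len
    ref_len = ref_seq.size
    if L > ref_len:
        raise ValueError("read_len exceeds reference length")
    seg_s, seg_e, offsets = _donor_segments(truth, ref_len)
    donor_len = int(offsets[-1])
    n_reads = int(round(config.coverage * ref_len / L))
    n_donor = int(rng.binomial(n_reads, config.purity))
    n_ref = n_reads - n_donor

    # --- donor reads: map donor start -> (ref pos, cigar shape) ---
    dstart = rng.integers(0, donor_len - L + 1, size=n_donor)
    seg_idx = np.searchsorted(offsets, dstart, side="right") - 1
    off_in_seg = dstart - offsets[seg_idx]
    ref_pos = seg_s[seg_idx] + off_in_seg
    room = offsets[seg_idx + 1] - dstart          # bases until segment end
    spans = room < L                              # crosses a copy junction
    prefix = np.where(spans, room, L).astype(np.int64)

    # alignment position: prefix-matched reads sit at ref_pos; reads
    # whose clipped prefix is shorter than the suffix re-anchor at the
    # next segment's start (the low breakpoint)
    next_start = seg_s[np.minimum(seg_idx + 1, len(seg_s) - 1)]
    use_suffix = spans & (prefix < L - prefix)    # tie -> keep prefix match
    pos = np.where(use_suffix, next_start, ref_pos)
    match_len = np.where(spans, np.where(use_suffix, L - prefix, prefix), L)

    # --- reference (normal contamination) reads: always full match ---
    ref_start = rng.integers(0, ref_len - L + 1, size=n_ref)

    all_pos = np.concatenate([pos, ref_start])
    all_match = np.concatenate([match_len, np.full(n_ref, L, dtype=np.int64)])
    all_prefix = np.concatenate([prefix, np.full(n_ref, L, dtype=np.int64)])
    all_spans = np.concatenate([spans, np.zeros(n_ref, dtype=bool)])
    all_suffix = np.concatenate([use_suffix, np.zeros(n_ref, dtype=bool)])
    all_dstart = np.concatenate([dstart, np.full(n_ref, -1, dtype=np.int64)])

    # MAPQ: degraded for donor-origin reads whose aligned span overlaps a
    # TD source segment (multi-copy sequence in the sampled genome maps
    # ambiguously); reference-origin reads keep full mapping quality
    td_starts = np.asarray([ev.start for ev in truth], dtype=np.int64)
    td_ends = np.asarray([ev.end for ev in truth], dtype=np.int64)
    if td_starts.size:
        j = np.searchsorted(td_ends, all_pos, side="right")
        in_dup = (j < td_starts.size) & (all_pos + all_match > td_starts[np.minimum(j, td_starts.size - 1)])
        in_dup &= all_dstart >= 0
    else:
        in_dup = np.zeros(all_pos.size, dtype=bool)
    mapq = np.where(in_dup,
                    rng.integers(0, config.mapq_dup_max + 1, size=all_pos.size),
                    config.mapq_normal).astype(np.int64)

    order = np.argsort(all_pos, kind="stable")

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": int(ref_len)}],
    })
    need_seq = config.with_seq or fastq_out is not None
    if need_seq and donor_seq is None:
        parts = [ref_seq[s:e] for s, e in zip(seg_s, seg_e)]
        donor_seq = np.concatenate(parts)
    fq = open(fastq_out, "w") if fastq_out is not None else None
    qual_line = "I" * L
    try:
        with pysam.AlignmentFile(os.fspath(out_bam), "wb", header=header) as bam:
            for rank, i in enumerate(order):
                a = pysam.AlignedSegment(header)
                a.query_name = f"r{i}"
                a.flag = 0
                a.reference_id = 0
                a.reference_start = int(all_pos[i])
                a.mapping_quality = int(mapq[i])
                m = int(all_match[i])
                if all_spans[i]:
                    clip = L - m
                    if all_suffix[i]:
                        a.cigartuples = [(4, clip), (0, m)]
                    else:
                        a.cigartuples = [(0, m), (4, clip)]
                else:
                    a.cigartuples = [(0, L)]
                if need_seq:
                    ds = int(all_dstart[i])
                    if ds >= 0:
                        seq = donor_seq[ds : ds + L].tobytes().decode("ascii")
                    else:
                        s0 = int(all_pos[i])
                        seq = ref_seq[s0 : s0 + L].tobytes().decode("ascii")
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array(qual_line)
                    if fq is not None:
                        fq.write(f"@r{i}\n{seq}\n+\n{qual_line}\n")
                bam.write(a)
    finally:
        if fq is not None:
            fq.close()
    pysam.index(os.fspath(out_bam))
    return os.fspath(out_bam)


def write_fasta(seq: np.ndarray, chrom: str, path, width: int = 60) -> None:
    """Write one sequence as uncompressed FASTA."""
    data = seq.tobytes().decode("ascii")
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(data), width):
            fh.write(data[i : i + width] + "\n")


def write_truth_bed(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tn_copies\n")
        for ev in truth:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.n_copies}\n")


def read_truth_bed(path) -> TruthSet:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            events.append(TDEvent(chrom=f[0], start=int(f[1]), end=int(f[2]),
                                  n_copies=int(f[3])))
    return TruthSet(events)


def simulate_dataset(config: SimConfig, outdir, prefix: str = "sim",
                     write_donor: bool = False, fastq: bool = False) -> dict:
    """Full simulation: reference FASTA, truth BED and aligned BAM.

    Returns a dict of output paths.  One RNG drives reference synthesis,
    TD placement and read rendering, so the whole dataset is a pure
    function of the config (including its seed).
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_runs = list(config.n_runs)
    if config.telomere_n > 0:
        # chromosome ends are unassembled in real references; masking them
        # also hides the coverage droop where reads cannot extend past the end
        t = min(config.telomere_n, config.ref_length // 2)
        n_runs += [(0, t), (config.ref_length - t, t)]
    ref_seq, _track = simulate_reference(config.ref_length, gc_target=config.gc_target,
                                         n_runs=n_runs, chrom=config.chrom, rng=rng)
    donor, truth = embed_tds(ref_seq, config, rng=rng)
    paths = {
        "fasta": os.path.join(outdir, f"{prefix}.ref.fa"),
        "truth": os.path.join(outdir, f"{prefix}.truth.bed"),
        "bam": os.path.join(outdir, f"{prefix}.bam"),
    }
    write_fasta(ref_seq, config.chrom, paths["fasta"])
    write_truth_bed(truth, paths["truth"])
    if write_donor:
        paths["donor_fasta"] = os.path.join(outdir, f"{prefix}.donor.fa")
        write_fasta(donor, config.chrom + "_donor", paths["donor_fasta"])
    fastq_out = None
    if fastq:
        fastq_out = paths["fastq"] = os.path.join(outdir, f"{prefix}.fastq")
    render_bam(ref_seq, truth, config, paths["bam"], rng=rng,
               donor_seq=donor if (config.with_seq or fastq) else None,
               fastq_out=fastq_out)
    return paths
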