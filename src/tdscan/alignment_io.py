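"""Reference and alignment-file access.

Reads a FASTA reference and a coordinate-sorted SAM/BAM file and turns
them into the per-position signal tracks and split-read signals consumed
downstream.  All coordinates are 0-based half-open internally; SAM's
1-based positions are converted on read.

Per-base pileup (rather than read-start counting) is used for read depth:
every aligned M base of a retained record increments the position's count,
so a read spanning a bin boundary contributes to both bins.  Positions
whose reference base is N carry no usable signal and are set to NaN; bins
containing them are filtered later.  Low-MAPQ reads are deliberately kept
(no quality filter by default): depressed mapping quality inside repeated
sequence is itself a detection feature.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

__all__ = [
    "ReferenceTrack",
    "PositionSignals",
    "SplitSignal",
    "PRE_ALIGNMENT",
    "POST_ALIGNMENT",
    "load_reference",
    "extract_position_signals",
    "extract_split_signals",
]

PRE_ALIGNMENT = "pre_alignment"    # yM (L-y)S : match first, clip last
POST_ALIGNMENT = "post_alignment"  # xS (L-x)M : clip first, match last

_CIGAR_MATCH = {0, 7, 8}   # M, =, X consume both query and reference
_CIGAR_CLIP = {4, 5}       # S, H
_CIGAR_REF_SKIP = {2, 3}   # D, N consume reference only


@dataclass
class ReferenceTrack:
    """Per-position masks for one reference chromosome."""

    chrom: str
    sequence_length: int
    n_mask: np.ndarray       # bool, True where base is N/n
    base_is_gc: np.ndarray   # bool, True for G/C/g/c

    def __post_init__(self):
        if len(self.n_mask) != self.sequence_length or len(self.base_is_gc) != self.sequence_length:
            raise ValueError("mask length does not match sequence_length")
        if bool(np.any(self.n_mask & self.base_is_gc)):
            raise ValueError("a position cannot be both N and G/C")


@dataclass
class PositionSignals:
    """Per-position read count and mapping-quality track for one chromosome.

    ``read_count`` and ``mq_mean`` are NaN exactly at N positions;
    ``mq_mean`` is 0 at uncovered non-N positions.
    """

    chrom: str
    read_count: np.ndarray   # float (NaN at N positions)
    mq_sum: np.ndarray       # float, sum of MAPQ of covering reads
    mq_mean: np.ndarray      # float, mean MAPQ of covering reads


@dataclass(frozen=True)
class SplitSignal:
    """One clip+match alignment record, classified by clip side.

    ``pos`` is the 0-based leftmost reference position of the matched
    segment.  For a pre-alignment (yM(L-y)S) the implied high breakpoint
    is ``pos + matched_len`` (half-open); for a post-alignment
    (xS(L-x)M) the implied low breakpoint is ``pos`` itself.
    """

    chrom: str
    pos: int
    kind: str               # PRE_ALIGNMENT or POST_ALIGNMENT
    matched_len: int
    read_len: int

    def __post_init__(self):
        if not (0 < self.matched_len < self.read_len):
            raise ValueError("matched_len must satisfy 0 < matched_len < read_len")
        if self.kind not in (PRE_ALIGNMENT, POST_ALIGNMENT):
            raise ValueError(f"unknown split kind {self.kind!r}")

    @property
    def breakpoint(self) -> int:
        """Implied breakpoint, 0-based half-open boundary coordinate."""
        if self.kind == POST_ALIGNMENT:
            return self.pos
        return self.pos + self.matched_len


def load_reference(fasta_path: str, chrom: str) -> ReferenceTrack:
    """Load one chromosome from a FASTA and compute N / GC masks."""
    with pysam.FastaFile(os.fspath(fasta_path)) as fa:
        if chrom not in fa.references:
            raise ValueError(
                f"chromosome {chrom!r} not found in {fasta_path}; "
                f"available: {', '.join(fa.references)}"
            )
        seq = fa.fetch(chrom).upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_mask = arr == ord("N")
    base_is_gc = (arr == ord("G")) | (arr == ord("C"))
    return ReferenceTrack(chrom=chrom, sequence_length=arr.size,
                          n_mask=n_mask, base_is_gc=base_is_gc)


def _open_alignment(path: str) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(os.fspath(path))


def _check_sorted(af: pysam.AlignmentFile, path: str) -> None:
    so = (af.header.get("HD") or {}).get("SO")
    if so is not None and so != "coordinate":
        raise ValueError(
            f"{path} is not coordinate-sorted (SO:{so}); "
            "run `samtools sort` and `samtools index` first"
        )


def _iter_chrom(af: pysam.AlignmentFile, chrom: str, path: str) -> Iterator[pysam.AlignedSegment]:
    if chrom not in af.references:
        raise ValueError(
            f"chromosome {chrom!r} not found in {path}; "
            f"available: {', '.join(af.references)}"
        )
    if af.is_bam or af.is_cram:
        try:
            yield from af.fetch(chrom)
            return
        except ValueError as exc:
            raise ValueError(
                f"{path} has no index; run `samtools index` (and `samtools sort` "
                "first if the file is unsorted)"
            ) from exc
    # SAM text: stream and filter
    for read in af:
        if read.reference_name == chrom:
            yield read


def _skip(read: pysam.AlignedSegment) -> bool:
    return (read.is_unmapped or read.is_secondary or read.is_supplementary
            or read.is_duplicate)


def extract_position_signals(bam_path: str, chrom: str, ref: ReferenceTrack) -> PositionSignals:
    """Per-base pileup of read count and summed MAPQ over one chromosome.

    Every M/=/X base of each retained record (primary, mapped,
    non-duplicate) increments ``read_count`` and adds the record's MAPQ
    to ``mq_sum``.  N positions are set to NaN regardless of coverage.
    """
    length = ref.sequence_length
    read_count = np.zeros(length, dtype=np.float64)
    mq_sum = np.zeros(length, dtype=np.float64)
    with _open_alignment(bam_path) as af:
        _check_sorted(af, bam_path)
        for read in _iter_chrom(af, chrom, bam_path):
            if _skip(read):
                continue
            mapq = read.mapping_quality
            pos = read.reference_start
            for op, ln in read.cigartuples or ():
                if op in _CIGAR_MATCH:
                    s = max(pos, 0)
                    e = min(pos + ln, length)
                    if e > s:
                        read_count[s:e] += 1.0
                        mq_sum[s:e] += mapq
                    pos += ln
                elif op in _CIGAR_REF_SKIP:
                    pos += ln
                # I/S/H/P consume no reference
    with np.errstate(invalid="ignore", divide="ignore"):
        mq_mean = np.where(read_count > 0, mq_sum / np.maximum(read_count, 1.0), 0.0)
    read_count[ref.n_mask] = np.nan
    mq_mean = mq_mean.astype(np.float64)
    mq_mean[ref.n_mask] = np.nan
    return PositionSignals(chrom=chrom, read_count=read_count, mq_sum=mq_sum, mq_mean=mq_mean)


def extract_split_signals(bam_path: str, chrom: str, min_clip_len: int = 10) -> list[SplitSignal]:
    """Collect clip+match split alignments for breakpoint refinement.

    Only records whose CIGAR is exactly two operations — one clip (soft
    or hard) and one match — are used.  Clip-first records are
    post-alignments (they anchor the low boundary at ``pos``); clip-last
    records are pre-alignments (they anchor the high boundary at
    ``pos + matched_len``).  All other CIGAR shapes, and clips shorter
    than ``min_clip_len``, are ignored.
    """
    out: list[SplitSignal] = []
    with _open_alignment(bam_path) as af:
        _check_sorted(af, bam_path)
        for read in _iter_chrom(af, chrom, bam_path):
            if read.is_unmapped or read.is_secondary or read.is_duplicate:
                continue
            cig = read.cigartuples
            if cig is None or len(cig) != 2:
                continue
            (op1, len1), (op2, len2) = cig
            if op1 in _CIGAR_CLIP and op2 in _CIGAR_MATCH:
                kind, clip_len, matched = POST_ALIGNMENT, len1, len2
            elif op1 in _CIGAR_MATCH and op2 in _CIGAR_CLIP:
                kind, clip_len, matched = PRE_ALIGNMENT, len2, len1
            else:
                continue
            if clip_len < min_clip_len:
                continue
            out.append(SplitSignal(chrom=chrom, pos=read.reference_start,
                                   kind=kind, matched_len=matched,
                                   read_len=matched + clip_len))
    out.sort(key=lambda s: (s.pos, s.kind, s.matched_len))
    return out
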