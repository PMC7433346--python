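"""From noise bins to tandem-duplication calls.

Stage one output (DBSCAN noise bins) is merged into rough regions at bin
resolution; stage two snaps each region boundary to the nucleotide level
using split-read evidence: post-alignments (xS(L-x)M) anchor the low
boundary at the matched segment's start, pre-alignments (yM(L-y)S)
anchor the high boundary at the matched segment's end.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import POST_ALIGNMENT, PRE_ALIGNMENT, SplitSignal
from .profile_prep import BinProfile

__all__ = [
    "TDRegion",
    "merge_noise_bins",
    "refine_breakpoints",
    "filter_duplication_like",
    "write_calls",
    "read_calls",
    "write_vcf",
]

STAGE_ROUGH = "rough"
STAGE_REFINED = "refined"


@dataclass(frozen=True)
class TDRegion:
    """One called tandem duplication (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    stage: str = STAGE_ROUGH
    n_bins: int = 0
    left_support: int = 0
    right_support: int = 0
    mean_rd: float = math.nan

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_noise_bins(noise_indices, profile: BinProfile,
                     bridge_invalid: bool = True) -> list[TDRegion]:
    """Merge runs of consecutive noise bins into rough regions.

    Maximal runs of consecutive bin indices become one region spanning
    from the first bin's start to the last bin's end.  Runs separated
    only by invalid (N-filtered) bins are still merged when
    ``bridge_invalid`` is set: a masked gap should not split one event.
    """
    idx = np.asarray(noise_indices, dtype=np.intp)
    if idx.size == 0:
        return []
    if np.any(np.diff(idx) <= 0):
        raise ValueError("noise_indices must be sorted ascending and unique")
    runs: list[list[int]] = [[int(idx[0])]]
    for prev, cur in zip(idx[:-1], idx[1:]):
        gap = np.arange(prev + 1, cur)
        contiguous = cur == prev + 1 or (
            bridge_invalid and gap.size > 0 and not profile.valid[gap].any()
        )
        if contiguous:
            runs[-1].append(int(cur))
        else:
            runs.append([int(cur)])
    regions = []
    rd = profile.rd_smooth if profile.rd_smooth is not None else profile.rd
    for run in runs:
        members = np.asarray(run)
        regions.append(TDRegion(
            chrom=profile.chrom,
            start=int(profile.bin_start[members[0]]),
            end=int(profile.bin_end[members[-1]]),
            stage=STAGE_ROUGH,
            n_bins=members.size,
            mean_rd=float(np.mean(rd[members])),
        ))
    return regions


def _best_candidate(positions: Sequence[int], anchor: int) -> tuple[int, int] | None:
    """Pick the breakpoint candidate: most support, then closest to the
    rough boundary, then smallest coordinate.  Returns (pos, support)."""
    if not positions:
        return None
    counts: dict[int, int] = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    best = min(counts.items(), key=lambda kv: (-kv[1], abs(kv[0] - anchor), kv[0]))
    return best[0], best[1]


def refine_breakpoints(regions: Iterable[TDRegion], splits: Sequence[SplitSignal],
                       search_pad: int) -> list[TDRegion]:
    """Snap rough boundaries to split-read breakpoints.

    For each region [a, b): candidate low boundaries are post-alignment
    positions within ``search_pad`` of a; candidate high boundaries are
    pre-alignment end positions (pos + matched_len, half-open) within
    ``search_pad`` of b.  The candidate with the most supporting signals
    wins.  A side with no candidate keeps its rough coordinate and a
    support count of 0.
    """
    if search_pad < 0:
        raise ValueError("search_pad must be >= 0")
    post = sorted(s.breakpoint for s in splits if s.kind == POST_ALIGNMENT)
    pre = sorted(s.breakpoint for s in splits if s.kind == PRE_ALIGNMENT)
    post_arr = np.asarray(post, dtype=np.int64)
    pre_arr = np.asarray(pre, dtype=np.int64)

    out = []
    for region in regions:
        a, b = region.start, region.end
        lo, hi = np.searchsorted(post_arr, [a - search_pad, a + search_pad + 1])
        left = _best_candidate(post_arr[lo:hi].tolist(), a)
        lo, hi = np.searchsorted(pre_arr, [b - search_pad, b + search_pad + 1])
        right = _best_candidate(pre_arr[lo:hi].tolist(), b)
        new_a, lsupp = (left if left else (a, 0))
        new_b, rsupp = (right if right else (b, 0))
        if new_a >= new_b:
            # degenerate refinement (crossed boundaries): keep rough span
            new_a, new_b, lsupp, rsupp = a, b, 0, 0
        stage = STAGE_REFINED if (lsupp or rsupp) else STAGE_ROUGH
        out.append(replace(region, start=int(new_a), end=int(new_b),
                           stage=stage, left_support=int(lsupp),
                           right_support=int(rsupp)))
    return out


def filter_duplication_like(regions: Iterable[TDRegion], profile: BinProfile,
                            enabled: bool = False) -> list[TDRegion]:
    """Optionally drop regions without elevated read depth.

    Density noise is sign-agnostic, but a tandem duplication raises copy
    number; when enabled, regions whose mean smoothed RD does not exceed
    the genome-wide median of valid bins are discarded.  Disabled by
    default: every noise region is reported as a TD candidate.
    """
    regions = list(regions)
    if not enabled:
        return regions
    rd = profile.rd_smooth if profile.rd_smooth is not None else profile.rd
    med = float(np.median(rd[profile.valid]))
    return [r for r in regions if r.mean_rd > med]


_BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand",
                "left_support", "right_support", "mean_rd", "stage")


def write_calls(regions: Sequence[TDRegion], out_path, fmt: str = "bed") -> None:
    """Write calls as BED6+ (or TSV with the same columns).

    Coordinates are 0-based half-open; score is the merged noise-bin
    count; deterministic (chrom, start) ordering.
    """
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    sep = "\t"
    with open(out_path, "w") as fh:
        fh.write("#" + sep.join(_BED_COLUMNS) + "\n")
        for i, r in enumerate(ordered, start=1):
            fh.write(sep.join([
                r.chrom, str(r.start), str(r.end), f"TD{i}", str(r.n_bins), ".",
                str(r.left_support), str(r.right_support),
                f"{r.mean_rd:.6g}", r.stage,
            ]) + "\n")


def read_calls(path) -> list[TDRegion]:
    """Re-parse a calls BED written by :func:`write_calls`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(TDRegion(
                chrom=f[0], start=int(f[1]), end=int(f[2]), n_bins=int(f[4]),
                left_support=int(f[6]), right_support=int(f[7]),
                mean_rd=float(f[8]), stage=f[9],
            ))
    return out


def write_vcf(regions: Sequence[TDRegion], out_path, contig_lengths: dict | None = None) -> None:
    """Minimal VCF 4.2 with SVTYPE=DUP records (1-based inclusive)."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(ordered, start=1):
            fh.write(f"{r.chrom}\t{r.start + 1}\tTD{i}\tN\t<DUP>\t.\tPASS\t"
                     f"SVTYPE=DUP;END={r.end}\n")
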