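"""End-to-end calling workflow.

Per chromosome: load reference masks -> per-base pileup -> bin features
-> GC correction, TV smoothing, MQ rescaling -> DBSCAN (noise bins are
TD candidates) -> merge into rough regions -> split-read breakpoint
refinement -> optional depth filter -> BED output.  Every stage is a
pure function of its inputs, so a given BAM + config always produces
byte-identical output.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np

from . import alignment_io, profile_prep, td_caller
from .density_cluster import dbscan, noise_bins
from .profile_prep import BinProfile
from .td_caller import TDRegion

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of the calling workflow (defaults as published:
    len_bin 2000, lambda 0.25, eps 0.7, min_pts 4, GC window 0.001)."""

    bam_path: str
    fasta_path: str
    chroms: tuple[str, ...] | None = None   # None -> all BAM chromosomes in the FASTA
    len_bin: int = 2000
    lam: float = 0.25
    eps: float = 0.7
    min_pts: int = 4
    gc_window: float = 0.001
    search_pad: int | None = None           # None -> 2 * len_bin
    min_clip_len: int = 10
    dup_filter: bool = False
    pool_genome: bool = False               # cluster all chromosomes jointly
    neighbors: str = "kdtree"               # or "brute"
    out_prefix: str | None = None
    log_level: str = "INFO"

    @property
    def pad(self) -> int:
        # two bins of slack: a rough boundary can sit one full bin outside
        # the event when a shoulder bin is flagged, plus the in-bin offset
        return 2 * self.len_bin if self.search_pad is None else self.search_pad


@dataclass
class PipelineResult:
    regions: list[TDRegion]
    profiles: dict[str, BinProfile]
    stats: dict[str, dict]

    def regions_for(self, chrom: str) -> list[TDRegion]:
        return [r for r in self.regions if r.chrom == chrom]


def _resolve_chroms(cfg: PipelineConfig) -> list[str]:
    import pysam

    with pysam.AlignmentFile(cfg.bam_path) as af:
        bam_chroms = list(af.references)
    with pysam.FastaFile(cfg.fasta_path) as fa:
        fa_chroms = set(fa.references)
    if cfg.chroms is not None:
        missing = [c for c in cfg.chroms if c not in bam_chroms or c not in fa_chroms]
        if missing:
            raise ValueError(f"chromosome(s) not in both inputs: {', '.join(missing)}")
        return list(cfg.chroms)
    chroms = [c for c in bam_chroms if c in fa_chroms]
    if not chroms:
        raise ValueError("no chromosome shared between BAM and FASTA")
    return chroms


def _atomic_write(path: str, writer) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", suffix=os.path.basename(path))
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full detection + refinement workflow.

    DBSCAN runs per chromosome by default (``pool_genome`` clusters all
    bins jointly instead).  When ``out_prefix`` is set, writes
    ``<prefix>.calls.bed``, ``<prefix>.bins.tsv`` and ``<prefix>.log``
    atomically.
    """
    handlers: list[logging.Handler] = []
    if cfg.out_prefix:
        fh = logging.FileHandler(f"{cfg.out_prefix}.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logging.getLogger("tdscan").addHandler(fh)
        handlers.append(fh)
    logging.getLogger("tdscan").setLevel(cfg.log_level)
    try:
        logger.info("pipeline config: %s", cfg)
        chroms = _resolve_chroms(cfg)
        profiles: dict[str, BinProfile] = {}
        splits_by_chrom: dict[str, list] = {}
        stats: dict[str, dict] = {}

        for chrom in chroms:
            logger.info("[%s] loading reference and extracting signals", chrom)
            ref = alignment_io.load_reference(cfg.fasta_path, chrom)
            ps = alignment_io.extract_position_signals(cfg.bam_path, chrom, ref)
            prof = profile_prep.bin_signals(ps, ref, len_bin=cfg.len_bin)
            profile_prep.preprocess_profile(prof, lam=cfg.lam, gc_window=cfg.gc_window)
            profiles[chrom] = prof
            splits_by_chrom[chrom] = alignment_io.extract_split_signals(
                cfg.bam_path, chrom, min_clip_len=cfg.min_clip_len)
            stats[chrom] = {
                "bins_total": int(prof.n_bins),
                "bins_valid": int(prof.valid.sum()),
                "split_signals": len(splits_by_chrom[chrom]),
            }
            logger.info("[%s] %d bins (%d valid), %d split signals", chrom,
                        prof.n_bins, int(prof.valid.sum()), len(splits_by_chrom[chrom]))

        # clustering: per chromosome (default) or pooled across the genome
        noise_by_chrom: dict[str, np.ndarray] = {}
        if cfg.pool_genome:
            idx_all, pts_all, owner = [], [], []
            for chrom in chroms:
                idx, pts = profiles[chrom].feature_points()
                idx_all.append(idx)
                pts_all.append(pts)
                owner.extend([chrom] * idx.size)
            pts_all = np.vstack(pts_all) if pts_all else np.empty((0, 2))
            labels = dbscan(pts_all, eps=cfg.eps, min_pts=cfg.min_pts,
                            neighbors=cfg.neighbors)
            flat_idx = np.concatenate(idx_all) if idx_all else np.empty(0, dtype=int)
            owner = np.asarray(owner)
            nz = labels.noise_mask
            for chrom in chroms:
                sel = nz & (owner == chrom)
                noise_by_chrom[chrom] = np.sort(flat_idx[sel])
        else:
            for chrom in chroms:
                idx, pts = profiles[chrom].feature_points()
                if pts.shape[0] == 0:
                    noise_by_chrom[chrom] = np.empty(0, dtype=int)
                    continue
                labels = dbscan(pts, eps=cfg.eps, min_pts=cfg.min_pts,
                                neighbors=cfg.neighbors)
                noise_by_chrom[chrom] = noise_bins(labels, bin_indices=idx)

        regions: list[TDRegion] = []
        for chrom in chroms:
            rough = td_caller.merge_noise_bins(noise_by_chrom[chrom], profiles[chrom])
            refined = td_caller.refine_breakpoints(rough, splits_by_chrom[chrom],
                                                   search_pad=cfg.pad)
            kept = td_caller.filter_duplication_like(refined, profiles[chrom],
                                                     enabled=cfg.dup_filter)
            stats[chrom].update({
                "noise_bins": int(len(noise_by_chrom[chrom])),
                "rough_regions": len(rough),
                "refined_regions": len(kept),
            })
            logger.info("[%s] %d noise bins -> %d rough -> %d final regions",
                        chrom, len(noise_by_chrom[chrom]), len(rough), len(kept))
            regions.extend(kept)
        regions.sort(key=lambda r: (r.chrom, r.start, r.end))

        if cfg.out_prefix:
            _atomic_write(f"{cfg.out_prefix}.calls.bed",
                          lambda p: td_caller.write_calls(regions, p))
            import pandas as pd

            frames = [profiles[c].to_dataframe() for c in chroms]
            _atomic_write(
                f"{cfg.out_prefix}.bins.tsv",
                lambda p: pd.concat(frames, ignore_index=True).to_csv(
                    p, sep="\t", index=False, float_format="%.6g"),
            )
        return PipelineResult(regions=regions, profiles=profiles, stats=stats)
    finally:
        for h in handlers:
            logging.getLogger("tdscan").removeHandler(h)
            h.close()
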