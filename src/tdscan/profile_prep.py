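"""Bin-level feature profile: binning, GC correction, smoothing, scaling.

Pipeline order: per-position signals are averaged into fixed-width bins
(read depth RD_i and mapping quality MQ_i), both tracks are corrected
for GC-content bias by median matching within narrow GC strata, both are
smoothed with exact 1D total-variation denoising, and finally the
mapping-quality track is affinely rescaled onto the range of the
read-depth track so that Euclidean distances in the (RD, MQ) plane weight
the two features comparably.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import PositionSignals, ReferenceTrack
from .tv_denoise import tv_smooth

__all__ = ["BinProfile", "bin_signals", "gc_correct", "normalize_mq", "preprocess_profile"]

logger = logging.getLogger(__name__)


@dataclass
class BinProfile:
    """Per-bin feature matrix for one chromosome.

    Raw fields (``rd``, ``mq``, ``gc``) are filled by :func:`bin_signals`;
    processed fields (``rd_corr`` ... ``mq_norm``) by
    :func:`preprocess_profile`.  Invalid bins (any N position) hold NaN
    in every signal column and are excluded from all statistics.
    """

    chrom: str
    len_bin: int
    bin_start: np.ndarray
    bin_end: np.ndarray
    rd: np.ndarray
    mq: np.ndarray
    gc: np.ndarray
    valid: np.ndarray
    rd_corr: np.ndarray | None = None
    mq_corr: np.ndarray | None = None
    rd_smooth: np.ndarray | None = None
    mq_smooth: np.ndarray | None = None
    mq_norm: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.bin_start.size

    def feature_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Valid-bin indices and their (rd_smooth, mq_norm) points."""
        if self.rd_smooth is None or self.mq_norm is None:
            raise ValueError("profile not preprocessed; call preprocess_profile first")
        idx = np.flatnonzero(self.valid)
        pts = np.column_stack([self.rd_smooth[idx], self.mq_norm[idx]])
        return idx, pts

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "chrom": self.chrom,
            "start": self.bin_start,
            "end": self.bin_end,
            "rd": self.rd,
            "mq": self.mq,
            "gc": self.gc,
            "valid": self.valid.astype(int),
        }
        for name in ("rd_corr", "mq_corr", "rd_smooth", "mq_smooth", "mq_norm"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        return pd.DataFrame(cols)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def bin_signals(ps: PositionSignals, ref: ReferenceTrack, len_bin: int = 2000) -> BinProfile:
    """Average position signals into non-overlapping bins.

    rd_i = mean per-position read count; mq_i = mean per-position mean
    MAPQ; gc_i = GC bases / non-N bases.  Bins containing any N position
    are marked invalid.  A terminal partial bin is kept when it spans at
    least half of ``len_bin``, otherwise dropped.
    """
    if len_bin < 1:
        raise ValueError("len_bin must be >= 1")
    length = ref.sequence_length
    if len_bin > length:
        warnings.warn(
            f"len_bin={len_bin} exceeds chromosome length {length}; using a single bin"
        )
    starts = np.arange(0, length, len_bin, dtype=np.int64)
    ends = np.minimum(starts + len_bin, length)
    if starts.size > 1 and (ends[-1] - starts[-1]) * 2 < len_bin:
        starts, ends = starts[:-1], ends[:-1]

    n = starts.size
    rd = np.empty(n)
    mq = np.empty(n)
    gc = np.empty(n)
    valid = np.empty(n, dtype=bool)
    nm = ref.n_mask
    isgc = ref.base_is_gc
    rc = ps.read_count
    mm = ps.mq_mean
    for i in range(n):
        s, e = starts[i], ends[i]
        has_n = bool(nm[s:e].any())
        valid[i] = not has_n
        if has_n:
            rd[i] = mq[i] = gc[i] = np.nan
            continue
        rd[i] = rc[s:e].mean()
        mq[i] = mm[s:e].mean()
        gc[i] = isgc[s:e].sum() / (e - s)
    return BinProfile(chrom=ps.chrom, len_bin=len_bin, bin_start=starts, bin_end=ends,
                      rd=rd, mq=mq, gc=gc, valid=valid)


def gc_correct(values, gc, window: float = 0.001) -> np.ndarray:
    """GC-bias correction by median matching within GC strata.

    corrected_i = (n / n_GC) * value_i, where n is the global median of
    ``values`` and n_GC is the median over bins whose GC fraction is
    within ``window`` of bin i's.  A stratum with zero median yields a
    corrected value of 0 (with a warning) rather than an infinity.
    """
    values = np.asarray(values, dtype=np.float64)
    gc = np.asarray(gc, dtype=np.float64)
    if values.shape != gc.shape or values.ndim != 1:
        raise ValueError("values and gc must be 1D arrays of the same length")
    if window <= 0:
        raise ValueError("window must be positive")
    if values.size == 0:
        return values.copy()
    n_global = np.median(values)
    order = np.argsort(gc, kind="stable")
    gc_sorted = gc[order]
    val_sorted = values[order]
    # bins with identical GC share a stratum; compute each stratum median once
    uniq, inverse = np.unique(gc, return_inverse=True)
    lo = np.searchsorted(gc_sorted, uniq - window, side="left")
    hi = np.searchsorted(gc_sorted, uniq + window, side="right")
    stratum_median = np.array([np.median(val_sorted[a:b]) for a, b in zip(lo, hi)])
    n_gc = stratum_median[inverse]
    zero = n_gc == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} bin(s) fall in a GC stratum with zero median; "
            "their corrected values are set to 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(zero, 0.0, n_global / np.where(zero, 1.0, n_gc) * values)
    return corrected


def normalize_mq(mq, rd) -> np.ndarray:
    """Affinely rescale the MQ track onto the range of the RD track.

    mq_norm = (mq - mq_min)/(mq_max - mq_min) * (rd_max - rd_min) + rd_min.
    Monotone, so the shape of the MQ distribution is unchanged; only its
    scale is matched to RD so both features contribute comparably to
    Euclidean distances.  Degenerate case (all MQ equal): every value
    maps to the midpoint of the RD range, with a warning.
    """
    mq = np.asarray(mq, dtype=np.float64)
    rd = np.asarray(rd, dtype=np.float64)
    if mq.size == 0:
        return mq.copy()
    rd_min, rd_max = float(rd.min()), float(rd.max())
    mq_min, mq_max = float(mq.min()), float(mq.max())
    if mq_max == mq_min:
        warnings.warn("all MQ values identical; mapping to midpoint of RD range")
        return np.full_like(mq, 0.5 * (rd_min + rd_max))
    return (mq - mq_min) / (mq_max - mq_min) * (rd_max - rd_min) + rd_min


def preprocess_profile(profile: BinProfile, lam: float = 0.25,
                       gc_window: float = 0.001) -> BinProfile:
    """GC-correct, TV-smooth and rescale the bin profile in place.

    Operates on valid bins only (invalid bins stay NaN).  The TV penalty
    ``lam`` is one scalar applied to both tracks.  Returns the profile
    for chaining.
    """
    v = profile.valid
    n = profile.n_bins
    for name in ("rd_corr", "mq_corr", "rd_smooth", "mq_smooth", "mq_norm"):
        setattr(profile, name, np.full(n, np.nan))
    if not np.any(v):
        logger.warning("%s: no valid bins; nothing to preprocess", profile.chrom)
        return profile
    profile.rd_corr[v] = gc_correct(profile.rd[v], profile.gc[v], window=gc_window)
    profile.mq_corr[v] = gc_correct(profile.mq[v], profile.gc[v], window=gc_window)
    profile.rd_smooth[v] = tv_smooth(profile.rd_corr[v], lam)
    profile.mq_smooth[v] = tv_smooth(profile.mq_corr[v], lam)
    profile.mq_norm[v] = normalize_mq(profile.mq_smooth[v], profile.rd_smooth[v])
    return profile
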