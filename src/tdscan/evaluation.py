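"""Scoring call sets against ground truth, and cross-method concordance.

A truth region counts as a true positive when a single call covers at
least half of its length (the half-overlap rule).  Matching is greedy by
overlap size and one-to-one: each call certifies at most one truth
region.  Boundary bias is the mean over matched pairs of the average
absolute start/end deviation in bases.

For call sets without ground truth, the overlapping density score
ODS = M_overlap^2 / N_called rewards methods whose calls are corroborated
by other methods without flooding the output: M_overlap is the mean, over
the other methods, of how many of this method's calls they overlap.

The permutation test uses the absolute difference of sample means as the
statistic; the p-value is the fraction of label permutations whose
statistic exceeds the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["EvalResult", "match_calls", "compute_metrics", "ods", "permutation_test"]


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f1: float
    boundary_bias: float   # mean bases over matched boundaries; NaN if no match


def _span(region) -> tuple[str, int, int]:
    """Accept TDRegion-like objects or (chrom, start, end[, ...]) tuples."""
    if hasattr(region, "chrom"):
        return region.chrom, int(region.start), int(region.end)
    chrom, start, end = region[0], int(region[1]), int(region[2])
    return chrom, start, end


def _overlap(a, b) -> int:
    ca, sa, ea = _span(a)
    cb, sb, eb = _span(b)
    if ca != cb:
        return 0
    return max(0, min(ea, eb) - max(sa, sb))


def match_calls(truth: Sequence, calls: Sequence):
    """Greedy one-to-one matching under the half-overlap rule.

    Returns (tp, fp, fn, matching) where matching is a list of
    (truth_index, call_index) pairs.  Candidate pairs require the call
    to cover >= 50% of the truth region; pairs are consumed largest
    overlap first (ties broken by indices) so the result is independent
    of input ordering.
    """
    truth = list(truth)
    calls = list(calls)
    candidates = []
    for ti, t in enumerate(truth):
        _, ts, te = _span(t)
        tlen = te - ts
        for ci, c in enumerate(calls):
            ov = _overlap(t, c)
            if 2 * ov >= tlen and ov > 0:
                candidates.append((ov, ti, ci))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched_t: set[int] = set()
    matched_c: set[int] = set()
    matching: list[tuple[int, int]] = []
    for _, ti, ci in candidates:
        if ti in matched_t or ci in matched_c:
            continue
        matched_t.add(ti)
        matched_c.add(ci)
        matching.append((ti, ci))
    tp = len(matching)
    fp = len(calls) - tp
    fn = len(truth) - tp
    return tp, fp, fn, matching


def compute_metrics(truth: Sequence, calls: Sequence,
                    match_result=None) -> EvalResult:
    """Sensitivity, precision, F1 and boundary bias for one call set.

    ``match_result`` may be the output of :func:`match_calls` to avoid
    recomputation.  Empty denominators yield 0 (not NaN) so the values
    remain plottable; boundary bias is NaN when nothing matched.
    """
    if match_result is None:
        match_result = match_calls(truth, calls)
    tp, fp, fn, matching = match_result
    truth = list(truth)
    calls = list(calls)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    if matching:
        devs = []
        for ti, ci in matching:
            _, ts, te = _span(truth[ti])
            _, cs, ce = _span(calls[ci])
            devs.append((abs(cs - ts) + abs(ce - te)) / 2.0)
        bias = float(np.mean(devs))
    else:
        bias = float("nan")
    return EvalResult(tp=tp, fp=fp, fn=fn, sensitivity=sens, precision=prec,
                      f1=f1, boundary_bias=bias)


def ods(call_sets: Mapping[str, Sequence]) -> dict[str, float]:
    """Overlapping density score per method: M_overlap^2 / N_called.

    A call is "overlapped" by another method when some call of that
    method covers >= 50% of it (the same half-overlap rule used against
    ground truth); M_overlap averages the overlapped-call counts over
    the other methods.
    """
    names = list(call_sets)
    if len(names) < 2:
        raise ValueError("ods needs call sets from at least two methods")
    scores = {}
    for name in names:
        calls = list(call_sets[name])
        n_called = len(calls)
        if n_called == 0:
            warnings.warn(f"method {name!r} made no calls; ODS set to 0")
            scores[name] = 0.0
            continue
        counts = []
        for other in names:
            if other == name:
                continue
            other_calls = list(call_sets[other])
            cnt = 0
            for c in calls:
                _, cs, ce = _span(c)
                clen = ce - cs
                if any(2 * _overlap(c, o) >= clen and _overlap(c, o) > 0
                       for o in other_calls):
                    cnt += 1
            counts.append(cnt)
        m_overlap = float(np.mean(counts))
        scores[name] = m_overlap * m_overlap / n_called
    return scores


def permutation_test(x, y, n_perm: int = 10_000, seed=None,
                     rng: np.random.Generator | None = None) -> float:
    """Two-sample permutation test on |mean(x) - mean(y)|.

    p = #{permuted statistic > observed} / n_perm.  Deterministic under
    ``seed`` (or a supplied generator).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if rng is None:
        rng = np.random.default_rng(seed)
    s_obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    nx = x.size
    # vectorized label permutations
    mat = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    stats = np.abs(mat[:, :nx].mean(axis=1) - mat[:, nx:].mean(axis=1))
    return float(np.count_nonzero(stats > s_obs) / n_perm)
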