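from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def write_sam(path, chrom, chrom_len, reads, sort_order="coordinate"):
    """Write a minimal SAM file.

    ``reads`` is an iterable of (qname, flag, pos_1based, mapq, cigar).
    """
    with open(path, "w") as fh:
        fh.write(f"@HD\tVN:1.6\tSO:{sort_order}\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len}\n")
        for qname, flag, pos, mapq, cigar in reads:
            fh.write(f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*\n")
    return str(path)


def write_fasta(path, chrom, seq):
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def naive_dbscan(pts, eps, min_pts):
    """Independent O(n^2) DBSCAN oracle (labels, core_mask)."""
    n = len(pts)
    pts = np.asarray(pts, float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    adj = d2 <= eps * eps
    core = adj.sum(axis=1) >= min_pts
    labels = np.full(n, -1)
    cid = 0
    for s in range(n):
        if not core[s] or labels[s] != -1:
            continue
        labels[s] = cid
        stack = [s]
        while stack:
            p = stack.pop()
            for q in np.flatnonzero(adj[p]):
                if labels[q] == -1:
                    labels[q] = cid
                    if core[q]:
                        stack.append(int(q))
        cid += 1
    return labels, core


def tv_oracle(b, lam):
    """Independent TV minimizer via the box-constrained dual least squares."""
    from scipy.optimize import lsq_linear

    b = np.asarray(b, float)
    n = b.size
    if n <= 1 or lam == 0:
        return b.copy()
    D = np.diff(np.eye(n), axis=0)
    res = lsq_linear(D.T, b, bounds=(-lam, lam), method="bvls", tol=1e-14)
    return b - D.T @ res.x
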