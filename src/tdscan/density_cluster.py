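"""Density-based clustering (DBSCAN) of 2D bin features.

Each genomic bin contributes one point with coordinates
``(read-depth feature, normalized mapping-quality feature)``.  Bins whose
signals differ from the genomic background form low-density outliers;
DBSCAN labels them noise, and those noise bins are the tandem-duplication
candidates.

Neighborhood searches use an exact 2D k-d tree (a binary search tree that
alternates median splits across the two feature axes, starting on the
mapping-quality axis).  The ε-neighborhood is a closed Euclidean ball and
includes the query point itself, so ``min_pts`` counts the point as its
own neighbor.  A brute-force neighborhood backend is provided as well;
both backends produce identical core-point and noise sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NOISE", "KDTree2D", "ClusterLabels", "build_2dbst", "dbscan", "noise_bins"]

NOISE = -1


@dataclass
class _Leaf:
    indices: np.ndarray


@dataclass
class _Node:
    axis: int
    split: float
    index: int          # index of the pivot point stored at this node
    left: object
    right: object


class KDTree2D:
    """Exact 2D k-d tree with alternating lower-median splits.

    The first split is on the second feature axis (mapping quality), the
    next on the first (read depth), and so on alternately.  Duplicate
    points are retained; the tree is a multiset.
    """

    def __init__(self, points, leaf_size: int = 16):
        pts = np.asarray(points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("KDTree2D expects an (n, 2) array of points")
        if pts.shape[0] == 0:
            raise ValueError("KDTree2D requires at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("KDTree2D requires finite coordinates")
        if leaf_size < 1:
            raise ValueError("leaf_size must be >= 1")
        self.points = pts
        self.leaf_size = leaf_size
        self.root = self._build(np.arange(pts.shape[0]), depth=0)

    @staticmethod
    def _axis(depth: int) -> int:
        # depth 0 splits on axis 1 (mapping quality), then alternates
        return 1 - (depth % 2)

    def _build(self, idx: np.ndarray, depth: int):
        if idx.size <= self.leaf_size:
            return _Leaf(idx)
        axis = self._axis(depth)
        order = idx[np.argsort(self.points[idx, axis], kind="stable")]
        m = (order.size - 1) // 2  # lower median for determinism
        pivot = order[m]
        return _Node(
            axis=axis,
            split=float(self.points[pivot, axis]),
            index=int(pivot),
            left=self._build(order[:m], depth + 1),
            right=self._build(order[m + 1 :], depth + 1),
        )

    def query_radius(self, q, eps: float) -> np.ndarray:
        """Indices of all points within the closed ball of radius eps at q.

        Exact: a subtree is pruned only when the splitting hyperplane is
        farther than eps from the query, so no qualifying point is missed.
        """
        if eps <= 0:
            raise ValueError("eps must be positive")
        q = np.asarray(q, dtype=np.float64)
        eps2 = eps * eps
        out: list[int] = []
        stack = [self.root]
        pts = self.points
        while stack:
            node = stack.pop()
            if isinstance(node, _Leaf):
                if node.indices.size:
                    d2 = np.sum((pts[node.indices] - q) ** 2, axis=1)
                    out.extend(node.indices[d2 <= eps2].tolist())
                continue
            dx = pts[node.index] - q
            if dx[0] * dx[0] + dx[1] * dx[1] <= eps2:
                out.append(node.index)
            diff = q[node.axis] - node.split
            # visit the near side always; the far side only if the
            # splitting plane intersects the closed ball
            if diff <= eps:
                stack.append(node.left)
            if diff >= -eps:
                stack.append(node.right)
        return np.sort(np.asarray(out, dtype=np.intp))


def build_2dbst(points, leaf_size: int = 16) -> KDTree2D:
    """Build the 2D binary search tree over bin feature points."""
    return KDTree2D(points, leaf_size=leaf_size)


@dataclass
class ClusterLabels:
    """Per-point DBSCAN labels: cluster id >= 0, or NOISE (-1)."""

    labels: np.ndarray
    core_mask: np.ndarray
    eps: float
    min_pts: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if self.labels.size else 0

    @property
    def noise_mask(self) -> np.ndarray:
        return self.labels == NOISE

    def point_sets(self) -> dict:
        """Return the core / non-core / noise index partition."""
        idx = np.arange(self.labels.size)
        core = idx[self.core_mask]
        noncore = idx[~self.core_mask & ~self.noise_mask]
        noise = idx[self.noise_mask]
        return {"core": core, "non_core": noncore, "noise": noise}


def _brute_neighborhoods(pts: np.ndarray, eps: float) -> list[np.ndarray]:
    eps2 = eps * eps
    n = pts.shape[0]
    neigh = []
    # blockwise to bound memory for large n
    block = max(1, int(4_000_000 // max(n, 1)))
    for start in range(0, n, block):
        chunk = pts[start : start + block]
        d2 = ((chunk[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        for row in d2:
            neigh.append(np.flatnonzero(row <= eps2))
    return neigh


def dbscan(points, eps: float = 0.7, min_pts: int = 4, neighbors: str = "kdtree",
           leaf_size: int = 16) -> ClusterLabels:
    """Run DBSCAN over 2D points.

    Parameters
    ----------
    points : (n, 2) array
        Bin feature points.
    eps : float
        Neighborhood radius (closed Euclidean ball).  Default 0.7.
    min_pts : int
        Minimum neighborhood size (including the point itself) for a
        core point.  Default 4, twice the number of features.
    neighbors : {"kdtree", "brute"}
        Neighborhood search backend.  Both are exact; results agree.

    Seed points are scanned in ascending point index, so border points
    attach to the first cluster that reaches them and the output is a
    deterministic function of the input.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("dbscan expects an (n, 2) array of points")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    n = pts.shape[0]
    if n == 0:
        z = np.zeros(0, dtype=np.intp)
        return ClusterLabels(labels=z.copy(), core_mask=z.astype(bool), eps=eps, min_pts=min_pts)

    if neighbors == "kdtree":
        tree = KDTree2D(pts, leaf_size=leaf_size)
        neigh = [tree.query_radius(pts[i], eps) for i in range(n)]
    elif neighbors == "brute":
        neigh = _brute_neighborhoods(pts, eps)
    else:
        raise ValueError(f"unknown neighbors backend: {neighbors!r}")

    core = np.fromiter((len(v) >= min_pts for v in neigh), dtype=bool, count=n)
    labels = np.full(n, NOISE, dtype=np.intp)
    cid = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != NOISE:
            continue
        labels[seed] = cid
        stack = [seed]
        while stack:
            p = stack.pop()
            for q in neigh[p]:
                if labels[q] == NOISE:
                    labels[q] = cid
                    if core[q]:
                        stack.append(int(q))
        cid += 1
    return ClusterLabels(labels=labels, core_mask=core, eps=eps, min_pts=min_pts)


def noise_bins(labels: ClusterLabels, bin_indices=None) -> np.ndarray:
    """Bin indices of DBSCAN noise points, ascending.

    ``bin_indices`` maps point order back to bin index (identity when
    omitted); noise points are the tandem-duplication candidate bins.
    """
    where = np.flatnonzero(labels.labels == NOISE)
    if bin_indices is not None:
        where = np.asarray(bin_indices, dtype=np.intp)[where]
    return np.sort(where)
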