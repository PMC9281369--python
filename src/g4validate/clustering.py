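"""Duplex-flexibility clustering.

Frames are aligned on the quadruplex, pairwise RMSD is measured on the
duplex, and hierarchical agglomerative clustering (average linkage by
default) defines the conformational families; representatives are
cluster medoids reported in descending population until a cumulative
coverage (80% by default) is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .core import TrajectorySet
from .observables import superpose


def pairwise_rmsd_matrix(traj: TrajectorySet, align_mask, measure_mask,
                         stride: int = 1) -> np.ndarray:
    """Symmetric RMSD matrix: entry (i, j) superposes frame j onto frame
    i on ``align_mask`` and measures RMSD over ``measure_mask``; the
    matrix is symmetrized by averaging the two orientations."""
    top = traj.topology
    align_idx = top.indices(align_mask)
    measure_idx = top.indices(measure_mask)
    if len(align_idx) == 0 or len(measure_idx) == 0:
        raise ValueError("empty mask")
    frames = traj.coordinates[::stride]
    n = len(frames)
    if n < 2:
        raise ValueError("need at least two frames")
    mat = np.zeros((n, n))
    for i in range(n):
        ref_a = frames[i, align_idx]
        ref_m = frames[i, measure_idx]
        for j in range(n):
            if i == j:
                continue
            (rot, t), _ = superpose(frames[j, align_idx], ref_a)
            moved = frames[j, measure_idx] @ rot.T + t
            mat[i, j] = np.sqrt(np.mean(np.sum((moved - ref_m) ** 2, axis=1)))
    mat = 0.5 * (mat + mat.T)
    return mat


@dataclass
class ClusterSolution:
    labels: np.ndarray          # per-frame cluster id, 0-based
    populations: np.ndarray     # fraction per cluster id
    representatives: np.ndarray  # medoid frame per cluster id
    linkage: np.ndarray | None  # scipy linkage record
    stride: int = 1

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def hierarchical_cluster(matrix: np.ndarray, method: str = "average",
                         n_clusters: int | None = None,
                         distance_cutoff: float | None = None,
                         stride: int = 1) -> ClusterSolution:
    """Agglomerative clustering of a precomputed RMSD matrix.

    Stop either at ``n_clusters`` or at a merge-distance cutoff.  The
    representative of each cluster is its medoid (frame minimizing the
    summed intra-cluster distance; ties broken by lowest frame index).
    """
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    n = matrix.shape[0]
    if (n_clusters is None) == (distance_cutoff is None):
        raise ValueError("give exactly one of n_clusters or distance_cutoff")
    if n_clusters is not None and n_clusters > n:
        raise ValueError(f"n_clusters {n_clusters} exceeds {n} frames")
    if n_clusters == n:
        raw = np.arange(1, n + 1)
        link = None
    else:
        condensed = squareform(matrix, checks=False)
        link = scipy_linkage(condensed, method=method)
        if n_clusters is not None:
            raw = fcluster(link, n_clusters, criterion="maxclust")
        else:
            raw = fcluster(link, distance_cutoff, criterion="distance")
    # relabel clusters 0..k-1 in order of first appearance (determinism)
    labels = np.empty(n, dtype=int)
    mapping: dict = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]
    k = len(mapping)
    populations = np.array([np.mean(labels == c) for c in range(k)])
    reps = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        sums = matrix[np.ix_(members, members)].sum(axis=1)
        reps[c] = members[int(np.argmin(sums))]  # argmin takes the lowest on ties
    return ClusterSolution(labels, populations, reps, link, stride)


def representative_set(solution: ClusterSolution, coverage: float = 0.80) -> pd.DataFrame:
    """Representatives ordered by population until cumulative coverage.

    Returns the smallest population-sorted prefix whose cumulative
    population reaches ``coverage`` (ties broken by earliest
    representative frame index).
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    order = sorted(range(solution.n_clusters),
                   key=lambda c: (-solution.populations[c], solution.representatives[c]))
    rows = []
    cum = 0.0
    for c in order:
        cum += solution.populations[c]
        rows.append({"cluster": c,
                     "representative_frame": int(solution.representatives[c] * solution.stride),
                     "population": float(solution.populations[c]),
                     "cumulative": float(cum)})
        if cum >= coverage - 1e-12:
            break
    return pd.DataFrame(rows, columns=["cluster", "representative_frame",
                                       "population", "cumulative"])
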