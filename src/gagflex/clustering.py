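"""Neighbour-count RMSD clustering of conformational ensembles.

The greedy algorithm of Daura and co-workers: given the matrix of fitted
pairwise RMSDs between all sampled conformations and a cutoff, repeatedly
(1) count, among the frames still unassigned, each frame's neighbours
within the cutoff (a frame is its own neighbour), (2) take the frame with
the most neighbours as a cluster centre (ties broken toward the lowest
frame index), (3) assign it and its neighbours to a new cluster and remove
them from the pool.  The number of clusters found as a function of
trajectory length is a convergence and flexibility diagnostic: the more
clusters, the more flexible the chain.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import rmsd_fitted

DEFAULT_RMSD_CUTOFF = 0.4  # nm; 0.3 and 0.5 are the standard alternatives
RMSD_CUTOFFS = (0.3, 0.4, 0.5)

# pairwise matrices are O(n^2) in memory and time; beyond this many frames
# the caller must opt in explicitly
PAIRWISE_FRAME_LIMIT = 4000


@dataclass(frozen=True)
class ClusterResult:
    """Partition of frames into RMSD-neighbourhood clusters."""

    labels: np.ndarray  # (n_frames,) cluster id, 0-based in discovery order
    centers: np.ndarray  # (n_clusters,) frame index of each cluster centre
    sizes: np.ndarray  # (n_clusters,)
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class ClusterEvolution:
    """Cluster count when only the first t frames are considered."""

    checkpoints: np.ndarray  # strictly increasing frame counts
    n_clusters: np.ndarray


def pairwise_rmsd_matrix(traj, selection=None, *,
                         allow_large: bool = False) -> np.ndarray:
    """Symmetric (n_frames, n_frames) matrix of fitted RMSDs (nm).

    Each entry is the RMSD after optimal rigid superposition of frame i
    onto frame j over ``selection`` (default all atoms).  Frame counts
    above ``PAIRWISE_FRAME_LIMIT`` are refused unless ``allow_large``.
    """
    n = traj.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    if n > PAIRWISE_FRAME_LIMIT and not allow_large:
        raise ValueError(
            f"{n} frames would need a {n}x{n} RMSD matrix; pass "
            "allow_large=True to proceed"
        )
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    X = traj.coords[:, sel, :]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = rmsd_fitted(X[i], X[j])
    return M


def daura_cluster(rmsd_matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbour-count clustering of a pairwise RMSD matrix."""
    M = np.asarray(rmsd_matrix, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("rmsd_matrix must be square")
    if not np.allclose(M, M.T, atol=1e-9):
        raise ValueError("rmsd_matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = M.shape[0]
    adj = M <= cutoff  # includes the diagonal: a frame neighbours itself
    remaining = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    centers, sizes = [], []
    cid = 0
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & remaining)
        labels[members] = cid
        centers.append(center)
        sizes.append(members.size)
        remaining[members] = False
        cid += 1
    return ClusterResult(labels=labels, centers=np.array(centers, int),
                         sizes=np.array(sizes, int), cutoff=cutoff)


def cluster_count_evolution(rmsd_matrix: np.ndarray, cutoff: float,
                            checkpoints) -> ClusterEvolution:
    """Cluster count at each checkpoint t, clustering only frames [0, t)."""
    checkpoints = np.asarray(checkpoints, int)
    if checkpoints.size == 0:
        raise ValueError("checkpoints must be nonempty")
    n = np.asarray(rmsd_matrix).shape[0]
    if (checkpoints < 1).any() or (checkpoints > n).any():
        raise ValueError("checkpoints must lie in [1, n_frames]")
    if (np.diff(checkpoints) <= 0).any():
        raise ValueError("checkpoints must be strictly increasing")
    counts = []
    for t in checkpoints:
        if t == 1:
            counts.append(1)
        else:
            counts.append(daura_cluster(rmsd_matrix[:t, :t], cutoff).n_clusters)
    return ClusterEvolution(checkpoints=checkpoints,
                            n_clusters=np.array(counts, int))
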