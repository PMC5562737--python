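"""RMSD-based conformational clustering of trajectory frames.

Greedy neighbor-count scheme (Daura-style): compute all pairwise RMSDs
over a selection (after per-pair superposition on that selection), then
repeatedly take the unassigned frame with the most unassigned neighbors
within the cutoff as a cluster center, assign those neighbors to it, and
remove them.  Ties in neighbor count break toward the lowest frame index,
so the result is deterministic.  The representative conformation is the
center of the largest cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io import MolecularStructure, TopologyParams, Trajectory
from .observables import Selection, kabsch_superpose

__all__ = ["ClusterResult", "pairwise_rmsd_matrix", "cluster_frames"]


@dataclass
class ClusterResult:
    """Frame-to-cluster assignment with per-cluster representative frames.

    Clusters are ordered by decreasing size (ties by lower center index);
    ``assignments[k]`` is frame k's cluster id, ``representative_frame[c]``
    the center of cluster c.
    """

    assignments: np.ndarray
    representative_frame: list[int]
    cutoff_used: float
    cluster_sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def representative(self) -> int:
        """Frame index of the largest cluster's center."""
        return self.representative_frame[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "cutoff_A": self.cutoff_used,
                "n_clusters": self.n_clusters,
                "cluster_sizes": self.cluster_sizes,
                "representative_frames": self.representative_frame,
                "assignments": self.assignments.tolist(),
            },
            indent=2,
        )


def pairwise_rmsd_matrix(
    traj: Trajectory,
    selection: Selection,
    params: TopologyParams | None = None,
) -> np.ndarray:
    """Symmetric frame-frame RMSD matrix over ``selection``, each pair
    superposed on the same selection before measuring."""
    idx = selection.resolve_nonempty(traj.template, params)
    coords = [f[idx] for f in traj.frames]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(coords[i], coords[j])
            mat[i, j] = mat[j, i] = r
    return mat


def cluster_frames(
    traj: Trajectory,
    selection: Selection | None = None,
    cutoff: float = 2.0,
    params: TopologyParams | None = None,
) -> ClusterResult:
    """Cluster trajectory frames by pairwise RMSD (greedy neighbor count).

    Default selection is Calpha plus ligand heavy atoms when a topology is
    supplied, else Calpha.  Default cutoff 2.0 A.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(traj) < 1:
        raise ValueError("need at least one frame")
    if selection is None:
        selection = Selection.ca()
        if params is not None and params.ligand_selection:
            selection = selection | (Selection.ligand() & Selection.heavy())
    rmsd = pairwise_rmsd_matrix(traj, selection, params)
    n = len(traj)
    unassigned = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    while unassigned.any():
        neighbor = (rmsd <= cutoff) & unassigned[None, :]
        counts = np.where(unassigned, neighbor.sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(neighbor[center] & unassigned)[0]
        cid = len(centers)
        assignments[members] = cid
        unassigned[members] = False
        centers.append(center)
        sizes.append(len(members))
    # reorder clusters by decreasing size, ties by lower center index
    order = sorted(range(len(centers)), key=lambda c: (-sizes[c], centers[c]))
    remap = {old: new for new, old in enumerate(order)}
    assignments = np.array([remap[a] for a in assignments])
    centers = [centers[c] for c in order]
    sizes = [sizes[c] for c in order]
    return ClusterResult(
        assignments=assignments,
        representative_frame=centers,
        cutoff_used=cutoff,
        cluster_sizes=sizes,
    )


def representative_structure(
    traj: Trajectory, result: ClusterResult
) -> MolecularStructure:
    """The largest cluster's center frame as a structure."""
    return traj.frame_structure(result.representative)
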