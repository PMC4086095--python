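"""Redundancy filtering of docked poses by windowed greedy clustering.

Poses are visited in ascending energy order; a pose whose docking-frame
RMSD to any of the most recent ``window`` cluster representatives falls
below the threshold is discarded as redundant, otherwise it founds a
new cluster.  Comparing only against the latest 50 representatives
keeps the procedure O(n) in the number of poses.

RMSD is computed without re-superposition: poses share the fixed
receptor frame, and re-fitting would merge placements at different
sites.  Poses of different conformers are compared over their CA beads
(same sequence, hence equal CA counts).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .confgen import Conformer
from .docking import DockedPose

__all__ = ["ClusterSet", "pose_rmsd", "greedy_cluster"]


@dataclasses.dataclass
class ClusterSet:
    """Cluster representatives in acceptance (energy) order."""

    representatives: list[DockedPose]
    member_counts: list[int]
    n_comparisons: int = 0

    def __len__(self) -> int:
        return len(self.representatives)


def _pose_coords(dp: DockedPose, conformers: list[Conformer]) -> np.ndarray:
    return dp.pose.apply(conformers[dp.conformer_id].reduced.positions)


def pose_rmsd(a: DockedPose, b: DockedPose,
              conformers: list[Conformer]) -> float:
    """Unfitted RMSD between two posed peptides in the receptor frame."""
    ca_model = conformers[a.conformer_id].reduced
    cb_model = conformers[b.conformer_id].reduced
    xa = _pose_coords(a, conformers)
    xb = _pose_coords(b, conformers)
    if a.conformer_id != b.conformer_id:
        xa = xa[ca_model.is_ca]
        xb = xb[cb_model.is_ca]
    if xa.shape != xb.shape:
        raise ValueError(
            f"bead-count mismatch ({xa.shape[0]} vs {xb.shape[0]}) with no "
            "CA mapping")
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def greedy_cluster(poses: list[DockedPose], conformers: list[Conformer],
                   threshold: float = 1.0,
                   window: int = 50) -> ClusterSet:
    """Energy-ordered leader clustering with a sliding comparison window.

    ``poses`` must already be sorted by ascending energy (contract
    error otherwise); ``threshold`` defaults to 1 A and ``window`` to
    the latest 50 representatives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    energies = [dp.energy.total for dp in poses]
    if any(e1 > e2 for e1, e2 in zip(energies, energies[1:])):
        raise ValueError("poses must be sorted by ascending energy")

    reps: list[DockedPose] = []
    rep_coords: list[tuple[np.ndarray, int]] = []  # (coords, conformer_id)
    counts: list[int] = []
    n_cmp = 0
    for dp in poses:
        coords = _pose_coords(dp, conformers)
        ca_mask = conformers[dp.conformer_id].reduced.is_ca
        best = None
        best_rmsd = np.inf
        lo = max(0, len(reps) - window)
        for ri in range(lo, len(reps)):
            rc, rcid = rep_coords[ri]
            if rcid == dp.conformer_id:
                xa, xb = coords, rc
            else:
                xa = coords[ca_mask]
                xb = rc[conformers[rcid].reduced.is_ca]
            n_cmp += 1
            r = float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
            if r < best_rmsd:
                best_rmsd, best = r, ri
        if best is not None and best_rmsd < threshold:
            counts[best] += 1
        else:
            reps.append(dp)
            rep_coords.append((coords, dp.conformer_id))
            counts.append(1)
    return ClusterSet(representatives=reps, member_counts=counts,
                      n_comparisons=n_cmp)
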