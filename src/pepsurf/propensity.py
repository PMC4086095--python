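"""Per-residue interface propensities over the top-ranked poses.

For each of the ``n_top`` (default 50) best non-redundant poses, the
receptor residues at the peptide interface are those with at least one
bead strictly within the contact cutoff (default 5 A) of any posed
peptide bead.  The propensity of residue r is the percentage of those
poses in which r is at the interface:

    p_r = 100 * (number of top poses whose interface contains r) / n_used

so every p_r is an integer multiple of 100 / n_used.  The alternative
``calpha`` mode restricts the peptide side to its CA beads with a
6.5 A cutoff (the convention used when comparing against site
predictors that return one point per residue); an all-atom mode
recomputes receptor-side contacts on the original atoms.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .cluster import ClusterSet
from .coarse_grain import ReducedModel
from .confgen import Conformer
from .structio import Structure

__all__ = ["PropensityMap", "interface_residues", "compute_propensities",
           "DEFAULT_CUTOFF", "CALPHA_CUTOFF"]

DEFAULT_CUTOFF = 5.0
CALPHA_CUTOFF = 6.5

ResidueKey = tuple[str, int, str]


@dataclasses.dataclass
class PropensityMap:
    """Per-residue propensity in [0, 100] with the settings that made it."""

    values: dict[ResidueKey, float]
    residue_order: list[ResidueKey]
    n_top: int
    n_used: int
    cutoff: float
    mode: str

    def get(self, key: ResidueKey) -> float:
        return self.values.get(key, 0.0)

    def top_residues(self, k: int) -> list[ResidueKey]:
        """The k highest-propensity residues; ties break by residue order."""
        order = {key: i for i, key in enumerate(self.residue_order)}
        ranked = sorted(self.residue_order,
                        key=lambda key: (-self.values.get(key, 0.0),
                                         order[key]))
        return ranked[:k]


def _receptor_points(receptor: ReducedModel,
                     receptor_structure: Structure | None):
    """Receptor-side coordinates and their residue keys."""
    if receptor_structure is None:
        keys = [receptor.residues[int(i)].key for i in receptor.residue_index]
        return receptor.positions, keys
    coords, keys = [], []
    for res in receptor_structure.residues:
        for atom in res.atoms:
            coords.append(atom.xyz)
            keys.append(res.key)
    return np.asarray(coords, dtype=float), keys


def interface_residues(receptor: ReducedModel, peptide: ReducedModel,
                       pose=None, cutoff: float = DEFAULT_CUTOFF,
                       mode: str = "heavy",
                       receptor_structure: Structure | None = None
                       ) -> set[ResidueKey]:
    """Receptor residues with a bead strictly below ``cutoff`` of the
    posed peptide.

    ``mode='heavy'`` uses every peptide bead; ``mode='calpha'`` only CA
    beads (pass ``cutoff=CALPHA_CUTOFF`` for the 6.5 A convention).
    Passing ``receptor_structure`` recomputes receptor-side contacts on
    the original heavy atoms instead of the beads.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("heavy", "calpha"):
        raise ValueError(f"unknown contact mode {mode!r}")
    coords = pose.apply(peptide.positions) if pose is not None \
        else peptide.positions
    if mode == "calpha":
        coords = coords[peptide.is_ca]
    rec_xyz, rec_keys = _receptor_points(receptor, receptor_structure)
    tree = cKDTree(coords)
    out: set[ResidueKey] = set()
    neigh = tree.query_ball_point(rec_xyz, cutoff)
    for bead_i, js in enumerate(neigh):
        if not js:
            continue
        d = np.linalg.norm(coords[js] - rec_xyz[bead_i], axis=1)
        if np.any(d < cutoff):  # strict inequality
            out.add(rec_keys[bead_i])
    return out


def compute_propensities(receptor: ReducedModel, clusters: ClusterSet,
                         conformers: list[Conformer], n_top: int = 50,
                         cutoff: float = DEFAULT_CUTOFF, mode: str = "heavy",
                         receptor_structure: Structure | None = None
                         ) -> PropensityMap:
    """Propensity map over the ``n_top`` best cluster representatives.

    When fewer than ``n_top`` poses survive clustering, all are used and
    the normalization becomes the count actually used.
    """
    reps = clusters.representatives[:n_top]
    if not reps:
        raise ValueError("no poses available for propensity computation")
    n_used = len(reps)
    counts: dict[ResidueKey, int] = {}
    for dp in reps:
        iface = interface_residues(
            receptor, conformers[dp.conformer_id].reduced, dp.pose,
            cutoff=cutoff, mode=mode, receptor_structure=receptor_structure)
        for key in iface:
            counts[key] = counts.get(key, 0) + 1
    values = {key: 100.0 * c / n_used for key, c in counts.items()}
    return PropensityMap(
        values=values,
        residue_order=[r.key for r in receptor.residues],
        n_top=n_top, n_used=n_used, cutoff=cutoff, mode=mode)
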