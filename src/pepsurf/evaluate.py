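"""Benchmark-style metrics and a synthetic-complex fixture generator.

The metrics mirror how blind site prediction is scored against a known
complex: the fraction of native interface residues contacted by the k
best poses, whether a top-k propensity residue is truly at the
interface, and peptide RMSD both after superposition (conformer
quality) and in the receptor frame (docking accuracy).

``make_synthetic_complex`` builds a compact dummy receptor — alanine
residues packed on concentric shells — with a groove carved
complementary to a sampled peptide conformer planted at a known pose,
so the full pipeline can be exercised end to end without any external
structure downloads.  The planted complex is labelled synthetic
throughout; it emulates a single well-formed binding groove on an
otherwise featureless convex surface and none of the chemical
heterogeneity of real binding sites.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from . import coarse_grain, confgen
from .coarse_grain import ForcefieldParams, ReducedModel
from .confgen import Conformer
from .docking import DockedPose
from .geometry import fibonacci_sphere, kabsch_rmsd
from .propensity import PropensityMap, interface_residues
from .structio import Atom, PeptideSequence, Residue, Structure, \
    validate_peptide_sequence

__all__ = ["ReferenceComplex", "interface_recovery", "top_propensity_hit",
           "peptide_pose_rmsd", "make_synthetic_complex"]

ResidueKey = tuple[str, int, str]


@dataclasses.dataclass
class ReferenceComplex:
    """A receptor with a bound peptide and its native interface set."""

    receptor: Structure
    receptor_model: ReducedModel
    peptide: Conformer              # bound (planted) coordinates
    peptide_free: Conformer         # same conformer in the generator frame
    planted_centroid: np.ndarray
    native_interface: set[ResidueKey]
    seed: int | None = None


def interface_recovery(native: set[ResidueKey], poses: list[DockedPose],
                       receptor: ReducedModel, conformers: list[Conformer],
                       k: int = 10, cutoff: float = 5.0,
                       mode: str = "heavy") -> float:
    """Fraction of native interface residues contacted by the k best poses."""
    if not native:
        raise ValueError("native interface set is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    union: set[ResidueKey] = set()
    for dp in poses[:k]:
        union |= interface_residues(
            receptor, conformers[dp.conformer_id].reduced, dp.pose,
            cutoff=cutoff, mode=mode)
    return len(native & union) / len(native)


def top_propensity_hit(pmap: PropensityMap, native: set[ResidueKey],
                       k: int = 1) -> bool:
    """True iff one of the k highest-propensity residues is native.

    Propensity ties are broken by receptor residue order.
    """
    if not pmap.residue_order:
        raise ValueError("empty propensity map")
    if not native:
        raise ValueError("native interface set is empty")
    return any(key in native for key in pmap.top_residues(k))


def _ca_coords(obj) -> np.ndarray:
    if isinstance(obj, Conformer):
        return obj.ca_coords
    if isinstance(obj, ReducedModel):
        return obj.positions[obj.is_ca]
    if isinstance(obj, Structure):
        coords = [a.xyz for r in obj.residues for a in r.atoms
                  if a.name == "CA"]
        return np.asarray(coords, dtype=float)
    raise TypeError(f"cannot extract CA coordinates from {type(obj)}")


def peptide_pose_rmsd(pose, conformer: Conformer,
                      native_peptide) -> tuple[float, float]:
    """CA RMSD of a posed conformer against the bound peptide.

    Returns ``(superposed, unfitted)``: the first after optimal
    superposition (conformer quality), the second in the receptor frame
    (docking accuracy).
    """
    native_ca = _ca_coords(native_peptide)
    coords = pose.apply(conformer.reduced.positions) if pose is not None \
        else conformer.reduced.positions
    posed_ca = coords[conformer.reduced.is_ca]
    if posed_ca.shape != native_ca.shape:
        raise ValueError(
            f"residue-count mismatch: {len(posed_ca)} vs {len(native_ca)}")
    unfitted = float(np.sqrt(np.mean(np.sum((posed_ca - native_ca) ** 2,
                                            axis=1))))
    return kabsch_rmsd(native_ca, posed_ca), unfitted


def _residue_template(params: ForcefieldParams) -> list[tuple[str, np.ndarray]]:
    """One alanine residue in local coordinates, CA at the origin."""
    bb = confgen._build_backbone(np.array([-120.0]), np.array([130.0]))
    ca = bb["CA"][0]
    atoms = [(n, bb[n][0] - ca) for n in ("N", "CA", "C", "O")]
    u = confgen._cb_direction(bb["N"][0], bb["CA"][0], bb["C"][0])
    atoms.append(("CB", 1.53 * u))
    return atoms


def _shell_points(radius: float, spacing: float) -> np.ndarray:
    n = max(4, int(round(4.0 * np.pi * radius ** 2 / spacing ** 2)))
    return radius * fibonacci_sphere(n)


def make_synthetic_complex(seed: int = 0, groove_depth: float = 5.0,
                           peptide_seq: str = "ATVRTYSC",
                           params: ForcefieldParams | None = None,
                           outer_radius: float = 11.0) -> ReferenceComplex:
    """Build a seeded synthetic receptor-peptide reference complex.

    Alanine residues are packed on concentric shells to form a compact
    quasi-spherical receptor; a peptide conformer sampled from
    ``peptide_seq`` is planted with its centroid ``groove_depth``
    Angstrom below the outer shell, and receptor residues clashing with
    it are removed, leaving a complementary groove.  The native
    interface is derived with the 5 A heavy-bead rule.
    """
    if params is None:
        params = coarse_grain.load_params()
    seq = validate_peptide_sequence(peptide_seq)
    rng = np.random.default_rng(seed)
    planted = confgen.sample_conformers(seq, n=1, seed=int(seed) + 10_000,
                                        params=params)[0]
    peptide_free = Conformer(sequence=planted.sequence,
                             reduced=planted.reduced.copy(),
                             phi=planted.phi.copy(), psi=planted.psi.copy(),
                             score=planted.score, seed=planted.seed)

    # plant the peptide at a seeded surface site
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    site = (outer_radius - groove_depth) * u
    rot = Rotation.random(rng=rng)
    model = planted.reduced
    model.positions = rot.apply(model.positions - planted.centroid) + site
    for res, idx in zip(model.residues, range(len(model.residues))):
        beads = model.residue_beads(idx)
        new_atoms = []
        for a in res.atoms:
            bi = [b for b in beads if model.bead_names[b] == a.name]
            if bi:
                new_atoms.append(dataclasses.replace(
                    a, xyz=tuple(model.positions[bi[0]])))
        res.atoms = new_atoms

    template = _residue_template(params)
    radii = np.arange(outer_radius, 1.5, -4.0)
    centers = np.vstack([_shell_points(r, 4.2) for r in radii])

    clash = 3.0  # A: receptor residues this close to the peptide are carved
    residues: list[Residue] = []
    resid = 0
    for c in centers:
        r_orient = Rotation.random(rng=rng)
        coords = {name: r_orient.apply(xyz) + c for name, xyz in template}
        d_min = min(np.linalg.norm(model.positions - coords[name],
                                   axis=1).min() for name in coords)
        if d_min < clash:
            continue
        resid += 1
        atoms = [Atom(name=name, element=name[0], resname="ALA",
                      resid=resid, icode="", chain="R",
                      xyz=tuple(coords[name]))
                 for name in ("N", "CA", "C", "O", "CB")]
        residues.append(Residue(chain="R", resid=resid, icode="",
                                name="ALA", atoms=atoms))
    receptor = Structure(residues=residues)
    receptor_model = coarse_grain.assign_charges(
        coarse_grain.reduce(receptor, params), params)
    native = interface_residues(receptor_model, model, pose=None,
                                cutoff=5.0, mode="heavy")
    return ReferenceComplex(
        receptor=receptor,
        receptor_model=receptor_model,
        peptide=planted,
        peptide_free=peptide_free,
        planted_centroid=model.positions.mean(axis=0),
        native_interface=native,
        seed=seed,
    )
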