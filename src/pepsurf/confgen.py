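"""De novo peptide conformer ensembles from sequence.

The generator fills the pipeline slot of a structure predictor: from a
peptide sequence it samples backbone dihedrals from residue-specific
Ramachandran basins (helix, sheet, polyproline-II/coil, left-handed;
glycine broadened, proline restrained), builds backbone coordinates by
standard-geometry chaining, places side-chain pseudo-beads by ideal
projection from the backbone, rejects self-clashing chains, and scores
each conformer with the coarse-grained self-energy.  The resulting
ensemble is clustered greedily (best score first) on superposed CA RMSD
and up to 20 cluster centroids are passed on to docking.  A loader for
externally generated multi-model PDB ensembles replaces the generator
when higher-fidelity conformers are available.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np

from . import structio
from .coarse_grain import ForcefieldParams, ReducedModel, load_params
from .energy import _pair_terms
from .geometry import kabsch_rmsd
from .structio import Atom, PeptideSequence, Residue, Structure

logger = logging.getLogger(__name__)

__all__ = ["Conformer", "ConformerEnsemble", "SamplingError",
           "sample_conformers", "cluster_ensemble", "load_external_ensemble",
           "self_energy"]

# standard trans-backbone geometry (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

CLASH_FLOOR = 2.2          # A, minimum bead-bead distance (|i-j| >= 2)
MAX_ATTEMPT_FACTOR = 100   # sampling gives up after 100*n attempts

# distance (A) from CA to each side-chain pseudo-bead along the CB direction
SIDE_BEAD_DISTANCES: dict[str, tuple[float, ...]] = {
    "GLY": (), "ALA": (1.5,), "SER": (1.9,), "CYS": (2.0,), "THR": (1.9,),
    "VAL": (1.9,), "PRO": (1.9,), "LEU": (2.3,), "ILE": (2.3,), "MET": (2.4,),
    "ASP": (2.5,), "ASN": (2.5,),
    "GLU": (2.1, 3.6), "GLN": (2.1, 3.6), "LYS": (2.1, 3.9),
    "ARG": (2.1, 4.9), "HIS": (2.1, 3.4), "PHE": (2.1, 3.9),
    "TYR": (2.1, 4.2), "TRP": (2.3, 4.3),
}

# Ramachandran basins: (phi_mean, phi_sd, psi_mean, psi_sd) in degrees
_BASINS = {
    "helix": (-63.0, 7.0, -43.0, 7.0),
    "sheet": (-120.0, 15.0, 135.0, 15.0),
    "ppii": (-75.0, 12.0, 150.0, 12.0),
    "left": (57.0, 7.0, 47.0, 7.0),
}
_BASIN_ORDER = ("helix", "sheet", "ppii", "left")

_HELIX_FORMERS = set("ALEMQKRH")
_SHEET_FORMERS = set("VITYFWC")


def _basin_weights(aa: str) -> tuple[float, ...]:
    if aa == "G":
        return (0.2, 0.2, 0.3, 0.3)
    if aa in _HELIX_FORMERS:
        return (0.45, 0.25, 0.25, 0.05)
    if aa in _SHEET_FORMERS:
        return (0.25, 0.45, 0.25, 0.05)
    return (0.3, 0.3, 0.3, 0.1)


class SamplingError(RuntimeError):
    """Clash rejection exhausted the attempt budget."""


@dataclasses.dataclass
class Conformer:
    """One peptide conformer: reduced bead model plus backbone dihedrals."""

    sequence: PeptideSequence
    reduced: ReducedModel
    phi: np.ndarray          # degrees; phi[0] is undefined (NaN)
    psi: np.ndarray          # degrees; psi[-1] drives only the terminal O
    score: float = 0.0
    seed: int | None = None

    @property
    def ca_coords(self) -> np.ndarray:
        return self.reduced.positions[self.reduced.is_ca]

    @property
    def centroid(self) -> np.ndarray:
        return self.reduced.positions.mean(axis=0)


@dataclasses.dataclass
class ConformerEnsemble:
    """A conformer collection with cluster assignments and centroids.

    ``centroid_indices`` are indices into ``conformers`` sorted by
    ascending score; at most 20 centroids are kept for docking.
    """

    conformers: list[Conformer]
    assignments: list[int]
    centroid_indices: list[int]

    @property
    def centroids(self) -> list[Conformer]:
        return [self.conformers[i] for i in self.centroid_indices]


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D from A-B-C with given C-D bond, B-C-D angle, A-B-C-D torsion."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _cb_direction(n, ca, c) -> np.ndarray:
    """Ideal CB direction from backbone frame (L-amino-acid chirality)."""
    b = ca - n
    cv = c - ca
    a = np.cross(b, cv)
    cb = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cv
    return cb / np.linalg.norm(cb)


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> dict[str, np.ndarray]:
    """Chain N/CA/C/O coordinates from dihedrals with standard geometry."""
    n_res = len(phi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(n_res - 1):
        N[i + 1] = _nerf(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        CA[i + 1] = _nerf(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA,
                          OMEGA)
        C[i + 1] = _nerf(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C,
                         phi[i + 1])
        # carbonyl O in the peptide plane, anti to the next N
        O[i] = _nerf(N[i + 1], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, 180.0)
    O[-1] = _nerf(N[-1], CA[-1], C[-1], BOND_C_O, ANGLE_CA_C_O,
                  psi[-1] + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _sample_dihedrals(seq: str, rng: np.random.Generator):
    phi = np.empty(len(seq))
    psi = np.empty(len(seq))
    for i, aa in enumerate(seq):
        if aa == "P":
            phi[i] = rng.normal(-65.0, 5.0)
            psi[i] = rng.normal(-35.0, 7.0) if rng.random() < 0.4 \
                else rng.normal(145.0, 10.0)
            continue
        widen = 2.0 if aa == "G" else 1.0
        k = rng.choice(4, p=np.array(_basin_weights(aa)))
        pm, ps, sm, ss = _BASINS[_BASIN_ORDER[k]]
        phi[i] = rng.normal(pm, ps * widen)
        psi[i] = rng.normal(sm, ss * widen)
    phi[0] = np.nan  # undefined at the N-terminus
    return phi, psi


def _peptide_model(seq: PeptideSequence, bb: dict[str, np.ndarray],
                   params: ForcefieldParams) -> ReducedModel:
    """Assemble the peptide ReducedModel from backbone coordinates."""
    positions: list[np.ndarray] = []
    type_ids: list[int] = []
    charges: list[float] = []
    residue_index: list[int] = []
    is_backbone: list[bool] = []
    bead_names: list[str] = []
    residues: list[Residue] = []
    for i, aa in enumerate(seq.sequence):
        res3 = structio.ONE_TO_THREE[aa]
        atoms = []
        for name in ("N", "CA", "C", "O"):
            xyz = bb[name][i]
            atoms.append(Atom(name=name, element=name[0], resname=res3,
                              resid=i + 1, icode="", chain="P",
                              xyz=tuple(xyz)))
            positions.append(np.asarray(xyz, dtype=float))
            type_ids.append(params.type_index[f"{name}_bb" if name != "CA"
                                              else "CA_bb"])
            charges.append(0.0)
            residue_index.append(i)
            is_backbone.append(True)
            bead_names.append(name)
        groups = params.groups[res3]
        dists = SIDE_BEAD_DISTANCES[res3]
        if groups:
            u = _cb_direction(bb["N"][i], bb["CA"][i], bb["C"][i])
            q_res = params.charges.get(res3, 0.0)
            for gi, (group, d) in enumerate(zip(groups, dists), start=1):
                positions.append(bb["CA"][i] + d * u)
                type_ids.append(params.type_index[group["type"]])
                charges.append(q_res if gi == len(groups) else 0.0)
                residue_index.append(i)
                is_backbone.append(False)
                bead_names.append(f"SC{gi}")
        residues.append(Residue(chain="P", resid=i + 1, icode="",
                                name=res3, atoms=atoms))
    return ReducedModel(
        positions=np.array(positions),
        type_ids=np.array(type_ids, dtype=np.intp),
        charges=np.array(charges),
        residue_index=np.array(residue_index, dtype=np.intp),
        is_backbone=np.array(is_backbone, dtype=bool),
        bead_names=bead_names,
        residues=residues,
        params=params,
    )


def _has_clash(model: ReducedModel) -> bool:
    pos = model.positions
    ridx = model.residue_index
    n = len(pos)
    ii, jj = np.triu_indices(n, k=1)
    far = np.abs(ridx[ii] - ridx[jj]) >= 2
    if not far.any():
        return False
    d = np.linalg.norm(pos[ii[far]] - pos[jj[far]], axis=1)
    return bool((d < CLASH_FLOOR).any())


def self_energy(model: ReducedModel) -> float:
    """Coarse-grained intra-peptide energy over residue-separated pairs."""
    p = model.params
    pos = model.positions
    ridx = model.residue_index
    ii, jj = np.triu_indices(len(pos), k=1)
    keep = np.abs(ridx[ii] - ridx[jj]) >= 2
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        return 0.0
    r = np.linalg.norm(pos[ii] - pos[jj], axis=1)
    ti, tj = model.type_ids[ii], model.type_ids[jj]
    e_lj, _, e_el, _ = _pair_terms(
        np.maximum(r, 1e-9), p.sigma_table[ti, tj], p.epsilon_table[ti, tj],
        p.attractive_table[ti, tj], model.charges[ii] * model.charges[jj],
        p.dielectric, p.coulomb_constant)
    return float(e_lj.sum() + e_el.sum())


def sample_conformers(seq: PeptideSequence, n: int = 200,
                      seed: int = 0,
                      params: ForcefieldParams | None = None) -> list[Conformer]:
    """Sample ``n`` clash-free conformers, reproducibly from ``seed``.

    Conformers are scored with the coarse-grained self-energy; the list
    is returned in sampling order (not sorted).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = load_params()
    rng = np.random.default_rng(seed)
    out: list[Conformer] = []
    attempts = 0
    budget = MAX_ATTEMPT_FACTOR * n
    while len(out) < n:
        if attempts >= budget:
            raise SamplingError(
                f"clash rejection exceeded {budget} attempts "
                f"({len(out)}/{n} conformers built)")
        attempts += 1
        phi, psi = _sample_dihedrals(seq.sequence, rng)
        bb = _build_backbone(np.nan_to_num(phi, nan=-120.0), psi)
        model = _peptide_model(seq, bb, params)
        if _has_clash(model):
            continue
        out.append(Conformer(sequence=seq, reduced=model, phi=phi, psi=psi,
                             score=self_energy(model), seed=seed))
    return out


def cluster_ensemble(conformers: list[Conformer], k_max: int = 20,
                     rmsd_threshold: float = 2.0) -> ConformerEnsemble:
    """Greedy best-score-first leader clustering on superposed CA RMSD.

    Conformers are visited in ascending score order; each joins the
    first existing cluster whose centroid lies within ``rmsd_threshold``
    CA RMSD (after optimal superposition), otherwise it founds a new
    cluster.  The centroids of up to ``k_max`` lowest-score clusters are
    selected.
    """
    if not conformers:
        raise ValueError("no conformers to cluster")
    order = sorted(range(len(conformers)), key=lambda i: conformers[i].score)
    centroid_of: list[int] = []   # conformer index of each cluster centroid
    assignments = [-1] * len(conformers)
    for idx in order:
        ca = conformers[idx].ca_coords
        placed = False
        for ci, cidx in enumerate(centroid_of):
            if kabsch_rmsd(conformers[cidx].ca_coords, ca) < rmsd_threshold:
                assignments[idx] = ci
                placed = True
                break
        if not placed:
            assignments[idx] = len(centroid_of)
            centroid_of.append(idx)
    return ConformerEnsemble(
        conformers=list(conformers),
        assignments=assignments,
        centroid_indices=centroid_of[:k_max],
    )


def load_external_ensemble(path: str | Path,
                           params: ForcefieldParams | None = None,
                           max_conformers: int = 20) -> ConformerEnsemble:
    """Load a user-supplied multi-model PDB as a conformer ensemble.

    Each MODEL becomes one conformer (score 0); all models must share
    one sequence.  Ensembles larger than ``max_conformers`` are capped
    with a warning, mirroring the up-to-20-centroids docking budget.
    """
    if params is None:
        params = load_params()
    models = structio.read_pose_models(path) if _is_bead_file(path) else None
    conformers: list[Conformer] = []
    if models is not None:
        conformers = _load_bead_models(models, params)
    else:
        conformers = _load_allatom_models(path, params)
    seqs = {c.sequence.sequence for c in conformers}
    if len(seqs) > 1:
        raise structio.FormatError(
            f"models in {path} disagree on sequence: {sorted(seqs)}")
    if len(conformers) > max_conformers:
        logger.warning("ensemble %s has %d models; capped at %d",
                       path, len(conformers), max_conformers)
        conformers = conformers[:max_conformers]
    return ConformerEnsemble(
        conformers=conformers,
        assignments=list(range(len(conformers))),
        centroid_indices=list(range(len(conformers))),
    )


def _is_bead_file(path: str | Path) -> bool:
    text = Path(path).read_text()
    return " SC1 " in text


def _residues_from_model(model: dict) -> list[tuple[int, str, list[tuple]]]:
    """Group one parsed MODEL dict into (resid, resname, atom list)."""
    groups: list[tuple[int, str, list[tuple]]] = []
    for name, resname, resid, xyz in zip(model["names"], model["resnames"],
                                         model["resids"], model["coords"]):
        if not groups or groups[-1][0] != resid:
            groups.append((resid, resname, []))
        groups[-1][2].append((name, xyz))
    return groups


def _load_bead_models(models: list[dict],
                      params: ForcefieldParams) -> list[Conformer]:
    conformers = []
    for model in models:
        positions, type_ids, charges, residue_index = [], [], [], []
        is_backbone, bead_names, residues = [], [], []
        for ridx, (resid, resname, atoms) in \
                enumerate(_residues_from_model(model)):
            res_atoms = []
            groups = params.groups.get(resname)
            if groups is None:
                raise structio.UnsupportedInputError(
                    f"non-standard residue {resname} in ensemble")
            q_res = params.charges.get(resname, 0.0)
            n_sc = sum(1 for name, _ in atoms if name.startswith("SC"))
            for name, xyz in atoms:
                positions.append(np.asarray(xyz, dtype=float))
                residue_index.append(ridx)
                bead_names.append(name)
                if name.startswith("SC"):
                    gi = int(name[2:])
                    type_ids.append(params.type_index[groups[gi - 1]["type"]])
                    charges.append(q_res if gi == n_sc else 0.0)
                    is_backbone.append(False)
                else:
                    type_ids.append(params.type_index[
                        f"{name}_bb" if name != "CA" else "CA_bb"])
                    charges.append(0.0)
                    is_backbone.append(True)
                    res_atoms.append(Atom(name=name, element=name[0],
                                          resname=resname, resid=resid,
                                          icode="", chain="P",
                                          xyz=tuple(xyz)))
            residues.append(Residue(chain="P", resid=resid, icode="",
                                    name=resname, atoms=res_atoms))
        rm = ReducedModel(
            positions=np.array(positions),
            type_ids=np.array(type_ids, dtype=np.intp),
            charges=np.array(charges),
            residue_index=np.array(residue_index, dtype=np.intp),
            is_backbone=np.array(is_backbone, dtype=bool),
            bead_names=bead_names, residues=residues, params=params)
        seq = "".join(structio.THREE_TO_ONE[r.name] for r in residues)
        conformers.append(Conformer(
            sequence=PeptideSequence(seq), reduced=rm,
            phi=np.full(len(residues), np.nan),
            psi=np.full(len(residues), np.nan), score=0.0))
    return conformers


def _load_allatom_models(path: str | Path,
                         params: ForcefieldParams) -> list[Conformer]:
    import gemmi

    from . import coarse_grain
    st = gemmi.read_pdb(str(path))
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    if len(st) == 0:
        raise structio.FormatError(f"{path}: no models")
    conformers = []
    for model in st:
        residues = []
        for chain in model:
            for res in chain:
                if res.name in structio.WATER_CODES:
                    continue
                conv = structio._convert_residue(chain.name, res)
                if conv is not None:
                    residues.append(conv)
        structure = Structure(residues=residues)
        rm = coarse_grain.assign_charges(
            coarse_grain.reduce(structure, params), params)
        conformers.append(Conformer(
            sequence=PeptideSequence(structure.sequence()), reduced=rm,
            phi=np.full(len(residues), np.nan),
            psi=np.full(len(residues), np.nan), score=0.0))
    return conformers
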