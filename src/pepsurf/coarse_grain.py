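"""Reduced coarse-grained representation of proteins and peptides.

All backbone heavy atoms (N, CA, C, O) are kept as beads; each side
chain is represented by up to two pseudo-beads placed at the centroids
of its heavy-atom groups (glycine: none; small side chains: one; larger
side chains: two, split at the first branch point).  Bead types index a
pair-parameter table loaded from a YAML parameter file; formal charges
sit on the distal side-chain bead of ASP/GLU (-1) and LYS/ARG (+1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .structio import Residue, Structure

logger = logging.getLogger(__name__)

__all__ = ["ForcefieldParams", "ReducedModel", "ReductionError",
           "load_params", "reduce", "assign_charges"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ReductionError(ValueError):
    """A residue cannot be reduced (missing backbone atoms, unknown type)."""


@dataclasses.dataclass
class ForcefieldParams:
    """Pair-parameter tables and charge rules for the reduced model.

    ``sigma_table``/``epsilon_table``/``attractive_table`` are symmetric
    (n_types, n_types) arrays; ``groups`` maps residue names to their
    side-chain heavy-atom groups.
    """

    type_names: list[str]
    type_index: dict[str, int]
    sigma_table: np.ndarray
    epsilon_table: np.ndarray
    attractive_table: np.ndarray
    groups: dict[str, list[dict]]
    charges: dict[str, float]
    dielectric: float
    coulomb_constant: float
    surface_bead_radius: float
    checksum: str = ""

    def pair(self, ti: int, tj: int) -> tuple[float, float, bool]:
        return (
            float(self.sigma_table[ti, tj]),
            float(self.epsilon_table[ti, tj]),
            bool(self.attractive_table[ti, tj]),
        )


def load_params(path: str | Path | None = None) -> ForcefieldParams:
    """Load force-field parameters, defaulting to the bundled generic set.

    The per-pair sigma is the arithmetic mean of the per-type sigmas and
    the per-pair epsilon the geometric mean of the per-type epsilons;
    pairs listed under ``repulsive_pairs`` are flagged non-attractive.
    A SHA-256 checksum of the file is logged at load time.
    """
    if path is None:
        text = (resources.files("pepsurf") / "data" / "forcefield.yaml").read_text()
        origin = "bundled forcefield.yaml"
    else:
        text = Path(path).read_text()
        origin = str(path)
    checksum = hashlib.sha256(text.encode()).hexdigest()
    logger.info("loading force-field parameters from %s (sha256=%s)",
                origin, checksum[:12])
    raw = yaml.safe_load(text)

    type_names = list(raw["types"])
    idx = {name: i for i, name in enumerate(type_names)}
    n = len(type_names)
    sig = np.array([raw["types"][t]["sigma"] for t in type_names])
    eps = np.array([raw["types"][t]["epsilon"] for t in type_names])
    if np.any(sig <= 0) or np.any(eps < 0):
        raise ValueError("sigma must be > 0 and epsilon >= 0")
    sigma_table = 0.5 * (sig[:, None] + sig[None, :])
    epsilon_table = np.sqrt(eps[:, None] * eps[None, :])
    attractive = np.ones((n, n), dtype=bool)
    for a, b in raw.get("repulsive_pairs", []):
        attractive[idx[a], idx[b]] = False
        attractive[idx[b], idx[a]] = False
    return ForcefieldParams(
        type_names=type_names,
        type_index=idx,
        sigma_table=sigma_table,
        epsilon_table=epsilon_table,
        attractive_table=attractive,
        groups=raw["groups"],
        charges={k: float(v) for k, v in raw.get("charges", {}).items()},
        dielectric=float(raw.get("dielectric", 15.0)),
        coulomb_constant=float(raw.get("coulomb_constant", 332.0636)),
        surface_bead_radius=float(raw.get("surface_bead_radius", 0.0)),
        checksum=checksum,
    )


@dataclasses.dataclass
class ReducedModel:
    """Coarse-grained bead set with force-field annotation.

    Arrays are aligned over beads; ``residue_index[b]`` maps bead ``b``
    back to ``residues[residue_index[b]]``.  Bead order is deterministic:
    residues in file order, backbone beads (N, CA, C, O) before
    side-chain pseudo-beads.
    """

    positions: np.ndarray          # (n_beads, 3) float
    type_ids: np.ndarray           # (n_beads,) int
    charges: np.ndarray            # (n_beads,) float
    residue_index: np.ndarray      # (n_beads,) int
    is_backbone: np.ndarray        # (n_beads,) bool
    bead_names: list[str]
    residues: list[Residue]
    params: ForcefieldParams

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def is_ca(self) -> np.ndarray:
        return np.array([n == "CA" for n in self.bead_names])

    def residue_beads(self, ridx: int) -> np.ndarray:
        return np.nonzero(self.residue_index == ridx)[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def copy(self) -> "ReducedModel":
        return ReducedModel(
            positions=self.positions.copy(),
            type_ids=self.type_ids.copy(),
            charges=self.charges.copy(),
            residue_index=self.residue_index.copy(),
            is_backbone=self.is_backbone.copy(),
            bead_names=list(self.bead_names),
            residues=self.residues,
            params=self.params,
        )


def reduce(structure: Structure, params: ForcefieldParams) -> ReducedModel:
    """Translate an all-atom structure into the reduced representation.

    Raises :class:`ReductionError` (naming the residue) when a backbone
    heavy atom is missing; a side-chain group with some atoms absent is
    reduced from the atoms present with a logged warning, and skipped if
    none of its atoms are present.
    """
    positions: list[np.ndarray] = []
    type_ids: list[int] = []
    residue_index: list[int] = []
    is_backbone: list[bool] = []
    bead_names: list[str] = []

    for ridx, res in enumerate(structure.residues):
        if res.name not in params.groups:
            raise ReductionError(f"unknown residue type {res.label()}")
        for aname in BACKBONE_ATOMS:
            atom = res.atom(aname)
            if atom is None:
                raise ReductionError(
                    f"missing backbone atom {aname} in residue {res.label()}"
                )
            positions.append(np.asarray(atom.xyz, dtype=float))
            type_ids.append(params.type_index[f"{aname}_bb" if aname != "CA"
                                              else "CA_bb"])
            residue_index.append(ridx)
            is_backbone.append(True)
            bead_names.append(aname)
        for gi, group in enumerate(params.groups[res.name], start=1):
            coords = [np.asarray(res.atom(a).xyz) for a in group["atoms"]
                      if res.atom(a) is not None]
            if len(coords) < len(group["atoms"]):
                if not coords:
                    logger.warning(
                        "residue %s: side-chain group %d has no atoms "
                        "present; pseudo-bead skipped", res.label(), gi)
                    continue
                logger.warning(
                    "residue %s: side-chain group %d incomplete "
                    "(%d/%d atoms); pseudo-bead built from atoms present",
                    res.label(), gi, len(coords), len(group["atoms"]))
            positions.append(np.mean(coords, axis=0))
            type_ids.append(params.type_index[group["type"]])
            residue_index.append(ridx)
            is_backbone.append(False)
            bead_names.append(f"SC{gi}")

    model = ReducedModel(
        positions=np.array(positions, dtype=float),
        type_ids=np.array(type_ids, dtype=np.intp),
        charges=np.zeros(len(positions)),
        residue_index=np.array(residue_index, dtype=np.intp),
        is_backbone=np.array(is_backbone, dtype=bool),
        bead_names=bead_names,
        residues=list(structure.residues),
        params=params,
    )
    if not np.all(np.isfinite(model.positions)):
        raise ReductionError("non-finite coordinates in reduced model")
    return model


def assign_charges(model: ReducedModel, params: ForcefieldParams) -> ReducedModel:
    """Return a copy of ``model`` with formal charges assigned.

    The charge of a charged residue sits on its last (distal) side-chain
    pseudo-bead; backbone beads and apolar side chains stay neutral.
    Terminal charges are not assigned.
    """
    out = model.copy()
    out.charges[:] = 0.0
    for ridx, res in enumerate(out.residues):
        q = params.charges.get(res.name, 0.0)
        if q == 0.0:
            continue
        beads = out.residue_beads(ridx)
        side = beads[~out.is_backbone[beads]]
        if len(side):
            out.charges[side[-1]] = q
        else:
            logger.warning("residue %s carries charge %+g but has no "
                           "side-chain bead; charge dropped", res.label(), q)
    return out
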