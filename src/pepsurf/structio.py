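"""Reading and writing of the structure formats the pipeline touches.

Protein receptors arrive as fixed-column PDB files; peptides as plain
sequences (optionally FASTA); results leave as fixed-column PDB again,
with per-residue interface propensities written into the temperature
factor field (columns 61-66) so that any molecular viewer can colour
the surface by predicted contact propensity.

Parsing is delegated to :mod:`gemmi`; only the first MODEL is read, the
first alternate location of each atom is kept, and hydrogens and waters
are stripped.  Writing is done with explicit fixed-column formatting
because downstream consumers rely on exact column placement.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PeptideSequence",
    "FormatError",
    "UnsupportedInputError",
    "SequenceError",
    "read_pdb",
    "validate_peptide_sequence",
    "write_propensity_pdb",
    "write_propensity_table",
    "write_pose_models",
    "read_pose_models",
]

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

NUCLEIC_CODES = {"A", "C", "G", "U", "T", "I",
                 "DA", "DC", "DG", "DT", "DU", "DI"}

WATER_CODES = {"HOH", "WAT", "DOD"}


class FormatError(ValueError):
    """The input file could not be interpreted as the expected format."""


class UnsupportedInputError(ValueError):
    """Structurally valid input outside the supported problem class."""


class SequenceError(ValueError):
    """A peptide sequence violating the length or alphabet contract."""


@dataclasses.dataclass(frozen=True)
class Atom:
    name: str
    element: str
    resname: str
    resid: int
    icode: str
    chain: str
    xyz: tuple[float, float, float]
    record: str = "ATOM"


@dataclasses.dataclass
class Residue:
    chain: str
    resid: int
    icode: str
    name: str
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def label(self) -> str:
        return f"{self.chain}/{self.resid}{self.icode.strip()}/{self.name}"


@dataclasses.dataclass
class Structure:
    """An ordered residue list; every atom belongs to exactly one residue."""

    residues: list[Residue]

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def __len__(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)


@dataclasses.dataclass(frozen=True)
class PeptideSequence:
    """A validated peptide sequence of 4-36 standard amino acids."""

    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self):
        return iter(self.sequence)


MIN_PEPTIDE = 4
MAX_PEPTIDE = 36


def validate_peptide_sequence(text: str) -> PeptideSequence:
    """Validate a raw sequence or single-record FASTA text.

    The sequence is uppercased and whitespace-stripped; it must consist
    of the 20 standard one-letter codes and have a length between 4 and
    36 residues.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    seq = "".join(ln for ln in lines if ln and not ln.startswith(">"))
    seq = "".join(seq.split()).upper()
    if not (MIN_PEPTIDE <= len(seq) <= MAX_PEPTIDE):
        raise SequenceError(
            f"peptide length {len(seq)} outside the supported range "
            f"[{MIN_PEPTIDE}, {MAX_PEPTIDE}]"
        )
    bad = sorted(set(seq) - set(ONE_TO_THREE))
    if bad:
        raise SequenceError(
            f"non-standard residue letter(s) {bad!r} in peptide sequence"
        )
    return PeptideSequence(seq)


def _convert_residue(chain_name: str, res: gemmi.Residue) -> Residue | None:
    name = res.name
    record = "HETATM" if res.het_flag == "H" else "ATOM"
    if name == "MSE":
        # selenomethionine: standard engineered residue, mapped to MET
        name = "MET"
        record = "ATOM"
    atoms: list[Atom] = []
    for a in res:
        el = a.element.name
        if el == "H" or a.name.startswith(("H", "D")) and el in ("H", "D", ""):
            continue
        aname = a.name
        if res.name == "MSE" and aname == "SE":
            aname, el = "SD", "S"
        atoms.append(
            Atom(
                name=aname,
                element=el or aname[:1],
                resname=name,
                resid=res.seqid.num,
                icode=res.seqid.icode.strip() or "",
                chain=chain_name,
                xyz=(a.pos.x, a.pos.y, a.pos.z),
                record=record,
            )
        )
    if not atoms:
        return None
    return Residue(
        chain=chain_name,
        resid=res.seqid.num,
        icode=res.seqid.icode.strip() or "",
        name=name,
        atoms=atoms,
    )


def read_pdb(path: str | Path, keep_hetero: bool = False) -> Structure:
    """Read a protein structure from a PDB file.

    Only the first MODEL is used; for atoms with alternate locations the
    first occurrence is kept; hydrogens and waters are always removed.
    With ``keep_hetero=False`` (the docking default) every HETATM-derived
    residue is discarded as well.

    Raises
    ------
    FormatError
        If the file contains no protein ATOM records.
    UnsupportedInputError
        If polymer chains contain nucleic-acid residues, or protein
        chains contain non-standard residues other than MSE.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi msg
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    if len(st) == 0:
        raise FormatError(f"{path} contains no coordinates")
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.name in WATER_CODES:
                continue
            het = res.het_flag == "H" and res.name != "MSE"
            if res.name in NUCLEIC_CODES and not het:
                raise UnsupportedInputError(
                    "non-polypeptide (nucleic acid) chains are not accepted"
                )
            if het and not keep_hetero:
                continue
            if not het and res.name not in AMINO_ACIDS_3 and res.name != "MSE":
                raise UnsupportedInputError(
                    f"non-standard polymer residue {res.name} is not supported"
                )
            conv = _convert_residue(chain.name, res)
            if conv is not None:
                residues.append(conv)
    if not any(a.record == "ATOM" for r in residues for a in r.atoms):
        raise FormatError(f"{path} contains no protein ATOM records")
    return Structure(residues=residues)


def _format_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    icode: str,
    xyz: Sequence[float],
    occupancy: float,
    bfactor: float,
    element: str,
    record: str = "ATOM",
) -> str:
    # PDB v3 name convention: 1-char elements start in column 14
    if len(name) < 4 and len(element) == 1:
        name_fmt = f" {name:<3s}"
    else:
        name_fmt = f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {name_fmt} {resname:>3s} {chain:1.1s}"
        f"{resid:>4d}{(icode or ' '):1.1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{bfactor:6.2f}          {element:>2s}"
    )


def write_propensity_pdb(
    structure: Structure,
    propensities: Mapping[tuple[str, int, str], float],
    path: str | Path,
) -> None:
    """Write ``structure`` with per-residue propensities in columns 61-66.

    Every atom line carries its residue's propensity, formatted ``%6.2f``,
    in the temperature factor field.  Residues absent from the map get 0.
    """
    for key, p in propensities.items():
        if not (0.0 <= p <= 100.0):
            raise ValueError(f"propensity {p} for residue {key} outside [0, 100]")
    lines = []
    serial = 0
    for res in structure.residues:
        p = float(propensities.get(res.key, 0.0))
        for atom in res.atoms:
            serial += 1
            lines.append(
                _format_atom_line(
                    serial, atom.name, res.name, res.chain, res.resid,
                    res.icode, atom.xyz, 1.0, p, atom.element, atom.record,
                )
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_propensity_table(
    structure: Structure,
    propensities: Mapping[tuple[str, int, str], float],
    path: str | Path,
) -> None:
    """Plain-text two-column table: residue identifier, propensity."""
    lines = ["# residue\tpropensity"]
    for res in structure.residues:
        p = float(propensities.get(res.key, 0.0))
        lines.append(f"{res.label()}\t{p:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pose_models(poses, conformers, path: str | Path) -> None:
    """Write docked poses as a multi-model PDB, one MODEL per pose.

    Poses must arrive sorted by ascending interaction energy; each MODEL
    block is preceded by a REMARK line recording the pose's energy and
    provenance.  Bead coordinates are written as pseudo-atom records
    (backbone beads under their atom names, side-chain beads as SC1/SC2).
    """
    poses = list(poses)
    if not poses:
        raise ValueError("no poses to write")
    lines = [
        "REMARK   3 PEPSURF DOCKED PEPTIDE POSES, RANKED BY INTERACTION ENERGY",
    ]
    for rank, dp in enumerate(poses, start=1):
        model = conformers[dp.conformer_id].reduced
        coords = dp.pose.apply(model.positions)
        lines.append(f"MODEL     {rank:>4d}")
        lines.append(
            f"REMARK   4 ENERGY {dp.energy.total:12.4f} LJ {dp.energy.lj:12.4f}"
            f" ELEC {dp.energy.elec:12.4f} CONFORMER {dp.conformer_id}"
            f" START {dp.start_id} ORIENT {dp.orientation_id}"
        )
        serial = 0
        sc_counter: dict[int, int] = {}
        for b in range(model.n_beads):
            ridx = int(model.residue_index[b])
            chain, resid, icode = model.residues[ridx].key
            resname = model.residues[ridx].name
            if model.is_backbone[b]:
                name = model.bead_names[b]
                element = name[0]
            else:
                sc_counter[ridx] = sc_counter.get(ridx, 0) + 1
                name = f"SC{sc_counter[ridx]}"
                element = "C"
            serial += 1
            lines.append(
                _format_atom_line(
                    serial, name, resname, chain, resid, icode,
                    coords[b], 1.0, 0.0, element,
                )
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pose_models(path: str | Path) -> list[dict]:
    """Read back a pose file written by :func:`write_pose_models`.

    Returns one dict per MODEL with keys ``energy`` (total, or None when
    the REMARK is absent) and ``coords`` (list of xyz triples in file
    order).  Used for round-trip checks and external ensemble input.
    """
    models: list[dict] = []
    current: dict | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            current = {"energy": None, "coords": [], "resnames": [],
                       "resids": [], "names": []}
        elif line.startswith("REMARK   4 ENERGY") and current is not None:
            current["energy"] = float(line.split()[3])
        elif line.startswith(("ATOM", "HETATM")) and current is not None:
            current["coords"].append(
                (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            )
            current["names"].append(line[12:16].strip())
            current["resnames"].append(line[17:20].strip())
            current["resids"].append(int(line[22:26]))
        elif line.startswith("ENDMDL") and current is not None:
            models.append(current)
            current = None
    if not models:
        raise FormatError(f"{path}: no MODEL blocks found")
    return models
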