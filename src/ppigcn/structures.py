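"""Residue-level protein structure model and PDB input/output.

A :class:`ProteinStructure` is the canonical container every other module
consumes: an ordered list of residues, grouped contiguously by chain, each
carrying its amino-acid type, author numbering, a mandatory C-alpha
coordinate, an optional full backbone (N, CA, C), and its atom list.

Parsing is built on :class:`Bio.PDB.PDBParser` with a fixed set of
conventions on top:

* only the first MODEL of multi-model files is read;
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altloc identifier, so ``A`` wins);
* HETATM records and waters are discarded, except selenomethionine (MSE),
  which is mapped to MET;
* residues lacking a CA atom are dropped entirely — every distance used
  downstream is C-alpha based, so such residues cannot participate in any
  graph;
* hydrogens are kept in the atom list but flagged, and interface labeling
  elsewhere uses only heavy atoms.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

#: Standard three-letter amino-acid codes, alphabetical. This ordering also
#: defines the one-hot layout used by the feature module.
STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

UNKNOWN_AA = "UNK"

_HYDROGEN_ELEMENTS = {"H", "D"}


class StructureError(ValueError):
    """Raised for unreadable input or structures that violate invariants."""


class EmptyStructureError(StructureError):
    """Raised when no residues survive parsing and filtering."""


@dataclass(frozen=True)
class Atom:
    """A single atom: label, element and Cartesian coordinate in Angstrom."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise StructureError(
                f"atom {self.name!r}: coordinate must be 3 finite components"
            )
        object.__setattr__(self, "coord", coord)
        object.__setattr__(self, "element", self.element.upper())

    @property
    def is_heavy(self) -> bool:
        return self.element not in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """One residue with its chain identity, numbering and atoms."""

    chain_id: str
    author_number: int
    insertion_code: str
    seq_index: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def ca(self) -> np.ndarray | None:
        for atom in self.atoms:
            if atom.name == "CA":
                return atom.coord
        return None

    @property
    def backbone(self) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
        """(N, CA, C) coordinates, or None if any of the three is missing."""
        found: dict[str, np.ndarray] = {}
        for atom in self.atoms:
            if atom.name in ("N", "CA", "C") and atom.name not in found:
                found[atom.name] = atom.coord
        if len(found) == 3:
            return found["N"], found["CA"], found["C"]
        return None

    def heavy_coords(self) -> np.ndarray:
        """(k, 3) array of heavy-atom coordinates."""
        coords = [a.coord for a in self.atoms if a.is_heavy]
        if not coords:
            return np.empty((0, 3))
        return np.stack(coords)


@dataclass
class ProteinStructure:
    """Ordered residues of one protein (possibly multi-chain)."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        for i, res in enumerate(self.residues):
            if res.seq_index != i:
                raise StructureError(
                    f"{self.id}: residue seq_index must be 0..n-1 in order "
                    f"(found {res.seq_index} at position {i})"
                )

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def ca_coords(self) -> np.ndarray:
        """(n, 3) C-alpha coordinate array, in residue order."""
        return np.stack([res.ca for res in self.residues])

    def sequence(self) -> list[str]:
        return [res.aa for res in self.residues]


def _resolve_altlocs(bio_residue) -> list:
    """Pick one conformer per atom name: highest occupancy, ties -> altloc 'A'."""
    chosen: dict[str, object] = {}
    for atom in bio_residue.get_unpacked_list():
        name = atom.get_name()
        prev = chosen.get(name)
        if prev is None:
            chosen[name] = atom
            continue
        occ = atom.get_occupancy() or 0.0
        prev_occ = prev.get_occupancy() or 0.0
        if occ > prev_occ or (occ == prev_occ and atom.get_altloc() < prev.get_altloc()):
            chosen[name] = atom
    return list(chosen.values())


def parse_pdb(
    source: str | Path | io.StringIO,
    chain_filter: Iterable[str] | None = None,
    structure_id: str | None = None,
) -> ProteinStructure:
    """Parse PDB text or a file path into a :class:`ProteinStructure`.

    Parameters
    ----------
    source
        Path to a PDB file, raw PDB text, or a text stream.
    chain_filter
        If given, keep only residues belonging to these chain identifiers.
    structure_id
        Identifier for the resulting structure; defaults to the file stem
        (or ``"structure"`` for in-memory sources).

    Raises
    ------
    StructureError
        If the source cannot be read.
    EmptyStructureError
        If no residues survive filtering.
    """
    chain_set = set(chain_filter) if chain_filter is not None else None

    if isinstance(source, io.StringIO):
        handle, sid = source, structure_id or "structure"
    elif isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).suffix
    ):
        path = Path(source)
        if not path.is_file():
            raise StructureError(f"cannot read PDB source: {path}")
        handle = io.StringIO(path.read_text())
        sid = structure_id or path.stem
    elif isinstance(source, str):
        handle, sid = io.StringIO(source), structure_id or "structure"
    else:
        raise StructureError(f"unsupported PDB source type: {type(source)!r}")

    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio_structure = parser.get_structure(sid, handle)
        except Exception as exc:  # Bio.PDB raises a mix of exception types
            raise StructureError(f"cannot parse PDB source {sid!r}: {exc}") from exc

    models = list(bio_structure.get_models())
    if not models:
        raise EmptyStructureError(f"{sid}: no models in PDB source")
    model = models[0]  # first model only

    residues: list[Residue] = []
    for chain in model:
        if chain_set is not None and chain.id not in chain_set:
            continue
        for bio_res in chain:
            hetflag, _, icode = bio_res.get_id()
            resname = bio_res.get_resname().strip()
            if hetflag == "W":
                continue
            if hetflag.strip():
                if resname != "MSE":
                    continue  # non-MSE HETATM excluded
            if resname == "MSE":
                aa = "MET"
            elif resname in STANDARD_AA:
                aa = resname
            else:
                aa = UNKNOWN_AA
            atoms = []
            for bio_atom in _resolve_altlocs(bio_res):
                element = (bio_atom.element or "").strip() or bio_atom.get_name()[0]
                atoms.append(
                    Atom(
                        name=bio_atom.get_name(),
                        element=element,
                        coord=np.asarray(bio_atom.get_coord(), dtype=float),
                    )
                )
            if not any(a.name == "CA" for a in atoms):
                logger.debug(
                    "%s: dropping residue %s %s%s (no CA atom)",
                    sid, resname, bio_res.get_id()[1], icode.strip(),
                )
                continue
            residues.append(
                Residue(
                    chain_id=chain.id,
                    author_number=bio_res.get_id()[1],
                    insertion_code=icode.strip(),
                    seq_index=len(residues),
                    aa=aa,
                    atoms=atoms,
                )
            )

    if not residues:
        raise EmptyStructureError(
            f"{sid}: no residues survive parsing"
            + (f" with chain_filter={sorted(chain_set)}" if chain_set else "")
        )
    return ProteinStructure(id=sid, residues=residues)


_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}"
)


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names of <4 chars start in column 14 unless the
    # element symbol is two characters long.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_toy_pdb(structure: ProteinStructure, path: str | Path) -> Path:
    """Write fixed-width ATOM records so that ``parse_pdb`` round-trips.

    Intended for synthetic fixtures; coordinates are emitted to 3 decimals,
    chains separated by TER records, file closed with END.
    """
    if structure.n == 0:
        raise StructureError("cannot write an empty structure")
    lines: list[str] = []
    serial = 1
    prev_chain: str | None = None
    for res in structure.residues:
        if not res.atoms:
            raise StructureError(
                f"{structure.id}: residue {res.chain_id}{res.author_number} has no atoms"
            )
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for atom in res.atoms:
            lines.append(
                _ATOM_FMT.format(
                    serial=serial,
                    name=_format_atom_name(atom.name),
                    altloc=" ",
                    resname=res.aa,
                    chain=res.chain_id,
                    resnum=res.author_number,
                    icode=res.insertion_code or " ",
                    x=atom.coord[0],
                    y=atom.coord[1],
                    z=atom.coord[2],
                    occ=1.0,
                    b=0.0,
                    element=atom.element[:2],
                )
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def to_pdb_text(structure: ProteinStructure) -> str:
    """PDB text of a structure (same records ``write_toy_pdb`` emits)."""
    import tempfile

    with tempfile.NamedTemporaryFile("r", suffix=".pdb") as handle:
        write_toy_pdb(structure, handle.name)
        return Path(handle.name).read_text()
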