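"""Reading protein-ligand structures into typed heavy-atom representations.

Parses PDB and PDBQT files into :class:`TypedAtom` lists, assigning the
interaction-class flags (hydrophobic carbon, hydrogen-bond donor/acceptor) and
van der Waals radii the pairwise descriptors need.  Hydrogens are stripped at
parse time: every downstream feature is a heavy-atom feature.  Waters
(HOH/WAT) and, on the protein side, HETATM cofactors are excluded so that the
atom lists describe the binary protein-ligand interface only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .config import vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "TypedAtom",
    "MolecularComplex",
    "TorsionInfo",
    "StructureParseError",
    "UnknownElementError",
    "parse_pdbqt",
    "parse_pdb",
    "assign_atom_properties",
    "count_rotatable_bonds",
    "write_pdbqt",
    "load_complex",
]


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed into heavy atoms."""

    def __init__(self, message: str, source: str = "<string>", line_no: int | None = None):
        self.source = source
        self.line_no = line_no
        loc = source if line_no is None else f"{source}:{line_no}"
        super().__init__(f"{loc}: {message}")


class UnknownElementError(ValueError):
    """Raised for an element symbol outside the recognised set."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(f"unrecognised element symbol: {element!r}")


# Elements we accept in structures. Metals and other rarities get the fallback
# vdW radius but are still parsed (they may be flagged upstream as uncommon).
_KNOWN_ELEMENTS = {
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se",
    "Zn", "Mg", "Ca", "Mn", "Fe", "Na", "K", "Cu", "Ni", "Co", "Cd", "Hg", "As",
}
_HYDROGEN_TYPES = {"H", "HD", "HS"}
# AutoDock atom type -> element
_PDBQT_TYPE_ELEMENT = {
    "C": "C", "A": "C", "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O", "S": "S", "SA": "S",
    "P": "P", "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
    "ZN": "Zn", "MG": "Mg", "CA": "Ca", "MN": "Mn", "FE": "Fe", "CU": "Cu",
    "SE": "Se", "B": "B", "SI": "Si",
}
_WATER_RESNAMES = {"HOH", "WAT", "DOD"}

#: distance below which an HD hydrogen counts as bonded to an N/O (Angstrom)
_POLAR_H_BOND_MAX = 1.3
#: heuristic radius for the connectivity-free hydrophobic-carbon rule
_HETERO_CONTACT_MAX = 1.9


@dataclass
class TypedAtom:
    """One heavy atom with the properties the descriptors consume."""

    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    role: str  # "protein" | "ligand"
    pdbqt_type: str | None = None
    is_hydrophobic: bool = False
    is_hbond_donor: bool = False
    is_hbond_acceptor: bool = False
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be a finite 3-vector")
        if self.vdw_radius == 0.0:
            self.vdw_radius = vdw_radius(self.element)
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if self.is_hydrophobic and self.element != "C":
            raise ValueError("only carbon can be hydrophobic")


@dataclass
class TorsionInfo:
    """Torsion metadata from a PDBQT torsion tree."""

    remark_active_torsions: int | None = None
    branch_count: int = 0


@dataclass
class MolecularComplex:
    """A protein atom set, a ligand atom set and the ligand's Nrot."""

    id: str
    protein_atoms: list[TypedAtom]
    ligand_atoms: list[TypedAtom]
    n_rotatable_bonds: int = 0

    def __post_init__(self) -> None:
        if self.n_rotatable_bonds < 0:
            raise ValueError("n_rotatable_bonds must be >= 0")
        for atom in self.protein_atoms:
            if atom.role != "protein":
                raise ValueError("protein_atoms contains a non-protein atom")
        for atom in self.ligand_atoms:
            if atom.role != "ligand":
                raise ValueError("ligand_atoms contains a non-ligand atom")


def assign_atom_properties(
    element: str,
    pdbqt_type: str | None = None,
    bonded_elements: Counter | list[str] | None = None,
) -> tuple[bool, bool, bool, float]:
    """Interaction-class flags and vdW radius for one heavy atom.

    ``bonded_elements`` is a multiset of neighbour symbols; the pseudo-symbol
    ``"HD"`` marks a bonded polar hydrogen.  Rules: a carbon is hydrophobic iff
    bonded only to C or H; an atom is an acceptor iff its AutoDock type is NA
    or OA (falling back to the plain N/O heuristic without typing); a donor is
    an N or O with a bonded polar hydrogen.

    Returns ``(is_hydrophobic, is_hbond_donor, is_hbond_acceptor, vdw_radius)``.
    """
    if element not in _KNOWN_ELEMENTS:
        raise UnknownElementError(element)
    bonded = Counter(bonded_elements) if bonded_elements is not None else None

    hydrophobic = False
    if element == "C" and bonded is not None:
        hydrophobic = all(sym in ("C", "H", "HD") for sym in bonded)
        if "HD" in bonded:  # a polar H on carbon would itself be unusual
            hydrophobic = False

    if pdbqt_type is not None:
        acceptor = pdbqt_type.upper() in ("NA", "OA")
    else:
        acceptor = element in ("N", "O")

    donor = element in ("N", "O") and bonded is not None and bonded.get("HD", 0) > 0
    return hydrophobic, donor, acceptor, vdw_radius(element)


def _parse_coords(line: str, source: str, line_no: int) -> np.ndarray:
    try:
        return np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
    except (ValueError, IndexError) as exc:
        raise StructureParseError(
            f"malformed coordinate field in ATOM record: {line.rstrip()!r}",
            source,
            line_no,
        ) from exc


def _element_from_name(name: str, resname: str) -> str:
    """Element heuristics from a PDB atom name when the element column is blank.

    Two-letter elements (Cl, Br, metals) occupy columns 13-14; standard
    protein/ligand atom names (" CA ", " N  ") start in column 14, so a
    leading non-blank character signals a two-letter element.
    """
    two = name[:2].strip().capitalize()
    if name[:1].strip() and two in _KNOWN_ELEMENTS and len(two) == 2:
        return two
    stripped = name.strip()
    first_alpha = next((c for c in stripped if c.isalpha()), "")
    if not first_alpha:
        raise UnknownElementError(name.strip())
    return first_alpha.upper()


def parse_pdbqt(text: str, role: str, source: str = "<string>") -> tuple[list[TypedAtom], TorsionInfo]:
    """Parse PDBQT content into heavy :class:`TypedAtom` records + torsion info.

    Coordinates come from the fixed PDB columns, the AutoDock atom type from
    the trailing field.  Hydrogens (types H/HD/HS) are dropped, but HD
    positions are used to mark N/O donors.  Waters are excluded; for
    ``role="protein"`` all HETATM records are excluded as cofactors.
    """
    torsions = TorsionInfo()
    raw: list[tuple[str, np.ndarray, str]] = []  # (pdbqt_type, coords, resname)
    hd_coords: list[np.ndarray] = []
    saw_atom_record = False

    for line_no, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "REMARK" and "active torsions" in line:
            for tok in line.split():
                if tok.isdigit():
                    torsions.remark_active_torsions = int(tok)
                    break
        elif rec == "BRANCH":
            torsions.branch_count += 1
        elif rec in ("ATOM", "HETATM"):
            saw_atom_record = True
            resname = line[17:20].strip().upper()
            coords = _parse_coords(line, source, line_no)
            fields = line[54:].split()
            pdbqt_type = fields[-1] if fields else ""
            if pdbqt_type.upper() in _HYDROGEN_TYPES or pdbqt_type.upper().startswith("H"):
                if pdbqt_type.upper() == "HD":
                    hd_coords.append(coords)
                continue
            if resname in _WATER_RESNAMES:
                continue
            if role == "protein" and rec == "HETATM":
                continue
            raw.append((pdbqt_type, coords, resname))

    if not saw_atom_record:
        raise StructureParseError("no ATOM/HETATM records found", source)
    if not raw:
        raise StructureParseError("no heavy atoms (hydrogens only)", source)

    coords_arr = np.array([c for _, c, _ in raw])
    elements = []
    for pdbqt_type, _, _ in raw:
        elem = _PDBQT_TYPE_ELEMENT.get(pdbqt_type.upper())
        if elem is None:
            elem = pdbqt_type.capitalize()
        if elem not in _KNOWN_ELEMENTS:
            raise UnknownElementError(pdbqt_type)
        elements.append(elem)

    atoms = _build_atoms(elements, coords_arr, role,
                         [t for t, _, _ in raw], hd_coords)
    return atoms, torsions


def parse_pdb(text: str, role: str, source: str = "<string>") -> list[TypedAtom]:
    """Parse plain PDB content into heavy :class:`TypedAtom` records.

    The element is taken from columns 77-78, falling back to atom-name
    heuristics.  No torsion metadata exists in PDB files.
    """
    raw: list[tuple[str, np.ndarray]] = []
    saw_atom_record = False
    for line_no, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        saw_atom_record = True
        resname = line[17:20].strip().upper()
        if resname in _WATER_RESNAMES:
            continue
        if role == "protein" and rec == "HETATM":
            continue
        coords = _parse_coords(line, source, line_no)
        element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
        if not element:
            element = _element_from_name(line[12:16], resname)
        if element == "H" or element == "D":
            continue
        if element not in _KNOWN_ELEMENTS:
            raise StructureParseError(
                f"unrecognised element {element!r}", source, line_no
            )
        raw.append((element, coords))

    if not saw_atom_record:
        raise StructureParseError("no ATOM/HETATM records found", source)
    if not raw:
        raise StructureParseError("no heavy atoms (hydrogens only)", source)

    coords_arr = np.array([c for _, c in raw])
    elements = [e for e, _ in raw]
    return _build_atoms(elements, coords_arr, role, [None] * len(raw), [])


def _build_atoms(
    elements: list[str],
    coords: np.ndarray,
    role: str,
    pdbqt_types: list[str | None],
    hd_coords: list[np.ndarray],
) -> list[TypedAtom]:
    """Assemble TypedAtoms, deriving flags from geometry where needed.

    Without explicit connectivity a carbon is treated as hydrophobic when no
    N/O/S heavy atom lies within bonding range (documented approximation), and
    an N/O is a donor when a polar hydrogen (HD) was written within bonding
    range of it.
    """
    n = len(elements)
    elem_arr = np.array(elements)
    hetero_mask = np.isin(elem_arr, ("N", "O", "S"))
    if hetero_mask.any():
        from scipy.spatial.distance import cdist

        d_het = cdist(coords, coords[hetero_mask])
    else:
        d_het = np.full((n, 0), np.inf)

    if hd_coords:
        from scipy.spatial.distance import cdist

        d_hd = cdist(coords, np.array(hd_coords))
        has_polar_h = (d_hd <= _POLAR_H_BOND_MAX).any(axis=1)
    else:
        has_polar_h = np.zeros(n, dtype=bool)

    atoms: list[TypedAtom] = []
    for i in range(n):
        element = elements[i]
        ptype = pdbqt_types[i]
        if ptype is not None:
            acceptor = ptype.upper() in ("NA", "OA")
        else:
            acceptor = element in ("N", "O")
        hydrophobic = False
        if element == "C":
            near_hetero = d_het[i][d_het[i] > 1e-9]  # exclude self if hetero
            hydrophobic = not (near_hetero <= _HETERO_CONTACT_MAX).any()
        donor = element in ("N", "O") and bool(has_polar_h[i])
        atoms.append(
            TypedAtom(
                element=element,
                coords=coords[i],
                role=role,
                pdbqt_type=ptype,
                is_hydrophobic=hydrophobic,
                is_hbond_donor=donor,
                is_hbond_acceptor=acceptor,
                vdw_radius=vdw_radius(element),
            )
        )
    return atoms


def count_rotatable_bonds(torsions: TorsionInfo) -> int:
    """Nrot from PDBQT torsion metadata.

    The REMARK-declared active-torsion count takes precedence; BRANCH records
    are the fallback.  A mismatch between the two is logged, not fatal.
    """
    remark = torsions.remark_active_torsions
    if remark is not None:
        if torsions.branch_count and torsions.branch_count != remark:
            logger.warning(
                "active-torsion REMARK (%d) disagrees with BRANCH count (%d); "
                "using the REMARK value",
                remark,
                torsions.branch_count,
            )
        return remark
    return torsions.branch_count


_ELEMENT_PDBQT_TYPE = {
    "C": "C", "N": "N", "O": "OA", "S": "SA", "P": "P",
    "F": "F", "Cl": "CL", "Br": "BR", "I": "I",
}


def write_pdbqt(atoms: list[TypedAtom], torsions: TorsionInfo | None = None) -> str:
    """Serialise atoms back to minimal PDBQT text (test fixtures, round trips).

    Donor N/O atoms get an explicit HD hydrogen written 0.98 A away so that
    re-parsing recovers the donor flag (hydrogens themselves are stripped on
    read).
    """
    lines: list[str] = []
    if torsions is not None and torsions.remark_active_torsions is not None:
        lines.append(f"REMARK  {torsions.remark_active_torsions} active torsions:")
    serial = 0

    def _atom_line(name: str, x: float, y: float, z: float, ptype: str) -> str:
        nonlocal serial
        serial += 1
        return (
            f"ATOM  {serial:5d}  {name:<3s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    +0.000 {ptype}"
        )

    for atom in atoms:
        ptype = atom.pdbqt_type
        if ptype is None:
            ptype = _ELEMENT_PDBQT_TYPE.get(atom.element, atom.element.upper())
            if atom.element == "N" and atom.is_hbond_acceptor:
                ptype = "NA"
            if atom.element == "O" and not atom.is_hbond_acceptor:
                ptype = "O"
        name = atom.element.upper()[:2]
        x, y, z = atom.coords
        lines.append(_atom_line(name, x, y, z, ptype))
        if atom.is_hbond_donor:
            lines.append(_atom_line("HD", x + 0.98, y, z, "HD"))
    if torsions is not None:
        for b in range(torsions.branch_count):
            lines.append(f"BRANCH   1   {b + 2}")
    return "\n".join(lines) + "\n"


def load_complex(
    protein_path: str,
    ligand_path: str,
    complex_id: str | None = None,
) -> MolecularComplex:
    """Read a protein (PDB or PDBQT) and a ligand (PDBQT) into one complex."""
    from pathlib import Path

    ppath, lpath = Path(protein_path), Path(ligand_path)
    ptext = ppath.read_text()
    if ppath.suffix.lower() == ".pdbqt":
        protein_atoms, _ = parse_pdbqt(ptext, "protein", source=str(ppath))
    else:
        protein_atoms = parse_pdb(ptext, "protein", source=str(ppath))
    ligand_atoms, torsions = parse_pdbqt(lpath.read_text(), "ligand", source=str(lpath))
    return MolecularComplex(
        id=complex_id or lpath.stem,
        protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms,
        n_rotatable_bonds=count_rotatable_bonds(torsions),
    )
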