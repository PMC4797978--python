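"""Structure I/O: PDB / Tripos mol2 / pdbqt parsing and the paired library.

Cross-docking operates on a family of pre-aligned receptor/ligand complexes.
Receptors and their co-crystallized ligands live in two directories and are
matched by a naming convention: ``<root>-p.<ext>`` for the receptor and
``<root>-l.<ext>`` for the ligand.  All coordinates are Cartesian angstroms
exactly as stored in the files; no superposition or re-centering is ever
applied, because the in-place RMSD bookkeeping downstream assumes one shared
crystallographic frame.

The parsers here deliberately preserve file atom order through every
transformation: docked poses reference the submitted ligand positionally.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "ReceptorLigandPair",
    "StructureLibrary",
    "StructureError",
    "FormatError",
    "PairingError",
    "read_structure",
    "write_structure",
    "strip_waters",
    "build_library",
    "perceive_bonds",
    "WATER_RESIDUES",
    "COVALENT_RADII",
]


class StructureError(Exception):
    """Base error for structure parsing and library assembly."""


class FormatError(StructureError):
    """Unknown or malformed structure format."""


class PairingError(StructureError):
    """Receptor/ligand naming convention violated (orphans or duplicates)."""


#: Residue names treated as water and removed from receptors on load.
WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD"})

# Cordero et al. single-bond covalent radii (angstrom) for the elements that
# occur in drug-like ligands and protein/cofactor structures.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "HE": 0.28,
    "LI": 1.28, "BE": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "NE": 0.58,
    "NA": 1.66, "MG": 1.41, "AL": 1.21, "SI": 1.11, "P": 1.07, "S": 1.05,
    "CL": 1.02, "AR": 1.06,
    "K": 2.03, "CA": 1.76, "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24,
    "CU": 1.32, "ZN": 1.22, "SE": 1.20, "BR": 1.20, "I": 1.39,
}

# Two-letter element symbols we recognise when deriving elements from atom
# names (PDB files without a proper element column).
_TWO_LETTER = {s for s in COVALENT_RADII if len(s) == 2}


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus Cartesian coordinates in angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    coords: tuple[float, float, float]
    is_hetero: bool = False
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise StructureError(f"non-finite coordinates for atom {self.name!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Molecule:
    """An ordered list of atoms with an optional bond list.

    Atom order is the file order and is preserved through every
    transformation; bond indices are 0-based into ``atoms``.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for i, j in self.bonds:
            if i == j:
                raise StructureError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond ({i},{j}) references a missing atom")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise StructureError(f"duplicate bond {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Same topology, new coordinates (one row per atom)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} != ({len(self.atoms)}, 3)"
            )
        atoms = [replace(a, coords=tuple(map(float, xyz)))
                 for a, xyz in zip(self.atoms, coords)]
        return Molecule(self.name, atoms, list(self.bonds), self.source_format)


@dataclass(frozen=True)
class ReceptorLigandPair:
    """A receptor and its co-crystallized ligand sharing one root name."""

    root: str
    receptor: Molecule
    ligand: Molecule


@dataclass
class StructureLibrary:
    """The full family of pairs, sorted lexicographically by root."""

    pairs: list[ReceptorLigandPair]

    def __post_init__(self) -> None:
        roots = [p.root for p in self.pairs]
        if len(set(roots)) != len(roots):
            raise PairingError(f"duplicate roots in library: {sorted(roots)}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterable[ReceptorLigandPair]:
        return iter(self.pairs)

    @property
    def roots(self) -> list[str]:
        return [p.root for p in self.pairs]

    def pair(self, root: str) -> ReceptorLigandPair:
        for p in self.pairs:
            if p.root == root:
                return p
        raise KeyError(root)


# ---------------------------------------------------------------------------
# element derivation


def element_from_name(name: str, residue_name: str = "") -> str:
    """Derive the element symbol from a PDB-style atom name.

    PDB atom names encode the element in columns 13-14; names such as
    ``1HB`` or ``HG21`` are hydrogens, ``CA`` in a protein residue is an
    alpha-carbon but in a HETATM ion record means calcium.  We use the
    standard heuristic: strip digits, prefer a two-letter match only when
    the raw name is right-justified into the element columns.
    """
    stripped = re.sub(r"[^A-Za-z]", "", name).upper()
    if not stripped:
        raise FormatError(f"cannot derive element from atom name {name!r}")
    if name[:1].isdigit() or name[:1] == " ":
        # digit- or space-led names are single-element (e.g. "1HB", " CA")
        return stripped[0]
    if stripped[:2] in _TWO_LETTER and residue_name.strip().upper() == stripped[:2]:
        # monoatomic ion residues (e.g. residue "ZN", atom "ZN")
        return stripped[:2]
    if stripped[:2] in {"CL", "BR"}:
        return stripped[:2]
    return stripped[0]


def _normalise_element(raw: str, name: str, residue: str) -> str:
    raw = raw.strip()
    if raw:
        return raw[:1].upper() + raw[1:].lower() if len(raw) > 1 else raw.upper()
    e = element_from_name(name, residue)
    return e[:1].upper() + e[1:].lower() if len(e) > 1 else e


# ---------------------------------------------------------------------------
# parsers


def _parse_pdb_like(text: str, name: str, fmt: str) -> Molecule:
    """Shared PDB/pdbqt reader: fixed-column ATOM/HETATM records.

    pdbqt files append partial charge and AutoDock atom type after the
    standard columns and interleave ROOT/BRANCH/TORSDOF torsion-tree lines;
    all of those are ignored here.  Multi-model files yield the first model.
    """
    atoms: list[Atom] = []
    in_model = 0
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM", "HETATM"):
            continue
        line = line.ljust(80)
        try:
            serial = int(line[6:11].strip() or len(atoms) + 1)
            atom_name = line[12:16].strip()
            residue = line[17:20].strip()
            chain = line[21].strip() or " "
            resnum = int(line[22:26].strip() or 0)
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            bfac = float(line[60:66].strip() or 0.0)
        except ValueError as exc:
            raise FormatError(f"{name}: malformed {rec} record: {line.rstrip()!r}") from exc
        if fmt == "pdbqt":
            # element from the AutoDock atom type (columns 77+), falling back
            # to the atom name; types like "OA", "NA", "HD", "A" (aromatic C)
            adtype = line[77:79].strip()
            element = _ADTYPE_TO_ELEMENT.get(adtype.upper()) if adtype else None
            if element is None:
                element = _normalise_element("", atom_name, residue)
        else:
            element = _normalise_element(line[76:78], atom_name, residue)
        atoms.append(Atom(serial, atom_name, element, residue, chain, resnum,
                          (x, y, z), is_hetero=(rec == "HETATM"), b_factor=bfac))
    if not atoms:
        raise StructureError(f"{name}: no atoms parsed")
    return Molecule(name, atoms, [], fmt)


# AutoDock atom types that do not equal their element symbol.
_ADTYPE_TO_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "O": "O", "SA": "S", "S": "S", "H": "H", "HD": "H", "HS": "H", "F": "F",
    "CL": "Cl", "BR": "Br", "I": "I", "P": "P", "ZN": "Zn", "MG": "Mg",
    "MN": "Mn", "CA": "Ca", "FE": "Fe",
}


def _parse_mol2(text: str, name: str) -> Molecule:
    """Tripos mol2: @<TRIPOS>ATOM and @<TRIPOS>BOND sections, first molecule."""
    section = None
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    serial_to_index: dict[int, int] = {}
    n_molecules = 0
    for line in text.splitlines():
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            if section == "MOLECULE":
                n_molecules += 1
                if n_molecules > 1:
                    break
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{name}: malformed mol2 atom line: {line!r}")
            try:
                serial = int(parts[0])
                atom_name = parts[1]
                x, y, z = (float(parts[2]), float(parts[3]), float(parts[4]))
                sybyl = parts[5]
            except ValueError as exc:
                raise FormatError(f"{name}: malformed mol2 atom line: {line!r}") from exc
            resnum = int(parts[6]) if len(parts) > 6 else 1
            resname = parts[7][:3] if len(parts) > 7 else "LIG"
            element = sybyl.split(".")[0]
            if element.upper() not in COVALENT_RADII and element.upper() != "DU":
                element = element_from_name(atom_name)
            element = element[:1].upper() + element[1:].lower()
            serial_to_index[serial] = len(atoms)
            atoms.append(Atom(serial, atom_name, element, resname, " ",
                              resnum, (x, y, z), is_hetero=False))
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{name}: malformed mol2 bond line: {line!r}")
            try:
                a, b = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{name}: malformed mol2 bond line: {line!r}") from exc
            bonds.append((serial_to_index[a], serial_to_index[b]))
    if not atoms:
        raise StructureError(f"{name}: no atoms parsed")
    return Molecule(name, atoms, bonds, "mol2")


_EXTENSIONS = {".pdb": "pdb", ".pdbqt": "pdbqt", ".mol2": "mol2", ".ent": "pdb"}


def read_structure(path: str | Path, fmt: str | None = None) -> Molecule:
    """Read one molecule from a PDB, Tripos mol2, or pdbqt file.

    Atom order follows the file; mol2 bonds are populated, PDB/pdbqt bonds
    are left empty for later perception.  Multi-model files yield the first
    model only.
    """
    path = Path(path)
    if fmt is None:
        fmt = _EXTENSIONS.get(path.suffix.lower())
        if fmt is None:
            raise FormatError(f"cannot infer format from extension of {path.name!r}")
    fmt = fmt.lower()
    if fmt not in ("pdb", "pdbqt", "mol2"):
        raise FormatError(f"unsupported format {fmt!r}")
    try:
        text = path.read_text()
    except OSError as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc
    name = path.stem
    if fmt == "mol2":
        return _parse_mol2(text, name)
    return _parse_pdb_like(text, name, fmt)


def write_structure(molecule: Molecule, path: str | Path, fmt: str | None = None) -> None:
    """Write a molecule as PDB or Tripos mol2 (the round-trippable formats)."""
    path = Path(path)
    if fmt is None:
        fmt = _EXTENSIONS.get(path.suffix.lower(), "pdb")
    if fmt == "mol2":
        lines = ["@<TRIPOS>MOLECULE", molecule.name,
                 f"{len(molecule.atoms)} {len(molecule.bonds)} 0 0 0",
                 "SMALL", "NO_CHARGES", "", "@<TRIPOS>ATOM"]
        for i, a in enumerate(molecule.atoms, start=1):
            lines.append(
                f"{i:>7} {a.name:<8} {a.coords[0]:>10.4f} {a.coords[1]:>10.4f} "
                f"{a.coords[2]:>10.4f} {a.element:<5} {a.residue_number:>3} "
                f"{a.residue_name:<4} 0.0000"
            )
        lines.append("@<TRIPOS>BOND")
        for k, (i, j) in enumerate(molecule.bonds, start=1):
            lines.append(f"{k:>6} {i + 1:>5} {j + 1:>5} 1")
        path.write_text("\n".join(lines) + "\n")
        return
    lines = []
    for i, a in enumerate(molecule.atoms, start=1):
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name4 = a.name if len(a.name) == 4 else f" {a.name:<3}"
        lines.append(
            f"{rec}{i:>5} {name4:<4} {a.residue_name:<3} {a.chain_id:1}"
            f"{a.residue_number:>4}    {a.coords[0]:>8.3f}{a.coords[1]:>8.3f}"
            f"{a.coords[2]:>8.3f}{1.0:>6.2f}{a.b_factor:>6.2f}          "
            f"{a.element:>2}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# operations


def strip_waters(molecule: Molecule,
                 water_residues: frozenset[str] | set[str] = WATER_RESIDUES) -> Molecule:
    """Remove water residues; cofactors and coenzymes stay (idempotent)."""
    keep = [i for i, a in enumerate(molecule.atoms)
            if a.residue_name.upper() not in water_residues]
    if len(keep) == len(molecule.atoms):
        return molecule
    index_map = {old: new for new, old in enumerate(keep)}
    bonds = [(index_map[i], index_map[j]) for i, j in molecule.bonds
             if i in index_map and j in index_map]
    return Molecule(molecule.name, [molecule.atoms[i] for i in keep],
                    bonds, molecule.source_format)


def _scan_roots(directory: Path, suffix: str) -> dict[str, Path]:
    """Map root name -> file for every structure file ending in ``suffix``."""
    found: dict[str, list[Path]] = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() not in _EXTENSIONS or not p.is_file():
            continue
        if p.stem.endswith(suffix):
            found.setdefault(p.stem[: -len(suffix)], []).append(p)
    dupes = {r: [f.name for f in fs] for r, fs in found.items() if len(fs) > 1}
    if dupes:
        raise PairingError(f"duplicate roots with different extensions: {dupes}")
    return {r: fs[0] for r, fs in found.items()}


def build_library(receptor_dir: str | Path, ligand_dir: str | Path,
                  water_residues: frozenset[str] | set[str] = WATER_RESIDUES,
                  ) -> StructureLibrary:
    """Assemble the paired library from the two structure directories.

    Pairing is by root name across the ``-p``/``-l`` suffix convention,
    case-sensitive on the root, extension-agnostic.  Waters are stripped
    from receptors on load.  Orphans on either side are an error that names
    every unmatched root.
    """
    receptor_dir, ligand_dir = Path(receptor_dir), Path(ligand_dir)
    for d in (receptor_dir, ligand_dir):
        if not d.is_dir():
            raise StructureError(f"not a directory: {d}")
    receptors = _scan_roots(receptor_dir, "-p")
    ligands = _scan_roots(ligand_dir, "-l")
    orphans = sorted(set(receptors) ^ set(ligands))
    if orphans:
        raise PairingError(f"unpaired roots: {orphans}")
    if not receptors:
        raise PairingError("no receptor/ligand pairs found")
    pairs = []
    for root in sorted(receptors):
        receptor = strip_waters(read_structure(receptors[root]), water_residues)
        ligand = read_structure(ligands[root])
        pairs.append(ReceptorLigandPair(root, receptor, ligand))
    return StructureLibrary(pairs)


def perceive_bonds(molecule: Molecule, tolerance: float = 1.3) -> Molecule:
    """Add bonds between atoms closer than ``tolerance`` x sum of covalent radii.

    Molecules that already carry bonds (mol2 input) are returned unchanged.
    """
    if molecule.bonds:
        return molecule
    radii = []
    for a in molecule.atoms:
        r = COVALENT_RADII.get(a.element.upper())
        if r is None:
            raise StructureError(f"no covalent radius for element {a.element!r}")
        radii.append(r)
    coords = molecule.coords
    n = len(coords)
    bonds: list[tuple[int, int]] = []
    if n > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        cutoff = tolerance * (np.array(radii)[:, None] + np.array(radii)[None, :])
        ii, jj = np.nonzero((dist <= cutoff) & (dist > 1e-6))
        bonds = [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]
    return Molecule(molecule.name, list(molecule.atoms), bonds,
                    molecule.source_format)
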