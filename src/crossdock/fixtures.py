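"""Synthetic aligned receptor/ligand families with planted docking outcomes.

Every other module is exercised against families generated here: toy
ligands with controlled topology (asymmetric chains, swap-pair symmetric
heads, all-carbon rings) sitting inside minimal cage "receptors", all in one
shared coordinate frame by construction.  Planted per-cell pose offsets and
energies give the mock engine an exact ground truth, so pipeline results can
be checked to numerical precision end to end.

The receptors are point scaffolds, not physically meaningful proteins: the
pipeline under test never evaluates physics, only geometry and bookkeeping.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import MockEngine
from .structures import (Atom, Molecule, StructureLibrary, build_library,
                         write_structure)

__all__ = ["FixtureSpec", "FixtureFamily", "generate_family", "make_ligand"]

Symmetry = str  # one of {"none", "swap-pair", "ring"}

_BOND_LENGTH = 1.5  # angstrom, generic single-bond scale


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic family.

    ``planted_pose_offsets``/``planted_energies`` optionally fix, per
    ``(ligand_root, receptor_root)`` cell, the rigid displacement (angstrom)
    and energy (kcal/mol) of every mock pose; both lists must have equal
    length in each cell.  Cells without planted values get seeded ones from
    the mock engine.
    """

    n_pairs: int = 3
    ligand_size: int = 5
    symmetry: Symmetry = "none"
    planted_pose_offsets: dict[tuple[str, str], list[float]] = field(
        default_factory=dict)
    planted_energies: dict[tuple[str, str], list[float]] = field(
        default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_pairs <= 20):
            raise ValueError("n_pairs must be in 1..20")
        if not (3 <= self.ligand_size <= 12):
            raise ValueError("ligand_size must be in 3..12")
        if self.symmetry not in ("none", "swap-pair", "ring"):
            raise ValueError(f"unknown symmetry kind {self.symmetry!r}")
        if set(self.planted_pose_offsets) != set(self.planted_energies):
            raise ValueError("planted offsets and energies cover different cells")
        for cell in self.planted_pose_offsets:
            if len(self.planted_pose_offsets[cell]) != len(self.planted_energies[cell]):
                raise ValueError(f"planted lists differ in length for cell {cell}")

    @property
    def roots(self) -> list[str]:
        return list(string.ascii_lowercase[: self.n_pairs])

    @property
    def planted(self) -> dict[tuple[str, str], list[tuple[float, float]]]:
        return {cell: list(zip(self.planted_pose_offsets[cell],
                               self.planted_energies[cell]))
                for cell in self.planted_pose_offsets}


def make_ligand(name: str, size: int, symmetry: Symmetry,
                rng: np.random.Generator,
                center: np.ndarray | None = None) -> Molecule:
    """Build one toy ligand of ``size`` heavy atoms with the given topology.

    * ``none`` — a zig-zag chain whose element sequence (S then a C/N/O
      cycle) has no graph automorphism besides the identity.
    * ``swap-pair`` — a carboxylate-like head: one carbon bearing two
      equivalent oxygens, continued by a carbon tail; the two oxygens are
      interchangeable, giving a nontrivial automorphism.
    * ``ring`` — an all-carbon regular ring (the full dihedral symmetry
      group of the polygon).
    """
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    coords: list[np.ndarray] = []
    elements: list[str] = []
    bonds: list[tuple[int, int]] = []

    if symmetry == "ring":
        radius = _BOND_LENGTH / (2 * np.sin(np.pi / size))
        for k in range(size):
            theta = 2 * np.pi * k / size
            coords.append(np.array([radius * np.cos(theta),
                                    radius * np.sin(theta), 0.0]))
            elements.append("C")
            bonds.append((k, (k + 1) % size))
    elif symmetry == "swap-pair":
        # head: C0 with O1/O2 at +-y; tail: zig-zag carbons along +x
        coords.append(np.array([0.0, 0.0, 0.0]))
        elements.append("C")
        for sign in (1.0, -1.0):
            coords.append(np.array([-0.6, sign * 1.1, 0.0]))
            elements.append("O")
            bonds.append((0, len(coords) - 1))
        prev = 0
        for k in range(size - 3):
            zig = 0.4 if k % 2 == 0 else -0.4
            coords.append(np.array([(k + 1) * 1.45, zig, 0.3]))
            elements.append("C")
            bonds.append((prev, len(coords) - 1))
            prev = len(coords) - 1
    else:
        cycle = ["C", "N", "O"]
        for k in range(size):
            zig = 0.45 if k % 2 == 0 else -0.45
            coords.append(np.array([k * 1.4, zig, 0.0]))
            elements.append("S" if k == 0 else cycle[(k - 1) % 3])
            if k > 0:
                bonds.append((k - 1, k))

    pts = np.array(coords)
    pts = pts - pts.mean(axis=0) + center
    # tiny seeded jitter keeps geometry generic without breaking bond
    # perception (cutoffs tolerate +-0.05 angstrom easily)
    pts = pts + rng.uniform(-0.05, 0.05, size=pts.shape)

    counts: dict[str, int] = {}
    atoms = []
    for i, (el, xyz) in enumerate(zip(elements, pts)):
        counts[el] = counts.get(el, 0) + 1
        atoms.append(Atom(i + 1, f"{el}{counts[el]}", el, "LIG", " ", 1,
                          tuple(map(float, xyz)), is_hetero=True))
    return Molecule(name, atoms, bonds, "pdb")


def _make_receptor(name: str, site: np.ndarray, rng: np.random.Generator,
                   n_cage: int = 20, with_waters: bool = True) -> Molecule:
    """A rigid cage of carbon pseudo-atoms around the binding site.

    A Fibonacci sphere of radius 8 angstrom plays the pocket; two water
    molecules are appended so loading exercises water stripping.
    """
    atoms = []
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for k in range(n_cage):
        z = 1.0 - 2.0 * (k + 0.5) / n_cage
        r = np.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * k
        xyz = site + 8.0 * np.array([r * np.cos(theta), r * np.sin(theta), z])
        xyz = xyz + rng.uniform(-0.1, 0.1, size=3)
        atoms.append(Atom(k + 1, "CA", "C", "ALA", "A", k + 1,
                          tuple(map(float, xyz))))
    if with_waters:
        for w in range(2):
            xyz = site + np.array([12.0 + w, 12.0, 12.0])
            atoms.append(Atom(len(atoms) + 1, "O", "O", "HOH", "A",
                              100 + w, tuple(map(float, xyz)), is_hetero=True))
    return Molecule(name, atoms, [], "pdb")


@dataclass
class FixtureFamily:
    """A generated family on disk plus its planted ground truth."""

    spec: FixtureSpec
    receptor_dir: Path
    ligand_dir: Path
    reference_ligands: dict[str, Molecule]

    @property
    def roots(self) -> list[str]:
        return self.spec.roots

    def library(self) -> StructureLibrary:
        return build_library(self.receptor_dir, self.ligand_dir)

    def engine(self, fail_cells=None) -> MockEngine:
        """Mock engine wired to this family's references and planted truth.

        References are re-read from the files on disk so the planted poses
        are exact translations of the crystal coordinates the scorer sees.
        """
        return MockEngine.for_library(self.library(), self.spec.planted,
                                      self.spec.seed,
                                      fail_cells=set(fail_cells or ()))


def generate_family(spec: FixtureSpec, out_dir: str | Path) -> FixtureFamily:
    """Materialize the family as PDB files under ``out_dir``.

    Writes ``receptors/<root>-p.pdb`` and ``ligands/<root>-l.pdb`` for each
    root, all in one frame (pre-aligned by construction; binding sites of
    the pairs nearly coincide, as after a structural alignment).
    Deterministic: the same spec and seed give byte-identical files.
    """
    out_dir = Path(out_dir)
    receptor_dir = out_dir / "receptors"
    ligand_dir = out_dir / "ligands"
    receptor_dir.mkdir(parents=True, exist_ok=True)
    ligand_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    references: dict[str, Molecule] = {}
    for root in spec.roots:
        site = rng.uniform(-0.8, 0.8, size=3)
        ligand = make_ligand(f"{root}-l", spec.ligand_size, spec.symmetry,
                             rng, center=site)
        receptor = _make_receptor(f"{root}-p", site, rng)
        write_structure(ligand, ligand_dir / f"{root}-l.pdb")
        write_structure(receptor, receptor_dir / f"{root}-p.pdb")
        references[root] = ligand
    return FixtureFamily(spec, receptor_dir, ligand_dir, references)
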