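"""Docking-engine contract, a deterministic mock engine, and a Vina adapter.

The harness never implements a conformational search or scoring function of
its own; docking is delegated through one small interface so the pipeline is
testable without any external binary.  Two adapters are provided:

* :class:`MockEngine` — a pure function of its inputs and seed.  Poses are
  the ligand's crystal conformation rigidly displaced by planted (or seeded)
  offsets, so every pose has a known ground-truth RMSD and energy.  This is
  what the test suite and the synthetic families run against.
* :class:`VinaEngine` — shells out to an AutoDock Vina executable, writing
  a per-cell work directory with the standard config-file keys and parsing
  the multi-model pdbqt output (``REMARK VINA RESULT`` lines).
"""

from __future__ import annotations

import hashlib
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .structures import Molecule, StructureError, read_structure, write_structure

__all__ = [
    "GridBox",
    "DockingParams",
    "Pose",
    "DockingResult",
    "DockingEngine",
    "EngineError",
    "EngineConfigurationError",
    "MockEngine",
    "VinaEngine",
    "compute_box_center",
    "parse_vina_poses",
]


class EngineError(RuntimeError):
    """The engine failed; carries the engine's diagnostic text."""


class EngineConfigurationError(EngineError):
    """The engine executable or its prerequisites are missing."""


@dataclass(frozen=True)
class GridBox:
    """Rectangular search volume: center and edge lengths in angstrom."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError(f"grid box sizes must be positive, got {self.size}")


@dataclass(frozen=True)
class DockingParams:
    """Engine run parameters; the defaults reproduce a standard run
    (exhaustiveness 8, ligand randomized before docking)."""

    exhaustiveness: int = 8
    num_modes: int = 9
    energy_range: float | None = None
    seed: int | None = None
    randomize_first: bool = True

    def __post_init__(self) -> None:
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be a positive integer")
        if self.num_modes < 1:
            raise ValueError("num_modes must be a positive integer")
        if self.energy_range is not None and self.energy_range < 0:
            raise ValueError("energy_range must be nonnegative")


@dataclass(frozen=True)
class Pose:
    """One binding mode: coordinates in ligand atom order plus its energy."""

    mode_index: int
    coords: tuple[tuple[float, float, float], ...]
    energy: float

    @property
    def coord_array(self) -> np.ndarray:
        return np.array(self.coords, dtype=float)


@dataclass
class DockingResult:
    """Engine output for one (ligand, receptor) cell, best energy first."""

    poses: list[Pose]
    engine_name: str
    log: str = ""

    def __post_init__(self) -> None:
        energies = [p.energy for p in self.poses]
        if energies != sorted(energies):
            raise EngineError(f"poses not sorted by energy: {energies}")


class DockingEngine(Protocol):
    """The docking contract every adapter satisfies."""

    name: str

    def randomize_ligand(self, ligand: Molecule, receptor: Molecule,
                         box: GridBox, seed: int | None = None) -> Molecule:
        """Return a randomized conformation of the ligand inside the box."""
        ...

    def dock(self, receptor: Molecule, ligand: Molecule, box: GridBox,
             params: DockingParams) -> DockingResult:
        """Dock the ligand into the receptor's grid box."""
        ...


def compute_box_center(native_ligand: Molecule) -> tuple[float, float, float]:
    """Unweighted centroid of the ligand's heavy atoms.

    The grid box is centered on the receptor's own co-crystallized ligand:
    with all structures in one aligned frame, that centroid marks the
    binding site for every incoming ligand.
    """
    heavy = native_ligand.heavy_atoms()
    if not heavy:
        raise StructureError(f"ligand {native_ligand.name!r} has no heavy atoms")
    coords = np.array([a.coords for a in heavy], dtype=float)
    return tuple(float(c) for c in coords.mean(axis=0))


# ---------------------------------------------------------------------------
# mock engine


def _cell_seed(seed: int, *tokens: str) -> int:
    """Stable per-cell seed below 2**31, derived from a global seed."""
    h = hashlib.sha256(("|".join(map(str, (seed,) + tokens))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _root_of(molecule: Molecule) -> str:
    """Ligand/receptor root name from the molecule's file stem."""
    return re.sub(r"-[lp]$", "", molecule.name)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@dataclass
class MockEngine:
    """Deterministic engine with known ground truth.

    ``references`` holds each ligand root's crystal heavy-atom coordinates;
    poses are that conformation rigidly translated by an offset of known
    magnitude, so the in-place RMSD of pose k is exactly its offset.

    ``planted`` optionally fixes per-cell ``(offset_A, energy_kcal)`` lists,
    keyed ``(ligand_root, receptor_root)``; cells without a planted entry get
    seeded offsets in [0, 4) angstrom with energy = -10 + offset, a monotone
    map that makes energy rank follow displacement.
    """

    references: dict[str, np.ndarray]
    planted: dict[tuple[str, str], list[tuple[float, float]]] = field(
        default_factory=dict)
    seed: int = 0
    name: str = "mock"
    fail_cells: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def for_library(cls, library, planted=None, seed: int = 0,
                    fail_cells=None) -> "MockEngine":
        refs = {
            pair.root: np.array([a.coords for a in pair.ligand.heavy_atoms()],
                                dtype=float)
            for pair in library
        }
        return cls(refs, dict(planted or {}), seed,
                   fail_cells=set(fail_cells or ()))

    def randomize_ligand(self, ligand: Molecule, receptor: Molecule,
                         box: GridBox, seed: int | None = None) -> Molecule:
        """Seeded rigid rotation about the centroid plus translation into the box.

        Mirrors a real engine's randomize-only step: hydrogens are dropped
        (pose files carry the heavy-atom representation) and heavy-atom
        identity and order are preserved.
        """
        rng = np.random.default_rng(
            _cell_seed(self.seed if seed is None else seed, "randomize",
                       ligand.name, receptor.name))
        heavy_idx = ligand.heavy_indices()
        heavy_atoms = [ligand.atoms[i] for i in heavy_idx]
        reindex = {old: new for new, old in enumerate(heavy_idx)}
        bonds = [(reindex[i], reindex[j]) for i, j in ligand.bonds
                 if i in reindex and j in reindex]
        stripped = Molecule(ligand.name, heavy_atoms, bonds, ligand.source_format)
        coords = stripped.coords
        centroid = coords.mean(axis=0)
        rot = _random_rotation(rng)
        target = np.array(box.center) + (rng.random(3) - 0.5) * np.array(box.size) * 0.5
        return stripped.with_coords((coords - centroid) @ rot.T + target)

    def dock(self, receptor: Molecule, ligand: Molecule, box: GridBox,
             params: DockingParams) -> DockingResult:
        lig_root, rec_root = _root_of(ligand), _root_of(receptor)
        if (lig_root, rec_root) in self.fail_cells:
            raise EngineError(f"planted failure for cell ({lig_root}, {rec_root})")
        if lig_root not in self.references:
            raise EngineError(f"mock engine has no reference for ligand {lig_root!r}")
        ref = self.references[lig_root]
        rng = np.random.default_rng(
            _cell_seed(self.seed if params.seed is None else params.seed,
                       "dock", lig_root, rec_root))
        cell = self.planted.get((lig_root, rec_root))
        if cell is None:
            offsets = np.sort(rng.random(params.num_modes) * 4.0)
            cell = [(float(d), -10.0 + float(d)) for d in offsets]
        pose_list: list[Pose] = []
        for offset, energy in cell:
            direction = rng.normal(size=3)
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            coords = ref + offset * direction
            pose_list.append(Pose(0, tuple(map(tuple, coords.tolist())), float(energy)))
        pose_list.sort(key=lambda p: p.energy)
        pose_list = [Pose(i + 1, p.coords, p.energy)
                     for i, p in enumerate(pose_list[: params.num_modes])]
        log = (f"mock dock {lig_root} -> {rec_root}: {len(pose_list)} poses, "
               f"seed={self.seed}")
        return DockingResult(pose_list, self.name, log)


# ---------------------------------------------------------------------------
# Vina adapter


_VINA_RESULT = re.compile(
    r"REMARK VINA RESULT:\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)")


def parse_vina_poses(text: str) -> list[Pose]:
    """Parse a Vina multi-model pdbqt: one Pose per MODEL block.

    Each block carries a ``REMARK VINA RESULT: <energy> <rmsd_lb> <rmsd_ub>``
    line; atoms are ATOM/HETATM records.  Hydrogens are kept here — the
    caller decides the heavy-atom subset.
    """
    poses: list[Pose] = []
    energy: float | None = None
    coords: list[tuple[float, float, float]] = []
    mode = 0

    def flush() -> None:
        nonlocal energy, coords
        if coords:
            if energy is None:
                raise EngineError("pose block without a REMARK VINA RESULT line")
            poses.append(Pose(len(poses) + 1, tuple(coords), energy))
        energy, coords = None, []

    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
            mode += 1
        elif rec == "ENDMDL":
            flush()
        elif line.startswith("REMARK VINA RESULT:"):
            m = _VINA_RESULT.search(line)
            if not m:
                raise EngineError(f"unparseable result line: {line!r}")
            energy = float(m.group(1))
        elif rec in ("ATOM", "HETATM"):
            try:
                coords.append((float(line[30:38]), float(line[38:46]),
                               float(line[46:54])))
            except ValueError as exc:
                raise EngineError(f"unparseable atom line: {line!r}") from exc
    flush()
    if not poses:
        raise EngineError("no poses found in engine output")
    return poses


@dataclass
class VinaEngine:
    """Adapter around an AutoDock Vina executable.

    Structures not already in pdbqt are converted with an external converter
    (Open Babel's ``obabel``); conversion is never reimplemented here.  Each
    call runs in its own work directory holding the engine config file with
    the standard keys (receptor, ligand, center_*, size_*, exhaustiveness,
    num_modes, energy_range, seed).
    """

    executable: str = "vina"
    converter: str = "obabel"
    name: str = "vina"
    keep_workdirs: bool = False
    workdir_root: Path | None = None

    def _check(self) -> None:
        if shutil.which(self.executable) is None:
            raise EngineConfigurationError(
                f"docking executable {self.executable!r} not found on PATH")

    def _to_pdbqt(self, molecule: Molecule, out: Path, receptor: bool) -> Path:
        if molecule.source_format == "pdbqt":
            src = out.with_suffix(".src.pdb")
            write_structure(molecule, src, fmt="pdb")
        else:
            src = out.with_suffix(f".src.{molecule.source_format}")
            write_structure(molecule, src, fmt=molecule.source_format)
        if shutil.which(self.converter) is None:
            raise EngineConfigurationError(
                f"structure converter {self.converter!r} not found on PATH")
        args = [self.converter, str(src), "-O", str(out)]
        if receptor:
            args += ["-xr"]
        proc = subprocess.run(args, capture_output=True, text=True)
        if proc.returncode != 0 or not out.exists():
            raise EngineError(f"pdbqt conversion failed: {proc.stderr}")
        return out

    def _workdir(self, tag: str) -> Path:
        if self.workdir_root is not None:
            d = Path(self.workdir_root) / tag
            d.mkdir(parents=True, exist_ok=True)
            return d
        return Path(tempfile.mkdtemp(prefix=f"crossdock-{tag}-"))

    def randomize_ligand(self, ligand: Molecule, receptor: Molecule,
                         box: GridBox, seed: int | None = None) -> Molecule:
        self._check()
        work = self._workdir("randomize")
        lig = self._to_pdbqt(ligand, work / "ligand.pdbqt", receptor=False)
        rec = self._to_pdbqt(receptor, work / "receptor.pdbqt", receptor=True)
        out = work / "randomized.pdbqt"
        cfg = self._write_config(work, rec, lig, box, DockingParams(seed=seed),
                                 out, randomize_only=True)
        self._run([self.executable, "--config", str(cfg), "--randomize_only"])
        return read_structure(out, fmt="pdbqt")

    def dock(self, receptor: Molecule, ligand: Molecule, box: GridBox,
             params: DockingParams) -> DockingResult:
        self._check()
        work = self._workdir("dock")
        lig = self._to_pdbqt(ligand, work / "ligand.pdbqt", receptor=False)
        rec = self._to_pdbqt(receptor, work / "receptor.pdbqt", receptor=True)
        out = work / "out.pdbqt"
        cfg = self._write_config(work, rec, lig, box, params, out)
        log = self._run([self.executable, "--config", str(cfg)])
        poses = parse_vina_poses(out.read_text())
        poses = poses[: params.num_modes]
        if not self.keep_workdirs and self.workdir_root is None:
            shutil.rmtree(work, ignore_errors=True)
        return DockingResult(poses, self.name, log)

    def _write_config(self, work: Path, receptor: Path, ligand: Path,
                      box: GridBox, params: DockingParams, out: Path,
                      randomize_only: bool = False) -> Path:
        lines = [
            f"receptor = {receptor}",
            f"ligand = {ligand}",
            f"center_x = {box.center[0]:.3f}",
            f"center_y = {box.center[1]:.3f}",
            f"center_z = {box.center[2]:.3f}",
            f"size_x = {box.size[0]:.3f}",
            f"size_y = {box.size[1]:.3f}",
            f"size_z = {box.size[2]:.3f}",
            f"out = {out}",
        ]
        if not randomize_only:
            lines += [f"exhaustiveness = {params.exhaustiveness}",
                      f"num_modes = {params.num_modes}"]
            if params.energy_range is not None:
                lines.append(f"energy_range = {params.energy_range}")
        if params.seed is not None:
            lines.append(f"seed = {params.seed}")
        cfg = work / "config.txt"
        cfg.write_text("\n".join(lines) + "\n")
        return cfg

    def _run(self, args: list[str]) -> str:
        proc = subprocess.run(args, capture_output=True, text=True)
        if proc.returncode != 0:
            raise EngineError(
                f"{self.executable} exited {proc.returncode}:\n{proc.stderr}")
        return proc.stdout
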