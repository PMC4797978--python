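"""Symmetry-aware, in-place heavy-atom RMSD between a pose and its reference.

Because every receptor of the family sits in one shared crystallographic
frame, pose quality is measured without any superposition: a fitted RMSD
would hide translation/rotation errors of the predicted binding mode, which
are exactly what cross-docking is meant to expose.

Topologically equivalent atoms (the two oxygens of a carboxylate, the ortho
carbons of a phenyl ring) must not be over-penalized when the engine reports
them in a different order than the crystal file.  ``symmetry_min_rmsd``
therefore minimizes over every automorphism of the ligand's heavy-atom graph
that preserves elements and bonds, enumerated with VF2.  A configurable cap
bounds the enumeration for pathologically symmetric molecules; past the cap
the identity mapping is used and the result is flagged as uncorrected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .structures import Molecule, perceive_bonds

__all__ = [
    "AtomMapping",
    "RmsdValue",
    "MappingError",
    "CorrespondenceError",
    "rmsd_in_place",
    "symmetry_min_rmsd",
    "heavy_atom_graph",
    "DEFAULT_AUTOMORPHISM_CAP",
]

log = logging.getLogger(__name__)

#: Automorphism mappings examined before falling back to the identity.
DEFAULT_AUTOMORPHISM_CAP = 10_000


class MappingError(ValueError):
    """Atom mapping is not a valid element-preserving bijection."""


class CorrespondenceError(ValueError):
    """Reference heavy atoms and pose coordinates cannot be put in correspondence."""


@dataclass(frozen=True)
class AtomMapping:
    """Bijection from reference heavy-atom positions to pose positions.

    ``pairs[i] = j`` maps the i-th reference heavy atom onto the j-th pose
    coordinate (both 0-based, in heavy-atom order).
    """

    pairs: tuple[int, ...]

    @classmethod
    def identity(cls, n: int) -> "AtomMapping":
        return cls(tuple(range(n)))

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, n: int) -> None:
        if len(self.pairs) != n or sorted(self.pairs) != list(range(n)):
            raise MappingError(
                f"mapping {self.pairs} is not a bijection on {n} atoms")


@dataclass(frozen=True)
class RmsdValue:
    """An RMSD in angstrom plus the mapping that produced it."""

    value: float
    mapping_used: AtomMapping
    symmetry_corrected: bool

    def __float__(self) -> float:
        return self.value


def _as_coords(pose_coords) -> np.ndarray:
    arr = np.asarray(pose_coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise CorrespondenceError(f"pose coordinates must be (n, 3), got {arr.shape}")
    if not np.isfinite(arr).all():
        raise CorrespondenceError("pose coordinates contain non-finite values")
    return arr


def rmsd_in_place(reference: Molecule, pose_coords, mapping: AtomMapping) -> RmsdValue:
    """RMSD over mapped heavy atoms in the shared frame (no fitting).

    value = sqrt( (1/N) * sum_i || r_ref(i) - r_pose(map(i)) ||^2 )
    """
    ref = np.array([a.coords for a in reference.heavy_atoms()], dtype=float)
    pose = _as_coords(pose_coords)
    n = len(ref)
    if n == 0:
        raise MappingError("no heavy atoms to map")
    mapping.validate(n)
    if len(pose) != n:
        raise CorrespondenceError(
            f"{n} reference heavy atoms but {len(pose)} pose coordinates")
    perm = np.fromiter(mapping.pairs, dtype=int)
    value = float(np.sqrt(((ref - pose[perm]) ** 2).sum() / n))
    return RmsdValue(value, mapping, symmetry_corrected=False)


def heavy_atom_graph(molecule: Molecule) -> nx.Graph:
    """Element-labelled heavy-atom graph; bonds perceived if absent."""
    mol = perceive_bonds(molecule)
    heavy = mol.heavy_indices()
    reindex = {old: new for new, old in enumerate(heavy)}
    g = nx.Graph()
    for new, old in enumerate(heavy):
        g.add_node(new, element=mol.atoms[old].element.upper())
    for i, j in mol.bonds:
        if i in reindex and j in reindex:
            g.add_edge(reindex[i], reindex[j])
    return g


def _automorphisms(g: nx.Graph, cap: int):
    """Yield up to ``cap`` element-preserving graph automorphisms as dicts."""
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    for count, iso in enumerate(matcher.isomorphisms_iter()):
        if count >= cap:
            return False
        yield iso
    return True


def symmetry_min_rmsd(reference: Molecule, pose_coords,
                      cap: int = DEFAULT_AUTOMORPHISM_CAP) -> RmsdValue:
    """Minimum in-place RMSD over heavy-atom graph automorphisms.

    The pose is the engine's transformation of the submitted ligand, so the
    base correspondence is positional (pose row i = reference heavy atom i);
    the automorphism group then absorbs any topologically equivalent
    relabelling.  Exceeding ``cap`` mappings falls back to the identity with
    ``symmetry_corrected=False`` and a warning.
    """
    pose = _as_coords(pose_coords)
    ref = np.array([a.coords for a in reference.heavy_atoms()], dtype=float)
    n = len(ref)
    if n == 0:
        raise MappingError("reference has no heavy atoms")
    if len(pose) != n:
        raise CorrespondenceError(
            f"{n} reference heavy atoms but {len(pose)} pose coordinates")
    g = heavy_atom_graph(reference)

    best_value = np.inf
    best_perm: tuple[int, ...] | None = None
    count = 0
    exhausted = True
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    for iso in matcher.isomorphisms_iter():
        if count >= cap:
            exhausted = False
            break
        count += 1
        perm = tuple(iso[i] for i in range(n))
        idx = np.fromiter(perm, dtype=int)
        value = float(np.sqrt(((ref - pose[idx]) ** 2).sum() / n))
        if value < best_value - 1e-15 or best_perm is None:
            best_value = value
            best_perm = perm
    if not exhausted:
        warnings.warn(
            f"automorphism enumeration exceeded cap={cap} for "
            f"{reference.name!r}; falling back to identity mapping",
            RuntimeWarning, stacklevel=2)
        log.warning("automorphism cap exceeded for %s", reference.name)
        return rmsd_in_place(reference, pose, AtomMapping.identity(n))
    assert best_perm is not None  # identity is always an automorphism
    return RmsdValue(best_value, AtomMapping(best_perm), symmetry_corrected=True)
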