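"""Shared fixtures: tiny molecules, synthetic families, brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from crossdock.structures import Atom, Molecule


def make_molecule(elements, coords, bonds, name="mol") -> Molecule:
    """Molecule from parallel element/coordinate lists and explicit bonds."""
    atoms = [Atom(i + 1, f"{el}{i + 1}", el, "LIG", " ", 1,
                  tuple(map(float, xyz)), is_hetero=True)
             for i, (el, xyz) in enumerate(zip(elements, coords))]
    return Molecule(name, atoms, list(bonds), "pdb")


def brute_force_min_rmsd(reference: Molecule, pose_coords: np.ndarray) -> float:
    """Independent oracle: minimum in-place RMSD over ALL element- and
    adjacency-preserving bijections of the heavy-atom set, by enumeration.

    Feasible for <= 7-8 heavy atoms; used to validate the automorphism-based
    implementation, never the other way around.
    """
    heavy = reference.heavy_atoms()
    n = len(heavy)
    ref = np.array([a.coords for a in heavy], dtype=float)
    pose = np.asarray(pose_coords, dtype=float)
    elements = [a.element for a in heavy]
    adjacency = {frozenset(b) for b in reference.bonds}

    # permute only within element classes
    classes: dict[str, list[int]] = {}
    for i, el in enumerate(elements):
        classes.setdefault(el, []).append(i)
    best = np.inf
    class_items = sorted(classes.items())
    for perms in itertools.product(
            *(itertools.permutations(idx) for _, idx in class_items)):
        mapping = [0] * n
        for (_, idx), perm in zip(class_items, perms):
            for src, dst in zip(idx, perm):
                mapping[src] = dst
        if {frozenset((mapping[i], mapping[j])) for i, j in adjacency} != adjacency:
            continue
        perm_arr = np.array(mapping)
        value = float(np.sqrt(((ref - pose[perm_arr]) ** 2).sum() / n))
        best = min(best, value)
    return best


def random_bonded_molecule(rng: np.random.Generator, n_max: int = 7) -> Molecule:
    """A random small molecule: random spanning tree plus occasional extra
    edge, elements drawn from {C, N, O}, coordinates in a 4-angstrom box."""
    n = int(rng.integers(3, n_max + 1))
    elements = [str(rng.choice(["C", "N", "O"])) for _ in range(n)]
    coords = rng.uniform(-2.0, 2.0, size=(n, 3))
    bonds = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    if n >= 4 and rng.random() < 0.4:  # one ring-closing edge
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        if (i, j) not in bonds and i != j:
            bonds.append((i, j))
    return make_molecule(elements, coords, bonds)


@pytest.fixture
def o_c_o() -> Molecule:
    """Linear O-C-O: the two oxygens are topologically equivalent."""
    return make_molecule(
        ["O", "C", "O"],
        [(-1.2, 0.0, 0.0), (0.0, 0.0, 0.0), (1.2, 0.0, 0.0)],
        [(0, 1), (1, 2)])


@pytest.fixture
def asymmetric_chain() -> Molecule:
    """C-N-C-O chain with a trivial automorphism group."""
    return make_molecule(
        ["C", "N", "C", "O"],
        [(0.0, 0.0, 0.0), (1.4, 0.3, 0.0), (2.8, -0.3, 0.0), (4.2, 0.3, 0.0)],
        [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def planted_family(tmp_path):
    """3-pair family with planted poses, including a cell where the
    best-RMSD and best-energy selections diverge."""
    from crossdock.fixtures import FixtureSpec, generate_family

    roots = ["a", "b", "c"]
    offsets, energies = {}, {}
    for lig in roots:
        for rec in roots:
            if lig == rec:
                offsets[(lig, rec)] = [0.0, 2.5]
                energies[(lig, rec)] = [-9.5, -8.0]
            elif (lig, rec) == ("a", "b"):
                # divergent cell: lowest RMSD is NOT the lowest energy
                offsets[(lig, rec)] = [0.5, 3.0]
                energies[(lig, rec)] = [-7.0, -9.0]
            else:
                offsets[(lig, rec)] = [1.2, 2.2, 4.0]
                energies[(lig, rec)] = [-8.5, -7.5, -6.0]
    spec = FixtureSpec(n_pairs=3, ligand_size=5, symmetry="none",
                       planted_pose_offsets=offsets,
                       planted_energies=energies, seed=11)
    return generate_family(spec, tmp_path / "family")
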