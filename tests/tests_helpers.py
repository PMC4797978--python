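"""Tiny molecule builders shared across test modules."""

from __future__ import annotations

from crossdock.structures import Atom, Molecule


def two_atoms(el1: str, el2: str, distance: float) -> Molecule:
    atoms = [
        Atom(1, el1, el1, "LIG", " ", 1, (0.0, 0.0, 0.0), is_hetero=True),
        Atom(2, el2, el2, "LIG", " ", 1, (distance, 0.0, 0.0), is_hetero=True),
    ]
    return Molecule("pair", atoms, [], "pdb")
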