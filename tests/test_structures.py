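"""Structure parsing, pairing, water stripping, and bond perception."""

import math

import numpy as np
import pytest

from crossdock.structures import (FormatError, PairingError, StructureError,
                                  build_library, perceive_bonds,
                                  read_structure, strip_waters,
                                  write_structure)
from crossdock.fixtures import FixtureSpec, generate_family

PDB_3ATOMS = """\
ATOM      1  C   ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   ALA A   1       1.400   0.000   0.000  1.00  0.00           N
ATOM      3  O   ALA A   1       2.800   0.000   0.000  1.00  0.00           O
END
"""

MOL2_5ATOMS = """\
@<TRIPOS>MOLECULE
toy
5 4 0 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1    0.0000    0.0000    0.0000 C.3     1  LIG 0.0000
      2 C2    1.5000    0.0000    0.0000 C.3     1  LIG 0.0000
      3 N1    2.9000    0.5000    0.0000 N.3     1  LIG 0.0000
      4 O1    4.1000    0.0000    0.0000 O.3     1  LIG 0.0000
      5 C3   -1.5000    0.5000    0.0000 C.3     1  LIG 0.0000
@<TRIPOS>BOND
     1     1     2 1
     2     2     3 1
     3     3     4 1
     4     1     5 1
"""

PDBQT_POSE = """\
MODEL 1
REMARK VINA RESULT:      -7.5      0.000      0.000
ROOT
ATOM      1  C   LIG     1       1.000   2.000   3.000  0.00  0.00    +0.150 C
ATOM      2  O   LIG     1       2.200   2.000   3.000  0.00  0.00    -0.350 OA
ENDROOT
TORSDOF 0
ENDMDL
"""


class TestReadStructure:
    def test_pdb_atoms_in_file_order(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        p.write_text(PDB_3ATOMS)
        mol = read_structure(p)
        assert [a.element for a in mol.atoms] == ["C", "N", "O"]
        assert mol.atoms[1].coords == (1.4, 0.0, 0.0)
        assert mol.bonds == []

    def test_mol2_bonds_populated(self, tmp_path):
        p = tmp_path / "toy.mol2"
        p.write_text(MOL2_5ATOMS)
        mol = read_structure(p)
        assert len(mol.atoms) == 5
        assert len(mol.bonds) == 4
        assert mol.atoms[2].element == "N"

    def test_pdbqt_pose_atoms_parsed_remarks_ignored(self, tmp_path):
        p = tmp_path / "pose.pdbqt"
        p.write_text(PDBQT_POSE)
        mol = read_structure(p)
        assert len(mol.atoms) == 2
        # element from the AutoDock atom type column (OA -> O)
        assert [a.element for a in mol.atoms] == ["C", "O"]
        assert mol.atoms[0].coords == (1.0, 2.0, 3.0)

    def test_unknown_extension_raises(self, tmp_path):
        p = tmp_path / "x.xyz"
        p.write_text("3\n")
        with pytest.raises(FormatError):
            read_structure(p)

    def test_zero_atoms_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER only\nEND\n")
        with pytest.raises(StructureError):
            read_structure(p)

    def test_multi_model_yields_first_model(self, tmp_path):
        text = ("MODEL 1\n" + PDB_3ATOMS.replace("END\n", "") +
                "ENDMDL\nMODEL 2\n" +
                PDB_3ATOMS.replace("0.000   0.000   0.000",
                                   "9.000   9.000   9.000").replace("END\n", "") +
                "ENDMDL\n")
        p = tmp_path / "multi.pdb"
        p.write_text(text)
        mol = read_structure(p)
        assert len(mol.atoms) == 3
        assert mol.atoms[0].coords == (0.0, 0.0, 0.0)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["pdb", "mol2"])
    def test_write_read_preserves_atoms(self, tmp_path, fmt, asymmetric_chain):
        path = tmp_path / f"rt.{fmt}"
        write_structure(asymmetric_chain, path, fmt=fmt)
        back = read_structure(path)
        assert len(back.atoms) == len(asymmetric_chain.atoms)
        assert [a.element for a in back.atoms] == \
               [a.element for a in asymmetric_chain.atoms]
        assert [a.name for a in back.atoms] == \
               [a.name for a in asymmetric_chain.atoms]
        np.testing.assert_allclose(back.coords, asymmetric_chain.coords,
                                   atol=5e-4)


class TestStripWaters:
    def test_waters_removed_hetero_kept(self, tmp_path):
        lines = [f"ATOM  {i + 1:>5}  CA  ALA A{i + 1:>4}    "
                 f"{i * 2.0:>8.3f}{0.0:>8.3f}{0.0:>8.3f}  1.00  0.00           C"
                 for i in range(5)]
        lines.append("HETATM    6  PA  ADP A 200      10.000   0.000"
                     "   0.000  1.00  0.00           P")
        for w in range(3):
            lines.append(f"HETATM{7 + w:>5}  O   HOH A{300 + w:>4}    "
                         f"{20.0 + w:>8.3f}{0.0:>8.3f}{0.0:>8.3f}"
                         "  1.00  0.00           O")
        p = tmp_path / "rec.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        mol = read_structure(p)
        stripped = strip_waters(mol)
        assert len(stripped.atoms) == 6
        assert any(a.residue_name == "ADP" for a in stripped.atoms)
        assert not any(a.residue_name == "HOH" for a in stripped.atoms)

    def test_idempotent_and_identity_without_waters(self, asymmetric_chain):
        once = strip_waters(asymmetric_chain)
        assert once is asymmetric_chain  # no waters: identical object
        assert strip_waters(once) is once


class TestBuildLibrary:
    def _family(self, tmp_path, n):
        spec = FixtureSpec(n_pairs=n, ligand_size=4, seed=3)
        return generate_family(spec, tmp_path / "fam")

    @pytest.mark.parametrize("n", [1, 2, 5, 12])
    def test_recovers_generated_roots_sorted(self, tmp_path, n):
        fam = self._family(tmp_path, n)
        lib = fam.library()
        assert lib.roots == sorted(fam.roots)
        assert len(lib) == n

    def test_orphan_ligand_raises_naming_root(self, tmp_path):
        fam = self._family(tmp_path, 1)
        (fam.ligand_dir / "c-l.pdb").write_text(
            (fam.ligand_dir / "a-l.pdb").read_text())
        with pytest.raises(PairingError, match="c"):
            build_library(fam.receptor_dir, fam.ligand_dir)

    def test_mixed_formats_pair(self, tmp_path):
        fam = self._family(tmp_path, 1)
        lig = read_structure(fam.ligand_dir / "a-l.pdb")
        (fam.ligand_dir / "a-l.pdb").unlink()
        write_structure(lig, fam.ligand_dir / "a-l.mol2", fmt="mol2")
        lib = build_library(fam.receptor_dir, fam.ligand_dir)
        assert lib.roots == ["a"]
        assert lib.pair("a").ligand.source_format == "mol2"

    def test_duplicate_roots_ambiguous(self, tmp_path):
        fam = self._family(tmp_path, 1)
        lig = read_structure(fam.ligand_dir / "a-l.pdb")
        write_structure(lig, fam.ligand_dir / "a-l.mol2", fmt="mol2")
        with pytest.raises(PairingError, match="duplicate"):
            build_library(fam.receptor_dir, fam.ligand_dir)

    def test_receptors_come_out_water_free(self, tmp_path):
        fam = self._family(tmp_path, 2)
        lib = fam.library()
        for pair in lib:
            assert not any(a.residue_name == "HOH" for a in pair.receptor.atoms)


class TestPerceiveBonds:
    def test_two_carbons_within_cutoff_bond(self):
        from tests_helpers import two_atoms
        mol = two_atoms("C", "C", 1.5)
        assert perceive_bonds(mol).bonds == [(0, 1)]

    def test_two_carbons_beyond_cutoff_no_bond(self):
        from tests_helpers import two_atoms
        mol = two_atoms("C", "C", 3.0)
        assert perceive_bonds(mol).bonds == []

    def test_existing_bonds_untouched(self, o_c_o):
        assert perceive_bonds(o_c_o).bonds == o_c_o.bonds

    def test_unknown_element_raises(self):
        from tests_helpers import two_atoms
        mol = two_atoms("Xx", "C", 1.5)
        with pytest.raises(StructureError):
            perceive_bonds(mol)
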