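"""Engine contract: box placement, mock determinism, Vina output parsing."""

import shutil

import numpy as np
import pytest

from crossdock.engine import (DockingParams, DockingResult, EngineError,
                              GridBox, MockEngine, Pose, VinaEngine,
                              compute_box_center, parse_vina_poses)
from crossdock.fixtures import FixtureSpec, generate_family
from crossdock.rmsd import symmetry_min_rmsd
from crossdock.structures import StructureError
from conftest import make_molecule
from tests_helpers import two_atoms


class TestComputeBoxCenter:
    def test_midpoint_of_two_atoms(self):
        assert compute_box_center(two_atoms("C", "C", 2.0)) == (1.0, 0.0, 0.0)

    def test_single_atom_is_its_own_center(self):
        mol = make_molecule(["C"], [(5.0, -1.0, 3.0)], [])
        assert compute_box_center(mol) == (5.0, -1.0, 3.0)

    def test_unit_cube_corner_mean(self):
        mol = make_molecule(["C"] * 4,
                            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)], [])
        assert compute_box_center(mol) == (0.25, 0.25, 0.25)

    def test_hydrogens_excluded(self):
        mol = make_molecule(["C", "H"], [(0, 0, 0), (100, 0, 0)], [(0, 1)])
        assert compute_box_center(mol) == (0.0, 0.0, 0.0)

    def test_hydrogen_only_ligand_rejected(self):
        mol = make_molecule(["H"], [(0, 0, 0)], [])
        with pytest.raises(StructureError):
            compute_box_center(mol)


class TestGridBoxAndParams:
    def test_nonpositive_box_size_rejected(self):
        with pytest.raises(ValueError):
            GridBox((0, 0, 0), (10.0, -1.0, 10.0))

    def test_defaults_reproduce_standard_run(self):
        params = DockingParams()
        assert params.exhaustiveness == 8
        assert params.randomize_first

    def test_unsorted_energies_rejected(self):
        with pytest.raises(EngineError):
            DockingResult([Pose(1, ((0, 0, 0),), -5.0),
                           Pose(2, ((0, 0, 0),), -9.0)], "mock")


@pytest.fixture
def family(tmp_path):
    return generate_family(FixtureSpec(n_pairs=2, ligand_size=5, seed=4),
                           tmp_path / "fam")


class TestMockEngine:
    def _cell(self, family, lig="a", rec="b"):
        lib = family.library()
        return (lib.pair(lig).ligand, lib.pair(rec).receptor,
                GridBox(compute_box_center(lib.pair(rec).ligand),
                        (20.0, 20.0, 20.0)))

    def test_dock_is_deterministic(self, family):
        ligand, receptor, box = self._cell(family)
        eng = family.engine()
        r1 = eng.dock(receptor, ligand, box, DockingParams(num_modes=5))
        r2 = eng.dock(receptor, ligand, box, DockingParams(num_modes=5))
        assert [(p.energy, p.coords) for p in r1.poses] == \
               [(p.energy, p.coords) for p in r2.poses]

    def test_randomize_deterministic_per_seed_and_differs_across_seeds(
            self, family):
        ligand, receptor, box = self._cell(family)
        eng = family.engine()
        a1 = eng.randomize_ligand(ligand, receptor, box, seed=1)
        a2 = eng.randomize_ligand(ligand, receptor, box, seed=1)
        b = eng.randomize_ligand(ligand, receptor, box, seed=2)
        np.testing.assert_array_equal(a1.coords, a2.coords)
        assert np.abs(a1.coords.mean(0) - b.coords.mean(0)).max() > 1e-6

    def test_randomize_conserves_heavy_atoms(self, family):
        ligand, receptor, box = self._cell(family)
        out = family.engine().randomize_ligand(ligand, receptor, box, seed=0)
        assert len(out) == len(ligand.heavy_atoms())
        assert [a.name for a in out.atoms] == \
               [a.name for a in ligand.heavy_atoms()]

    def test_planted_poses_sorted_by_energy(self, tmp_path):
        spec = FixtureSpec(
            n_pairs=1, ligand_size=4, seed=2,
            planted_pose_offsets={("a", "a"): [0.0, 1.5, 4.0]},
            planted_energies={("a", "a"): [-9.1, -8.0, -6.2]})
        fam = generate_family(spec, tmp_path / "p")
        lib = fam.library()
        box = GridBox(compute_box_center(lib.pair("a").ligand), (20,) * 3)
        result = fam.engine().dock(lib.pair("a").receptor,
                                   lib.pair("a").ligand, box,
                                   DockingParams(num_modes=9))
        assert [p.energy for p in result.poses] == [-9.1, -8.0, -6.2]
        assert [p.mode_index for p in result.poses] == [1, 2, 3]

    def test_num_modes_truncates(self, tmp_path):
        spec = FixtureSpec(
            n_pairs=1, ligand_size=4, seed=2,
            planted_pose_offsets={("a", "a"): [0.0, 1.5, 4.0]},
            planted_energies={("a", "a"): [-9.1, -8.0, -6.2]})
        fam = generate_family(spec, tmp_path / "p")
        lib = fam.library()
        box = GridBox(compute_box_center(lib.pair("a").ligand), (20,) * 3)
        result = fam.engine().dock(lib.pair("a").receptor,
                                   lib.pair("a").ligand, box,
                                   DockingParams(num_modes=2))
        assert len(result.poses) == 2

    def test_planted_offset_equals_computed_rmsd(self, tmp_path):
        """Central self-consistency: the mock's planted displacement is the
        RMSD the scoring module reports, to 1e-6 angstrom."""
        offsets = [0.0, 1.5, 4.0]
        spec = FixtureSpec(
            n_pairs=1, ligand_size=6, symmetry="swap-pair", seed=8,
            planted_pose_offsets={("a", "a"): offsets},
            planted_energies={("a", "a"): [-9.0, -8.0, -7.0]})
        fam = generate_family(spec, tmp_path / "p")
        lib = fam.library()
        crystal = lib.pair("a").ligand
        box = GridBox(compute_box_center(crystal), (20,) * 3)
        result = fam.engine().dock(lib.pair("a").receptor, crystal, box,
                                   DockingParams(num_modes=9))
        for pose, offset in zip(result.poses, offsets):
            rv = symmetry_min_rmsd(crystal, pose.coord_array)
            assert rv.value == pytest.approx(offset, abs=1e-6)


VINA_OUT = """\
MODEL 1
REMARK VINA RESULT:      -7.5      0.000      0.000
REMARK  9 active torsions
ROOT
ATOM      1  C   LIG     1       1.000   2.000   3.000  0.00  0.00    +0.100 C
ATOM      2  O   LIG     1       2.200   2.000   3.000  0.00  0.00    -0.300 OA
ENDROOT
TORSDOF 0
ENDMDL
MODEL 2
REMARK VINA RESULT:      -6.1      1.800      2.500
ROOT
ATOM      1  C   LIG     1       1.500   2.500   3.000  0.00  0.00    +0.100 C
ATOM      2  O   LIG     1       2.700   2.500   3.000  0.00  0.00    -0.300 OA
ENDROOT
TORSDOF 0
ENDMDL
"""


class TestVinaAdapter:
    def test_pose_parser_recovers_energy_and_coords(self):
        poses = parse_vina_poses(VINA_OUT)
        assert len(poses) == 2
        assert poses[0].energy == -7.5
        assert poses[1].energy == -6.1
        assert poses[0].coords[1] == (2.2, 2.0, 3.0)
        assert [p.mode_index for p in poses] == [1, 2]

    def test_parser_rejects_block_without_result_line(self):
        bad = "MODEL 1\nATOM      1  C   LIG     1       1.000   2.000" \
              "   3.000  0.00  0.00    +0.100 C\nENDMDL\n"
        with pytest.raises(EngineError):
            parse_vina_poses(bad)

    def test_missing_executable_is_configuration_error(self, family):
        from crossdock.engine import EngineConfigurationError
        lib = family.library()
        eng = VinaEngine(executable="definitely-not-a-docking-binary")
        box = GridBox((0, 0, 0), (20, 20, 20))
        with pytest.raises(EngineConfigurationError):
            eng.dock(lib.pair("a").receptor, lib.pair("a").ligand, box,
                     DockingParams())

    @pytest.mark.skipif(shutil.which("vina") is None,
                        reason="AutoDock Vina executable not on PATH")
    def test_smoke_dock_with_real_binary(self, family):
        lib = family.library()
        pair = lib.pair("a")
        box = GridBox(compute_box_center(pair.ligand), (20.0, 20.0, 20.0))
        result = VinaEngine().dock(pair.receptor, pair.ligand, box,
                                   DockingParams(num_modes=3, seed=1))
        assert len(result.poses) >= 1
        energies = [p.energy for p in result.poses]
        assert energies == sorted(energies)
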