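"""Run the full cross-docking grid and assemble the scored result.

For every ordered (ligand, receptor) pair of the family the ligand is
randomized, docked into a box centered on the receptor's own co-crystallized
ligand, and every returned pose is scored by symmetry-aware in-place RMSD
against the ligand's crystal conformation.  Engine failures on single cells
are recorded explicitly and never abort the grid.

The grid is reproducible: each cell's seed is derived deterministically from
the global seed and the two root names, so cells are independent of
execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .engine import (DockingEngine, DockingParams, EngineError, GridBox, Pose,
                     compute_box_center, _cell_seed)
from .rmsd import RmsdValue, symmetry_min_rmsd
from .structures import StructureLibrary

__all__ = [
    "DockRecord",
    "CrossDockResult",
    "EmptyRecordError",
    "run_crossdock",
    "select_best_rmsd",
    "select_best_energy",
    "save_result",
    "load_result",
]


class EmptyRecordError(ValueError):
    """A selection rule was applied to a record with no scored poses."""


@dataclass
class DockRecord:
    """One grid cell: every scored pose plus the two selections.

    ``best_rmsd`` is (rmsd, energy, mode_index) of the pose minimizing RMSD;
    ``best_energy`` is (energy, rmsd, mode_index) of the pose minimizing
    energy — the pose a virtual screen would actually keep.  The two need
    not coincide, which is precisely what the paired matrix reports expose.
    """

    ligand_root: str
    receptor_root: str
    poses: list[tuple[Pose, RmsdValue]] = field(default_factory=list)
    failed: bool = False
    failure_reason: str = ""

    @property
    def is_self_dock(self) -> bool:
        return self.ligand_root == self.receptor_root

    @property
    def best_rmsd(self) -> tuple[float, float, int]:
        return select_best_rmsd(self)

    @property
    def best_energy(self) -> tuple[float, float, int]:
        return select_best_energy(self)


def select_best_rmsd(record: DockRecord) -> tuple[float, float, int]:
    """(rmsd, energy, mode) of the lowest-RMSD pose; ties -> lower mode."""
    if not record.poses:
        raise EmptyRecordError(
            f"no scored poses in cell ({record.ligand_root}, {record.receptor_root})")
    pose, rv = min(record.poses, key=lambda pr: (pr[1].value, pr[0].mode_index))
    return (rv.value, pose.energy, pose.mode_index)


def select_best_energy(record: DockRecord) -> tuple[float, float, int]:
    """(energy, rmsd, mode) of the lowest-energy pose; ties -> lower mode."""
    if not record.poses:
        raise EmptyRecordError(
            f"no scored poses in cell ({record.ligand_root}, {record.receptor_root})")
    pose, rv = min(record.poses, key=lambda pr: (pr[0].energy, pr[0].mode_index))
    return (pose.energy, rv.value, pose.mode_index)


@dataclass
class CrossDockResult:
    """The complete ligand x receptor grid plus the parameters that made it."""

    records: dict[tuple[str, str], DockRecord]
    params_used: DockingParams
    library_roots: list[str]
    box_size: tuple[float, float, float]
    seed: int | None = None
    engine_name: str = ""

    def __post_init__(self) -> None:
        n = len(self.library_roots)
        if len(self.records) != n * n:
            raise ValueError(
                f"incomplete grid: {len(self.records)} records for {n} roots")

    def record(self, ligand_root: str, receptor_root: str) -> DockRecord:
        return self.records[(ligand_root, receptor_root)]

    def column(self, receptor_root: str) -> list[DockRecord]:
        """All cells for one receptor, in ligand (row) order."""
        return [self.records[(lig, receptor_root)] for lig in self.library_roots]

    @property
    def n_failed(self) -> int:
        return sum(r.failed for r in self.records.values())


def run_crossdock(library: StructureLibrary, engine: DockingEngine,
                  params: DockingParams,
                  box_size: tuple[float, float, float] = (22.0, 22.0, 22.0),
                  seed: int | None = None) -> CrossDockResult:
    """Dock every ligand into every receptor and score all poses.

    Row-major over the sorted roots; each cell gets a deterministic seed
    derived from ``seed`` and the cell's (ligand, receptor) roots.  A cell
    whose engine call fails is marked failed with the diagnostic and the run
    continues; if every cell fails the run itself is an error.
    """
    if len(library) == 0:
        raise ValueError("empty structure library")
    base_seed = 0 if seed is None else seed
    records: dict[tuple[str, str], DockRecord] = {}
    for lig_pair in library:
        crystal = lig_pair.ligand
        for rec_pair in library:
            key = (lig_pair.root, rec_pair.root)
            cell_seed = _cell_seed(base_seed, lig_pair.root, rec_pair.root)
            try:
                box = GridBox(compute_box_center(rec_pair.ligand), box_size)
                ligand = crystal
                if params.randomize_first:
                    ligand = engine.randomize_ligand(
                        crystal, rec_pair.receptor, box, seed=cell_seed)
                cell_params = DockingParams(
                    exhaustiveness=params.exhaustiveness,
                    num_modes=params.num_modes,
                    energy_range=params.energy_range,
                    seed=cell_seed if params.seed is None else params.seed,
                    randomize_first=params.randomize_first)
                result = engine.dock(rec_pair.receptor, ligand, box, cell_params)
                scored = [(pose, symmetry_min_rmsd(crystal, pose.coord_array))
                          for pose in result.poses]
                records[key] = DockRecord(lig_pair.root, rec_pair.root, scored)
            except EngineError as exc:
                records[key] = DockRecord(lig_pair.root, rec_pair.root,
                                          failed=True, failure_reason=str(exc))
    if all(r.failed for r in records.values()):
        reasons = {r.failure_reason for r in records.values()}
        raise EngineError(f"every grid cell failed: {sorted(reasons)}")
    return CrossDockResult(records, params, library.roots, tuple(box_size),
                           seed, getattr(engine, "name", ""))


# ---------------------------------------------------------------------------
# persistence — docking is the expensive step, so the scored grid is saved
# as JSON and reports can be rebuilt without re-docking.


def save_result(result: CrossDockResult, path: str | Path) -> None:
    """Serialize a scored grid (poses, RMSDs, parameters) to JSON."""
    payload = {
        "library_roots": result.library_roots,
        "box_size": list(result.box_size),
        "seed": result.seed,
        "engine_name": result.engine_name,
        "params": {
            "exhaustiveness": result.params_used.exhaustiveness,
            "num_modes": result.params_used.num_modes,
            "energy_range": result.params_used.energy_range,
            "seed": result.params_used.seed,
            "randomize_first": result.params_used.randomize_first,
        },
        "records": [
            {
                "ligand_root": r.ligand_root,
                "receptor_root": r.receptor_root,
                "failed": r.failed,
                "failure_reason": r.failure_reason,
                "poses": [
                    {
                        "mode_index": p.mode_index,
                        "energy": p.energy,
                        "rmsd": rv.value,
                        "symmetry_corrected": rv.symmetry_corrected,
                        "mapping": list(rv.mapping_used.pairs),
                        "coords": [list(c) for c in p.coords],
                    }
                    for p, rv in r.poses
                ],
            }
            for r in result.records.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_result(path: str | Path) -> CrossDockResult:
    from .rmsd import AtomMapping

    payload = json.loads(Path(path).read_text())
    records: dict[tuple[str, str], DockRecord] = {}
    for rec in payload["records"]:
        poses = [
            (Pose(p["mode_index"], tuple(map(tuple, p["coords"])), p["energy"]),
             RmsdValue(p["rmsd"], AtomMapping(tuple(p["mapping"])),
                       p["symmetry_corrected"]))
            for p in rec["poses"]
        ]
        records[(rec["ligand_root"], rec["receptor_root"])] = DockRecord(
            rec["ligand_root"], rec["receptor_root"], poses,
            failed=rec["failed"], failure_reason=rec["failure_reason"])
    pp = payload["params"]
    params = DockingParams(pp["exhaustiveness"], pp["num_modes"],
                           pp["energy_range"], pp["seed"], pp["randomize_first"])
    return CrossDockResult(records, params, payload["library_roots"],
                           tuple(payload["box_size"]), payload["seed"],
                           payload["engine_name"])
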