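"""Matrix and long-form reports: spreadsheets with traffic-light bands.

Six files describe one cross-docking run:

1. ``Output`` — every pose of every cell (RMSD and energy, long form).
2. ``Output_the_best_RMSD`` — per cell, the best RMSD and its energy.
3. ``Table_the_best_RMSD`` — matrix of best RMSDs.
4. ``Table_the_best_energy`` — matrix of best energies.
5. ``Table_RMSD_for_the_best_energy`` — matrix of the RMSD carried by each
   cell's lowest-energy pose (the pose a virtual screen would keep).
6. ``Table_energy_for_the_best_RMSD`` — matrix of the energy carried by
   each cell's best-RMSD pose.

Matrices put receptors in columns and co-crystallized ligands in rows;
self-docking cells (row label == column label) are bold.  Cells are colored
by nearest-rank percentiles of the pooled matrix values — green at or below
the 10th, yellow at or below the 50th, red at or above the 90th — so the
promising receptors stand out at a glance.  CSV mirrors carry full-precision
values and a sidecar of band assignments; the spreadsheets round to two
decimals.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .aggregate import SUCCESS_THRESHOLD, summarize_receptor
from .orchestrate import CrossDockResult

__all__ = [
    "MatrixTable",
    "ReportSet",
    "MATRIX_FILE_STEMS",
    "build_tables",
    "assign_bands",
    "nearest_rank",
    "write_reports",
]

Band = Literal["green", "yellow", "red", "none"]
BandScope = Literal["matrix", "column"]

#: Output file stems, exactly as users of the original workflow expect them.
MATRIX_FILE_STEMS = (
    "Table_the_best_RMSD",
    "Table_the_best_energy",
    "Table_RMSD_for_the_best_energy",
    "Table_energy_for_the_best_RMSD",
)
LONG_FILE_STEMS = ("Output", "Output_the_best_RMSD")

_FILLS = {"green": "FF92D050", "yellow": "FFFFFF00", "red": "FFFF0000"}


@dataclass
class MatrixTable:
    """One ligand x receptor matrix with footer statistics and cell bands."""

    name: str
    row_labels: list[str]          # ligand roots
    column_labels: list[str]       # receptor roots
    cells: list[list[float | None]]  # None marks a failed cell
    footer_rows: list[tuple[str, list[float | int]]] = field(default_factory=list)
    band_of_cell: dict[tuple[int, int], Band] = field(default_factory=dict)

    def bold_mask(self, i: int, j: int) -> bool:
        return self.row_labels[i] == self.column_labels[j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, index=self.row_labels,
                          columns=self.column_labels, dtype=float)
        for label, values in self.footer_rows:
            df.loc[label] = values
        df.index.name = "ligand"
        return df


@dataclass
class ReportSet:
    """All six tables for one run, keyed by file stem."""

    long_tables: dict[str, pd.DataFrame]
    matrices: dict[str, MatrixTable]


def nearest_rank(sorted_values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("no values")
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return sorted_values[min(rank, n) - 1]


def assign_bands(cells: list[list[float | None]],
                 scope: BandScope = "matrix") -> dict[tuple[int, int], Band]:
    """Traffic-light band per finite cell from 10th/50th/90th percentiles.

    Precedence green > yellow > red: a cell at or below the 10th-percentile
    threshold is green even when degenerate thresholds collapse; at or below
    the 50th, yellow; at or above the 90th, red; otherwise no band.
    With ``scope="column"`` thresholds come from each column separately.
    """
    bands: dict[tuple[int, int], Band] = {}
    n_rows = len(cells)
    n_cols = len(cells[0]) if n_rows else 0

    def classify(value: float, pool: list[float]) -> Band:
        t10 = nearest_rank(pool, 10)
        t50 = nearest_rank(pool, 50)
        t90 = nearest_rank(pool, 90)
        if value <= t10:
            return "green"
        if value <= t50:
            return "yellow"
        if value >= t90:
            return "red"
        return "none"

    if scope == "matrix":
        pool = sorted(v for row in cells for v in row if v is not None)
        for i in range(n_rows):
            for j in range(n_cols):
                if cells[i][j] is not None and pool:
                    bands[(i, j)] = classify(cells[i][j], pool)
    else:
        for j in range(n_cols):
            pool = sorted(cells[i][j] for i in range(n_rows)
                          if cells[i][j] is not None)
            for i in range(n_rows):
                if cells[i][j] is not None and pool:
                    bands[(i, j)] = classify(cells[i][j], pool)
    return bands


def _matrix(result: CrossDockResult, extract) -> list[list[float | None]]:
    return [[None if result.record(lig, rec).failed
             else extract(result.record(lig, rec))
             for rec in result.library_roots]
            for lig in result.library_roots]


def build_tables(result: CrossDockResult,
                 threshold: float = SUCCESS_THRESHOLD,
                 include_self: bool = True,
                 band_scope: BandScope = "matrix") -> ReportSet:
    """Assemble the two long-form tables and the four matrices."""
    if not result.records:
        raise ValueError("empty cross-docking result")
    roots = result.library_roots

    pose_rows = []
    best_rows = []
    for lig in roots:
        for rec in roots:
            record = result.record(lig, rec)
            if record.failed:
                continue
            for pose, rv in record.poses:
                pose_rows.append({"ligand": lig, "receptor": rec,
                                  "mode": pose.mode_index, "rmsd": rv.value,
                                  "energy": pose.energy,
                                  "symmetry_corrected": rv.symmetry_corrected})
            rmsd, energy, mode = record.best_rmsd
            best_rows.append({"ligand": lig, "receptor": rec,
                              "best_rmsd": rmsd, "energy": energy,
                              "mode": mode,
                              "self_dock": record.is_self_dock})
    long_tables = {
        "Output": pd.DataFrame(pose_rows),
        "Output_the_best_RMSD": pd.DataFrame(best_rows),
    }

    summaries = {root: summarize_receptor(result, root, threshold, include_self)
                 for root in roots}

    def make(name: str, extract, avg_key: str | None, n_key: str | None
             ) -> MatrixTable:
        cells = _matrix(result, extract)
        footer: list[tuple[str, list]] = []
        if avg_key:
            footer.append(("average",
                           [getattr(summaries[r], avg_key) for r in roots]))
        if n_key:
            footer.append((f"n(RMSD<{threshold:g})",
                           [getattr(summaries[r], n_key) for r in roots]))
        return MatrixTable(name, list(roots), list(roots), cells, footer,
                           assign_bands(cells, band_scope))

    matrices = {
        "Table_the_best_RMSD": make(
            "Table_the_best_RMSD", lambda r: r.best_rmsd[0],
            "mean_best_rmsd", "n_success"),
        "Table_the_best_energy": make(
            "Table_the_best_energy", lambda r: r.best_energy[0], None, None),
        "Table_RMSD_for_the_best_energy": make(
            "Table_RMSD_for_the_best_energy", lambda r: r.best_energy[1],
            "mean_bestenergy_rmsd", "n_success_bestenergy"),
        "Table_energy_for_the_best_RMSD": make(
            "Table_energy_for_the_best_RMSD", lambda r: r.best_rmsd[1],
            None, None),
    }
    return ReportSet(long_tables, matrices)


# ---------------------------------------------------------------------------
# writing


def _atomic_write(path: Path, writer) -> None:
    """Write to a temp file in the same directory, then rename over target."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _write_matrix_xlsx(table: MatrixTable, path: Path) -> None:
    from openpyxl import Workbook
    from openpyxl.styles import Font, PatternFill

    wb = Workbook()
    ws = wb.active
    ws.title = table.name[:31]
    ws.append([""] + table.column_labels)
    for c in ws[1]:
        c.font = Font(bold=True)
    for i, row_label in enumerate(table.row_labels):
        values = [None if v is None else round(v, 2) for v in table.cells[i]]
        ws.append([row_label] + values)
        ws.cell(row=i + 2, column=1).font = Font(bold=True)
        for j in range(len(table.column_labels)):
            cell = ws.cell(row=i + 2, column=j + 2)
            if table.cells[i][j] is None:
                cell.value = "FAILED"
            if table.bold_mask(i, j):
                cell.font = Font(bold=True)
            band = table.band_of_cell.get((i, j), "none")
            if band in _FILLS:
                cell.fill = PatternFill("solid", fgColor=_FILLS[band])
    for label, values in table.footer_rows:
        ws.append([label] + [round(v, 2) if isinstance(v, float) else v
                             for v in values])
        ws.cell(row=ws.max_row, column=1).font = Font(bold=True)
    _atomic_write(path, wb.save)


def _write_long_xlsx(df: pd.DataFrame, name: str, path: Path) -> None:
    from openpyxl import Workbook
    from openpyxl.styles import Font

    wb = Workbook()
    ws = wb.active
    ws.title = name[:31]
    ws.append(list(df.columns))
    for c in ws[1]:
        c.font = Font(bold=True)
    for row in df.itertuples(index=False):
        ws.append([round(v, 2) if isinstance(v, float) else v for v in row])
    _atomic_write(path, wb.save)


def write_reports(reports: ReportSet, output_dir: str | Path,
                  formats: Sequence[str] = ("spreadsheet", "csv")) -> list[Path]:
    """Write the six report files (and CSV mirrors + band sidecar).

    Existing files are replaced atomically.  Returns the written paths.
    CSVs carry full precision and are the machine-readable source of truth;
    the band sidecar (``band_assignments.csv``) lists table, ligand,
    receptor, and band for every colored cell.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - {"spreadsheet", "csv"}
    if unknown:
        raise ValueError(f"unknown report formats: {sorted(unknown)}")
    written: list[Path] = []

    for stem, df in reports.long_tables.items():
        if "spreadsheet" in formats:
            p = output_dir / f"{stem}.xlsx"
            _write_long_xlsx(df, stem, p)
            written.append(p)
        if "csv" in formats:
            p = output_dir / f"{stem}.csv"
            _atomic_write(p, lambda tmp, df=df: df.to_csv(tmp, index=False))
            written.append(p)

    band_rows = []
    for stem, table in reports.matrices.items():
        if "spreadsheet" in formats:
            p = output_dir / f"{stem}.xlsx"
            _write_matrix_xlsx(table, p)
            written.append(p)
        if "csv" in formats:
            p = output_dir / f"{stem}.csv"
            frame = table.to_frame()
            _atomic_write(p, lambda tmp, frame=frame: frame.to_csv(tmp))
            written.append(p)
        for (i, j), band in sorted(table.band_of_cell.items()):
            if band != "none":
                band_rows.append({"table": stem,
                                  "ligand": table.row_labels[i],
                                  "receptor": table.column_labels[j],
                                  "band": band})
    if "csv" in formats:
        p = output_dir / "band_assignments.csv"
        sidecar = pd.DataFrame(band_rows,
                               columns=["table", "ligand", "receptor", "band"])
        _atomic_write(p, lambda tmp: sidecar.to_csv(tmp, index=False))
        written.append(p)
    return written
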