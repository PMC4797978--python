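"""Per-receptor summary statistics and receptor ranking.

A receptor's fitness for pose prediction and virtual screening is judged by
how well it accommodates the *other* ligands of the family: the average
best RMSD over its column of the grid, and the number of docks below the
conventional 2.0-angstrom success cutoff.  The cutoff is strict — a dock at
exactly 2.0 angstrom counts as a failure.

Self-docking cells sit on the matrix diagonal and are included in the
averages and counts by default (they appear inside the same matrix, only
typographically distinguished); a switch excludes them for users who want
cross-docks only.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Literal

from .orchestrate import CrossDockResult

__all__ = [
    "ReceptorSummary",
    "Ranking",
    "UndefinedSummaryError",
    "SUCCESS_THRESHOLD",
    "summarize_receptor",
    "rank_receptors",
]

#: Conventional success cutoff (angstrom); strictly below counts as success.
SUCCESS_THRESHOLD = 2.0

Criterion = Literal["mean_best_rmsd", "n_success", "mean_bestenergy_rmsd"]


class UndefinedSummaryError(ValueError):
    """Every cell in the receptor's column failed; no statistics exist."""


@dataclass(frozen=True)
class ReceptorSummary:
    receptor_root: str
    mean_best_rmsd: float
    n_success: int
    mean_bestenergy_rmsd: float
    n_success_bestenergy: int
    n_failed_cells: int


def summarize_receptor(result: CrossDockResult, receptor_root: str,
                       threshold: float = SUCCESS_THRESHOLD,
                       include_self: bool = True) -> ReceptorSummary:
    """Column statistics for one receptor over the non-failed cells."""
    if receptor_root not in result.library_roots:
        raise KeyError(receptor_root)
    column = result.column(receptor_root)
    if not include_self:
        column = [r for r in column if not r.is_self_dock]
    ok = [r for r in column if not r.failed]
    if not ok:
        raise UndefinedSummaryError(
            f"all cells failed for receptor {receptor_root!r}")
    best_rmsds = [r.best_rmsd[0] for r in ok]
    be_rmsds = [r.best_energy[1] for r in ok]
    return ReceptorSummary(
        receptor_root=receptor_root,
        mean_best_rmsd=fmean(best_rmsds),
        n_success=sum(v < threshold for v in best_rmsds),
        mean_bestenergy_rmsd=fmean(be_rmsds),
        n_success_bestenergy=sum(v < threshold for v in be_rmsds),
        n_failed_cells=len(column) - len(ok),
    )


@dataclass(frozen=True)
class Ranking:
    receptor_roots: tuple[str, ...]
    criterion: Criterion


def rank_receptors(result: CrossDockResult,
                   criterion: Criterion = "mean_best_rmsd",
                   threshold: float = SUCCESS_THRESHOLD,
                   include_self: bool = True) -> Ranking:
    """Order receptors best-first by the chosen criterion.

    Means rank ascending (lower RMSD is better), success counts descending.
    Ties break on the complementary criterion (count for mean-based
    rankings, mean for the count-based one), then lexicographic root.
    """
    if criterion not in ("mean_best_rmsd", "n_success", "mean_bestenergy_rmsd"):
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    summaries = [summarize_receptor(result, root, threshold, include_self)
                 for root in result.library_roots]
    if criterion == "mean_best_rmsd":
        key = lambda s: (s.mean_best_rmsd, -s.n_success, s.receptor_root)
    elif criterion == "mean_bestenergy_rmsd":
        key = lambda s: (s.mean_bestenergy_rmsd, -s.n_success_bestenergy,
                         s.receptor_root)
    else:  # n_success, higher is better
        key = lambda s: (-s.n_success, s.mean_best_rmsd, s.receptor_root)
    ordered = sorted(summaries, key=key)
    return Ranking(tuple(s.receptor_root for s in ordered), criterion)
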