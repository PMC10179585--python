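"""Delta-delta-G pose selection over an ensemble of docking runs.

Docking scoring functions rank poses imperfectly: the geometrically correct
pose is often present among the top few but not always rank 1.  The
selection rule therefore keeps, for every run, the top-ranked pose plus
every lower-ranked pose whose affinity lies within a small cutoff of the
top pose's affinity:

    ddG = |dG(top pose) - dG(lower-ranked pose)| <= cutoff   (inclusive)

The stored ``delta_delta_g`` is the magnitude of that difference (the raw
top-minus-lower expression is <= 0), so cutoffs are positive numbers.
Selected-set sizes are summarized per cutoff as ``set-n`` in cutoff order;
totals are non-decreasing in the cutoff by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .docking_interface import DockingRun

__all__ = [
    "SelectedComplex",
    "SelectionSummary",
    "select_poses",
    "select_ensemble",
    "summarize_selection",
    "selection_table",
    "summary_table",
]


@dataclass(frozen=True)
class SelectedComplex:
    """A (receptor conformer, pose) pair surviving the ddG rule."""

    receptor_label: str
    ligand_label: str
    pose_rank: int
    affinity: float        # kcal/mol
    delta_delta_g: float   # kcal/mol, >= 0; 0 for the top pose


@dataclass(frozen=True)
class SelectionSummary:
    """Selected-set accounting at one cutoff: n_total = n_top + n_lower."""

    cutoff: float
    n_top: int
    n_lower: int

    @property
    def n_total(self) -> int:
        return self.n_top + self.n_lower


def select_poses(run: DockingRun, cutoff: float) -> list[SelectedComplex]:
    """Apply the ddG rule to one run; output in rank order.

    The top (first-file) pose is always selected with ddG = 0; pose k > 1
    is selected iff |affinity_k - affinity_1| <= cutoff.  Duplicate best
    affinities count as lower-ranked poses with ddG = 0 (trivially kept).
    """
    if cutoff < 0:
        raise ValueError("ddG cutoff must be non-negative")
    top = run.poses[0].affinity
    selected = []
    for pose in run.poses:
        ddg = abs(pose.affinity - top)
        # small tolerance keeps the inclusive boundary inclusive under
        # binary floating point (e.g. a 0.05*6 gap against a 0.3 cutoff)
        if pose.pose_rank == 1 or ddg <= cutoff + 1e-9:
            selected.append(SelectedComplex(
                receptor_label=run.receptor_label, ligand_label=run.ligand_label,
                pose_rank=pose.pose_rank, affinity=pose.affinity, delta_delta_g=ddg))
    return selected


def select_ensemble(runs: Sequence[DockingRun], cutoff: float) -> list[SelectedComplex]:
    """ddG selection over all runs of one ligand."""
    out: list[SelectedComplex] = []
    for run in runs:
        out.extend(select_poses(run, cutoff))
    return out


def summarize_selection(runs: Sequence[DockingRun],
                        cutoffs: Sequence[float]) -> list[SelectionSummary]:
    """One :class:`SelectionSummary` per cutoff (cutoffs must be ascending).

    ``n_top`` always equals the number of runs; ``n_total`` is monotone
    non-decreasing across cutoffs.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no docking runs to summarize")
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be sorted ascending")
    summaries = []
    for cutoff in cutoffs:
        selected = select_ensemble(runs, cutoff)
        n_lower = sum(1 for s in selected if s.pose_rank > 1)
        summaries.append(SelectionSummary(cutoff=cutoff, n_top=len(runs), n_lower=n_lower))
    return summaries


def selection_table(selected: Sequence[SelectedComplex]) -> pd.DataFrame:
    """One row per selected complex."""
    return pd.DataFrame(
        [{"receptor": s.receptor_label, "ligand": s.ligand_label,
          "pose_rank": s.pose_rank, "affinity": s.affinity,
          "delta_delta_g": s.delta_delta_g} for s in selected])


def summary_table(summaries: Sequence[SelectionSummary]) -> pd.DataFrame:
    """Set accounting table: set-n label, cutoff, top/lower/total counts."""
    return pd.DataFrame(
        [{"set": f"set-{i + 1}", "cutoff": s.cutoff, "n_top": s.n_top,
          "n_lower": s.n_lower, "n_total": s.n_total}
         for i, s in enumerate(summaries)])
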