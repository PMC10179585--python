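"""Per-residue ensemble contact statistics and hot-spot ranking.

A receptor residue is a *binding residue* of a complex when at least one of
its heavy atoms lies within a distance cutoff (inclusive) of any ligand
heavy atom; hydrogens are ignored on both sides.  Counting how often each
residue is a binding residue across all selected complexes, at a ladder of
cutoffs (conventionally 3.0-5.0 A), yields a contact table whose top rows
are the binding hot spots.

Count semantics: the default mode counts each (complex, residue) pair at
most once ("binary" — a residue either is or is not a binding residue of a
complex).  An alternative "atom_pairs" mode counts every heavy-atom pair
within the cutoff, for analyses that weight by contact surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pose_selection import SelectedComplex
from .structure_io import PoseBlock, Structure

__all__ = [
    "binding_residues",
    "residue_min_distances",
    "build_contact_table",
    "HotspotReport",
    "rank_hotspots",
]

DISTANCE_TOL = 1e-9  # absorbs float noise at inclusive cutoff boundaries


def _residue_atom_groups(receptor: Structure) -> list[tuple[str, np.ndarray]]:
    groups = []
    coords = receptor.coords
    for key, indices in receptor.residues():
        heavy = [i for i in indices if receptor.atoms[i].is_heavy]
        label = f"{key[3]}{key[1]}{key[2]}"
        groups.append((label, coords[heavy] if heavy else np.empty((0, 3))))
    return groups


def _ligand_heavy_coords(pose: PoseBlock) -> np.ndarray:
    coords = np.array([a.coords for a in pose.atoms if a.is_heavy])
    if coords.size == 0:
        raise ValueError("pose has no heavy atoms")
    return coords


def residue_min_distances(receptor: Structure, pose: PoseBlock) -> dict[str, float]:
    """Minimum heavy-atom distance from each receptor residue to the ligand.

    Computed once, this answers binding-residue membership at every cutoff.
    Residues without heavy atoms map to +inf.
    """
    ligand = _ligand_heavy_coords(pose)
    tree = cKDTree(ligand)
    out: dict[str, float] = {}
    for label, coords in _residue_atom_groups(receptor):
        if coords.shape[0] == 0:
            out[label] = float("inf")
            continue
        d, _ = tree.query(coords, k=1)
        out[label] = float(d.min())
    if all(v == float("inf") for v in out.values()):
        raise ValueError("receptor has no heavy atoms")
    return out


def binding_residues(receptor: Structure, pose: PoseBlock, cutoff: float) -> set[str]:
    """Residue labels with at least one heavy atom within ``cutoff`` of any
    ligand heavy atom (boundary inclusive)."""
    if cutoff <= 0:
        raise ValueError("distance cutoff must be positive")
    dmin = residue_min_distances(receptor, pose)
    return {label for label, d in dmin.items() if d <= cutoff + DISTANCE_TOL}


def _atom_pair_counts(receptor: Structure, pose: PoseBlock,
                      cutoffs: Sequence[float]) -> dict[str, np.ndarray]:
    ligand = _ligand_heavy_coords(pose)
    tree = cKDTree(ligand)
    out: dict[str, np.ndarray] = {}
    for label, coords in _residue_atom_groups(receptor):
        counts = np.zeros(len(cutoffs), dtype=int)
        if coords.shape[0]:
            for k, cutoff in enumerate(cutoffs):
                hits = tree.query_ball_point(coords, cutoff + DISTANCE_TOL)
                counts[k] = sum(len(h) for h in hits)
        out[label] = counts
    return out


def build_contact_table(complexes: Sequence[SelectedComplex],
                        structure_lookup: Callable[[SelectedComplex], tuple[Structure, PoseBlock]],
                        cutoffs: Sequence[float],
                        mode: str = "binary") -> pd.DataFrame:
    """Contact table: rows = receptor residues (in sequence order, zero-filled),
    columns = distance cutoffs, cells = number of complexes in which the
    residue is a binding residue (``mode="binary"``) or the total number of
    in-cutoff heavy-atom pairs (``mode="atom_pairs"``).

    ``structure_lookup`` resolves each selected complex to its (receptor
    conformer, pose) pair; lookup failures are reported with the complex
    identity.
    """
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be sorted ascending")
    if not complexes:
        raise ValueError("no complexes to analyse")
    if mode not in ("binary", "atom_pairs"):
        raise ValueError(f"unknown contact counting mode {mode!r}")
    table: pd.DataFrame | None = None
    for cplx in complexes:
        try:
            receptor, pose = structure_lookup(cplx)
        except Exception as exc:
            raise LookupError(
                f"cannot resolve structures for complex "
                f"({cplx.receptor_label}, {cplx.ligand_label}, pose {cplx.pose_rank}): {exc}"
            ) from exc
        if table is None:
            labels = receptor.residue_labels()
            table = pd.DataFrame(0, index=labels, columns=cutoffs, dtype=int)
        if mode == "binary":
            dmin = residue_min_distances(receptor, pose)
            for label, d in dmin.items():
                for cutoff in cutoffs:
                    if d <= cutoff + DISTANCE_TOL:
                        table.loc[label, cutoff] += 1
        else:
            for label, counts in _atom_pair_counts(receptor, pose, cutoffs).items():
                table.loc[label] += counts
    table.index.name = "residue"
    return table


@dataclass
class HotspotReport:
    """Residues ranked by contact count at one cutoff, plus the share of
    all contacts falling in a residue-number window."""

    cutoff: float
    ranking: pd.Series          # counts, sorted desc (ties: residue number asc)
    top: list[str]              # top-k residue labels
    window: tuple[int, int]
    window_share: float         # in [0, 1]; 0/0 defined as 0


def _residue_number(label: str) -> int:
    digits = "".join(ch for ch in label if ch.isdigit())
    return int(digits) if digits else -1


def rank_hotspots(table: pd.DataFrame, cutoff: float,
                  window: tuple[int, int] = (10, 20), top_k: int = 10) -> HotspotReport:
    """Rank residues by contact count at one table cutoff.

    Sort is count descending with ties broken by residue number ascending;
    the window share is the fraction of all counts carried by residues whose
    number falls in ``window`` (inclusive).  Residues with zero counts are
    excluded from the top-k list.
    """
    if cutoff not in table.columns:
        raise KeyError(f"cutoff {cutoff} is not a column of the contact table "
                       f"(available: {list(table.columns)})")
    counts = table[cutoff]
    order = sorted(counts.index, key=lambda lbl: (-counts[lbl], _residue_number(lbl)))
    ranking = counts.loc[order]
    top = [lbl for lbl in order if counts[lbl] > 0][:top_k]
    total = int(counts.sum())
    lo, hi = window
    in_window = sum(int(counts[lbl]) for lbl in counts.index
                    if lo <= _residue_number(lbl) <= hi)
    share = in_window / total if total else 0.0
    return HotspotReport(cutoff=cutoff, ranking=ranking, top=top,
                         window=window, window_share=share)
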