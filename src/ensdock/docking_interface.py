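"""Docking search boxes, run assembly, and the external-engine hook.

The search box follows the ensemble-docking convention: an axis-aligned
rectangular box centred at the receptor's centre of mass, sized so that
every receptor atom keeps at least a fixed margin (default 12 A) from every
box face.  Because each conformer has its own shape, a box is built per
conformer.

Result files follow the ``<receptor_label>__<ligand_label>.pdbqt`` naming
pattern; :func:`assemble_runs` matches them against a library manifest and
flags (never reorders) runs whose affinities are out of rank order.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from string import Formatter

import numpy as np

from .structure_io import PoseBlock, Structure, read_vina_pdbqt
from .trajectory_metrics import ATOMIC_MASSES

__all__ = [
    "SearchBox",
    "DockingRun",
    "build_search_box",
    "assemble_runs",
    "result_filename",
    "external_dock_hook",
    "DockingConfigError",
]

RESULT_PATTERN = "{receptor}__{ligand}.pdbqt"


class DockingConfigError(ValueError):
    pass


@dataclass
class SearchBox:
    """Axis-aligned docking box: centre and full edge lengths, Angstrom."""

    center: np.ndarray
    size: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.size = np.asarray(self.size, float)
        if self.center.shape != (3,) or self.size.shape != (3,):
            raise ValueError("box center and size must be 3-vectors")
        if np.any(self.size <= 0):
            raise ValueError("box sizes must be positive")

    def contains(self, points: np.ndarray, clearance: float = 0.0) -> bool:
        """True if every point is inside with at least ``clearance`` from
        each face."""
        half = self.size / 2.0 - clearance
        return bool(np.all(np.abs(np.asarray(points) - self.center) <= half + 1e-9))


@dataclass
class DockingRun:
    """All ranked poses of one (receptor conformer, ligand) docking run."""

    receptor_label: str
    ligand_label: str
    poses: list[PoseBlock]
    box: SearchBox | None = None
    source_path: Path | None = None

    def __post_init__(self):
        if not self.poses:
            raise ValueError("DockingRun requires at least one pose")

    @property
    def affinities(self) -> np.ndarray:
        return np.array([p.affinity for p in self.poses])

    @property
    def rank_order_ok(self) -> bool:
        """Vina writes best (most negative) affinities first."""
        a = self.affinities
        return bool(np.all(np.diff(a) >= -1e-9))


def build_search_box(receptor: Structure, margin: float = 12.0,
                     heavy_only: bool = True, mass_weighted: bool = False) -> SearchBox:
    """Docking box around a receptor conformer.

    Centre is the atom centroid (optionally mass-weighted); the half-edge on
    each axis is the maximal atomic excursion from the centre plus the
    margin, so every considered atom is at least ``margin`` from every face.
    ``heavy_only`` restricts both centre and extents to heavy atoms.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if heavy_only:
        idx = receptor.heavy_indices
        if idx.size == 0:
            raise ValueError("receptor has no heavy atoms")
        atoms = [receptor.atoms[i] for i in idx]
    else:
        atoms = receptor.atoms
    coords = np.array([a.coords for a in atoms])
    if mass_weighted:
        w = np.array([ATOMIC_MASSES.get(a.element, 12.011) for a in atoms])
        center = np.average(coords, axis=0, weights=w)
    else:
        center = coords.mean(axis=0)
    half = np.abs(coords - center).max(axis=0) + margin
    return SearchBox(center=center, size=2.0 * half)


def result_filename(receptor_label: str, ligand_label: str) -> str:
    return RESULT_PATTERN.format(receptor=receptor_label, ligand=ligand_label)


def assemble_runs(result_dir, receptor_labels, ligand_label: str,
                  boxes: dict[str, SearchBox] | None = None) -> list[DockingRun]:
    """Collect one :class:`DockingRun` per receptor label from a results
    directory laid out as ``<receptor>__<ligand>.pdbqt``.

    Missing files raise an error listing every missing label; runs whose
    affinities are out of Vina rank order are kept but carry
    ``rank_order_ok == False`` for the validation report.
    """
    result_dir = Path(result_dir)
    receptor_labels = list(receptor_labels)
    if len(set(receptor_labels)) != len(receptor_labels):
        dupes = sorted({l for l in receptor_labels if receptor_labels.count(l) > 1})
        raise ValueError(f"duplicate receptor labels in manifest: {dupes}")
    missing = [l for l in receptor_labels
               if not (result_dir / result_filename(l, ligand_label)).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing docking results for {len(missing)} receptor(s): "
            + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""))
    runs = []
    for label in receptor_labels:
        path = result_dir / result_filename(label, ligand_label)
        poses = read_vina_pdbqt(path)
        runs.append(DockingRun(receptor_label=label, ligand_label=ligand_label,
                               poses=poses, box=(boxes or {}).get(label),
                               source_path=path))
    return runs


_HOOK_PLACEHOLDERS = {"receptor", "ligand", "cx", "cy", "cz", "sx", "sy", "sz", "out"}


def external_dock_hook(receptor_path, ligand_path, box: SearchBox,
                       command_template: str, out_path) -> Path:
    """Run an external docking engine through a shell command template.

    The template must reference at least the box centre (``{cx} {cy} {cz}``)
    and output (``{out}``) placeholders; unknown placeholders are a
    configuration error.  The command's output file is returned untouched —
    parsing is :func:`ensdock.structure_io.read_vina_pdbqt`'s job.
    """
    fields = {f for _, f, _, _ in Formatter().parse(command_template) if f}
    unknown = fields - _HOOK_PLACEHOLDERS
    if unknown:
        raise DockingConfigError(f"unknown placeholders in command template: {sorted(unknown)}")
    required = {"cx", "cy", "cz", "out"}
    if not required.issubset(fields):
        raise DockingConfigError(
            f"command template must use placeholders {sorted(required)}; got {sorted(fields)}")
    command = command_template.format(
        receptor=receptor_path, ligand=ligand_path, out=out_path,
        cx=box.center[0], cy=box.center[1], cz=box.center[2],
        sx=box.size[0], sy=box.size[1], sz=box.size[2],
    )
    proc = subprocess.run(command, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"docking command failed with exit status {proc.returncode}:\n{proc.stderr}")
    out_path = Path(out_path)
    if not out_path.exists():
        raise RuntimeError(f"docking command succeeded but produced no output at {out_path}")
    return out_path
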