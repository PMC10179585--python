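"""Validation metrics for conformer trajectories.

Implements the standard observables used to judge whether a peptide--ligand
complex stays bound and compact over a trajectory: minimal RMSD after
optimal (Kabsch) superposition, radius of gyration, Shrake--Rupley solvent
accessible surface area, minimum inter-group distances, hydrogen-bond time
series and end-to-end distance.

Units: coordinates are Angstrom internally; distance-like report values
(Rg, minimum distances, end-to-end) are nanometres, matching the
conventions of MD analysis tooling.  SASA is reported in Angstrom^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "Trajectory",
    "MetricSeries",
    "SasaResult",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "kabsch_rotation",
    "kabsch_superpose",
    "kabsch_rmsd",
    "rmsd_series",
    "radius_of_gyration",
    "rg_series",
    "sasa",
    "sasa_series",
    "min_distance_series",
    "hbond_series",
    "end_to_end_series",
]

# Bondi-style van der Waals radii, Angstrom ("bondi-1964" table).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
VDW_RADII_VERSION = "bondi-1964"

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971,
}

ANGSTROM_PER_NM = 10.0


@dataclass
class Trajectory:
    """A sequence of frames with a constant atom count."""

    frames: list[Structure]
    frame_interval: float = 1.0  # arbitrary time unit

    def __post_init__(self):
        if not self.frames:
            raise ValueError("Trajectory requires at least one frame")
        n = len(self.frames[0])
        for i, f in enumerate(self.frames):
            if len(f) != n:
                raise ValueError(f"frame {i} has {len(f)} atoms, expected {n}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) array."""
        return np.array([f.coords for f in self.frames])


@dataclass
class MetricSeries:
    """A named per-frame series with summary statistics."""

    name: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centred ``mobile`` onto centred
    ``reference`` (Kabsch, via SVD; proper rotation enforced)."""
    H = mobile.T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``reference``; returns moved coords."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    R = kabsch_rotation(mobile - mc, reference - rc)
    return (mobile - mc) @ R + rc


def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray,
                selection: np.ndarray | None = None) -> float:
    """Minimal mass-unweighted RMSD (Angstrom) over rigid motions.

    ``selection`` is an optional index or boolean mask applied to both sets;
    at least 3 selected atoms are required.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if selection is not None:
        selection = np.asarray(selection)
        mobile = mobile[selection]
        reference = reference[selection]
    if mobile.shape != reference.shape:
        raise ValueError(f"coordinate shapes differ: {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    aligned = kabsch_superpose(mobile, reference)
    return float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))


def rmsd_series(trajectory: Trajectory, reference: Structure | None = None,
                selection: np.ndarray | None = None) -> MetricSeries:
    """Per-frame Kabsch RMSD (Angstrom) to a reference (default: frame 1)."""
    ref = (reference or trajectory.frames[0]).coords
    vals = [kabsch_rmsd(f.coords, ref, selection) for f in trajectory.frames]
    return MetricSeries("rmsd", np.array(vals), unit="A")


# ---------------------------------------------------------------------------
# Radius of gyration / end-to-end
# ---------------------------------------------------------------------------

def radius_of_gyration(structure: Structure, mass_weighted: bool = False) -> float:
    """Radius of gyration in nm: sqrt(sum w_i |r_i - rbar|^2 / sum w_i)."""
    coords = structure.coords
    if mass_weighted:
        w = np.array([ATOMIC_MASSES.get(a.element, 12.011) for a in structure.atoms])
    else:
        w = np.ones(len(coords))
    centre = np.average(coords, axis=0, weights=w)
    rg2 = np.average(np.sum((coords - centre) ** 2, axis=1), weights=w)
    return float(np.sqrt(rg2)) / ANGSTROM_PER_NM


def rg_series(trajectory: Trajectory, mass_weighted: bool = False) -> MetricSeries:
    vals = [radius_of_gyration(f, mass_weighted) for f in trajectory.frames]
    return MetricSeries("rg", np.array(vals), unit="nm")


def end_to_end_series(trajectory: Trajectory, anchor_name: str = "CA") -> MetricSeries:
    """Per-frame distance (nm) between the anchor atoms of the first and
    last residue (default anchor: backbone alpha-carbon)."""
    frame0 = trajectory.frames[0]
    residues = frame0.residues()
    first_key, first_idx = residues[0]
    last_key, last_idx = residues[-1]

    def _anchor(indices, key):
        for i in indices:
            if frame0.atoms[i].name == anchor_name:
                return i
        raise ValueError(f"residue {key[3]}{key[1]} has no anchor atom {anchor_name!r}")

    ia, ib = _anchor(first_idx, first_key), _anchor(last_idx, last_key)
    coords = trajectory.coords()
    d = np.linalg.norm(coords[:, ia] - coords[:, ib], axis=1)
    return MetricSeries("end_to_end", d / ANGSTROM_PER_NM, unit="nm")


# ---------------------------------------------------------------------------
# SASA (Shrake--Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    total: float  # A^2
    per_atom: np.ndarray  # A^2, aligned with structure.atoms
    per_residue: dict[str, float]  # residue label -> A^2


def sasa(structure: Structure, probe_radius: float = 1.4,
         n_sphere_points: int = 960) -> SasaResult:
    """Shrake--Rupley solvent accessible surface area.

    Every atom present (hydrogens included, if any) gets a van der Waals
    radius from the shipped Bondi table; unknown elements raise.  Per-residue
    values sum exactly to the total.
    """
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be >= 60")
    try:
        radii = np.array([VDW_RADII[a.element] for a in structure.atoms])
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r} "
                         f"(table {VDW_RADII_VERSION})") from None
    coords = structure.coords
    expanded = radii + probe_radius
    sphere = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], expanded[i] + expanded.max())
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        frac = accessible.mean()
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    per_residue: dict[str, float] = {}
    for key, indices in structure.residues():
        label = f"{key[3]}{key[1]}{key[2]}"
        per_residue[label] = float(per_atom[indices].sum())
    return SasaResult(total=float(per_atom.sum()), per_atom=per_atom,
                      per_residue=per_residue)


def sasa_series(trajectory: Trajectory, probe_radius: float = 1.4,
                n_sphere_points: int = 240) -> MetricSeries:
    vals = [sasa(f, probe_radius, n_sphere_points).total for f in trajectory.frames]
    return MetricSeries("sasa", np.array(vals), unit="A^2")


# ---------------------------------------------------------------------------
# Inter-group distances / hydrogen bonds
# ---------------------------------------------------------------------------

def _heavy_subset(structure: Structure, mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty atom mask")
    idx = np.arange(len(structure))[mask]
    heavy = [i for i in idx if structure.atoms[i].is_heavy]
    if not heavy:
        raise ValueError("atom mask selects no heavy atoms")
    return np.array(heavy, dtype=int)


def min_distance_series(trajectory: Trajectory, group_a, group_b) -> MetricSeries:
    """Per-frame minimum heavy-atom pair distance (nm) between two atom
    groups, given as index arrays or boolean masks over the frame atoms."""
    frame0 = trajectory.frames[0]
    ia = _heavy_subset(frame0, group_a)
    ib = _heavy_subset(frame0, group_b)
    vals = []
    for frame in trajectory.frames:
        c = frame.coords
        d, _ = cKDTree(c[ib]).query(c[ia], k=1)
        vals.append(d.min())
    return MetricSeries("min_distance", np.array(vals) / ANGSTROM_PER_NM, unit="nm")


def hbond_series(trajectory: Trajectory, annotation_a, annotation_b,
                 criteria=None) -> tuple[MetricSeries, dict[str, float]]:
    """Per-frame hydrogen-bond count between two annotated molecules, plus
    the per-residue average number of bonds (keyed by residue labels of the
    first molecule).

    Annotations and criteria are those of
    :func:`ensdock.interaction_geometry.detect_hbonds`; the count is
    evaluated frame by frame on the trajectory coordinates.
    """
    from .interaction_geometry import HBondCriteria, detect_hbonds

    criteria = criteria or HBondCriteria()
    counts = []
    residue_totals: dict[str, float] = {}
    n_frames = len(trajectory)
    for frame in trajectory.frames:
        records = detect_hbonds(frame, frame, annotation_a, annotation_b, criteria)
        counts.append(len(records))
        for rec in records:
            label = rec.participants.get("donor_residue")
            if rec.participants.get("donor_side") != "a":
                label = rec.participants.get("acceptor_residue")
            if label:
                residue_totals[label] = residue_totals.get(label, 0.0) + 1.0
    per_residue = {k: v / n_frames for k, v in residue_totals.items()}
    return MetricSeries("hbonds", np.array(counts, float), unit="count"), per_residue
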