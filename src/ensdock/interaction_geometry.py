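"""Geometric detection and classification of noncovalent interactions.

Covers the interaction types that dominate small-molecule binding to
aromatic-rich peptide regions: hydrogen bonds, pi-pi stacking (parallel and
T-shaped), XH-pi with X in {C, N, O}, and lone-pair-pi contacts.

The literature names these types without universal thresholds, so every
cutoff lives in one criteria object (:class:`InteractionCriteria`) with
defaults that follow common structural-biology practice.  Every emitted
:class:`InteractionRecord` stores the geometry it was classified on, and
:func:`audit_record` re-checks a record against the criteria — so results
are reproducible and self-consistent for *any* chosen thresholds.

Angle conventions: the interplanar angle between two rings is folded to
[0, 90] degrees so the sign ambiguity of plane normals cannot flip a
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .structure_io import Atom, Structure

__all__ = [
    "AromaticRing",
    "InteractionRecord",
    "HBondCriteria",
    "InteractionCriteria",
    "MoleculeAnnotation",
    "RING_TEMPLATES",
    "detect_rings",
    "detect_hbonds",
    "classify_aromatic",
    "classify_xh_pi",
    "classify_lonepair_pi",
    "classify_complex",
    "audit_record",
    "build_protein_annotation",
]

# Side-chain ring templates for the aromatic amino acids.
RING_TEMPLATES: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"],
    ],
}

# Donor heavy atoms (beyond backbone N) and acceptors per amino acid.
_SIDECHAIN_DONORS: dict[str, list[str]] = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "TRP": ["NE1"], "HIS": ["ND1", "NE2"],
    "ASN": ["ND2"], "GLN": ["NE2"], "CYS": ["SG"],
}
_SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "SER": ["OG"],
    "THR": ["OG1"], "TYR": ["OH"], "ASN": ["OD1"], "GLN": ["OE1"],
    "HIS": ["ND1", "NE2"], "MET": ["SD"],
}


@dataclass(frozen=True)
class HBondCriteria:
    """Hydrogen-bond acceptance: donor-acceptor distance and D-H-A angle."""

    d_max: float = 3.5       # A, donor heavy atom to acceptor
    theta_min: float = 130.0  # degrees, donor-H-acceptor
    distance_only: bool = False  # accept on distance alone (no hydrogens needed)


@dataclass(frozen=True)
class InteractionCriteria:
    """All geometric thresholds of the aromatic classifiers, in one place."""

    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    pi_pi_parallel_d_max: float = 5.5   # A, centroid-centroid
    pi_pi_parallel_alpha_max: float = 30.0  # degrees, interplanar
    pi_pi_tshaped_d_max: float = 6.0
    pi_pi_tshaped_alpha_min: float = 60.0
    xh_pi_h_centroid_max: float = 3.0   # A, H to ring centroid
    xh_pi_lateral_slack: float = 0.5    # A beyond ring radius, in-plane offset
    xh_pi_approach_max: float = 60.0    # degrees between X->H and H->centroid
    lonepair_pi_d_max: float = 3.5      # A, atom to centroid
    lonepair_pi_axial_max: float = 25.0  # degrees off the ring normal
    # aromatic rings are planar to < 0.01 A while saturated half-chair rings
    # (e.g. the flavan pyran) deviate by ~0.25-0.5 A; 0.1 A separates them
    ring_planarity_tol: float = 0.1     # A, max out-of-plane deviation


@dataclass
class AromaticRing:
    """A perceived aromatic ring: member atoms, centroid and unit normal."""

    member_indices: list[int]
    centroid: np.ndarray
    normal: np.ndarray
    source: str  # e.g. "TYR10" or "LIG:ring0"
    radius: float  # mean member-centroid distance, A

    def __post_init__(self):
        n = np.asarray(self.normal, float)
        self.normal = n / np.linalg.norm(n)
        self.centroid = np.asarray(self.centroid, float)


@dataclass
class InteractionRecord:
    """One classified interaction with the geometry it was accepted on."""

    kind: str  # hbond | pi_pi_parallel | pi_pi_tshaped | xh_pi | lonepair_pi
    participants: dict
    geometry: dict  # distances in A, angles in degrees


@dataclass
class MoleculeAnnotation:
    """Donor/acceptor/ring annotation for one molecule.

    ``donors`` are (heavy atom index, hydrogen index or None) pairs,
    ``acceptors`` are atom indices, ``rings`` are lists of member indices.
    Indices refer to the structure the annotation is applied to.
    """

    donors: list[tuple[int, int | None]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    rings: list[list[int]] = field(default_factory=list)
    label: str = ""


def _fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit plane through points: (centroid, unit normal, max deviation)."""
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    _, _, vt = np.linalg.svd(centred)
    normal = vt[2]
    deviation = float(np.abs(centred @ normal).max())
    return centroid, normal, deviation


def _ring_from_indices(structure: Structure, indices: Sequence[int], source: str,
                       planarity_tol: float) -> AromaticRing | None:
    coords = structure.coords[list(indices)]
    centroid, normal, deviation = _fit_plane(coords)
    if deviation > planarity_tol:
        return None
    radius = float(np.linalg.norm(coords - centroid, axis=1).mean())
    return AromaticRing(list(indices), centroid, normal, source, radius)


def detect_rings(structure: Structure,
                 ligand_rings: Sequence[Sequence[int]] | None = None,
                 connectivity: Iterable[tuple[int, int]] | None = None,
                 criteria: InteractionCriteria | None = None) -> list[AromaticRing]:
    """Perceive aromatic rings.

    Protein rings come from fixed residue templates (PHE/TYR six-membered,
    HIS five-membered, TRP both).  Ligand rings come from an explicit
    annotation (lists of atom indices) when given, otherwise from cycle
    perception on a bond connectivity table: 5- and 6-membered cycles that
    pass the planarity tolerance are accepted (puckered rings such as a
    flavan pyran ring are rejected by planarity).
    """
    criteria = criteria or InteractionCriteria()
    tol = criteria.ring_planarity_tol
    rings: list[AromaticRing] = []
    for key, indices in structure.residues():
        resname = key[3]
        templates = RING_TEMPLATES.get(resname)
        if not templates:
            continue
        by_name = {structure.atoms[i].name: i for i in indices}
        for template in templates:
            if all(n in by_name for n in template):
                ring = _ring_from_indices(structure, [by_name[n] for n in template],
                                          f"{resname}{key[1]}", tol)
                if ring is not None:
                    rings.append(ring)
    if ligand_rings is not None:
        for k, members in enumerate(ligand_rings):
            for i in members:
                if i < 0 or i >= len(structure):
                    raise ValueError(f"ring annotation references missing atom index {i}")
            ring = _ring_from_indices(structure, list(members), f"LIG:ring{k}", tol)
            if ring is not None:
                rings.append(ring)
    elif connectivity is not None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(structure)))
        g.add_edges_from(connectivity)
        seen: set[frozenset] = set()
        for cycle in nx.minimum_cycle_basis(g):
            if len(cycle) not in (5, 6):
                continue
            fs = frozenset(cycle)
            if fs in seen:
                continue
            seen.add(fs)
            ordered = _order_cycle(g, cycle)
            ring = _ring_from_indices(structure, ordered,
                                      f"LIG:ring{len(rings)}", tol)
            if ring is not None:
                rings.append(ring)
    return rings


def _order_cycle(graph, cycle: list[int]) -> list[int]:
    """Order cycle members by walking edges (minimum_cycle_basis is unordered)."""
    members = set(cycle)
    start = cycle[0]
    ordered = [start]
    prev = None
    while len(ordered) < len(cycle):
        nxt = [n for n in graph.neighbors(ordered[-1]) if n in members and n != prev]
        if not nxt:
            return cycle  # not a simple cycle in this subgraph; fall back
        prev = ordered[-1]
        ordered.append(nxt[0])
    return ordered


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between ring planes, folded to [0, 90] degrees."""
    cosang = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(structure_a: Structure, structure_b: Structure,
                  annotation_a: MoleculeAnnotation, annotation_b: MoleculeAnnotation,
                  criteria: HBondCriteria | None = None) -> list[InteractionRecord]:
    """Detect inter-molecular hydrogen bonds, symmetric over which molecule
    donates: both (donor in A, acceptor in B) and (donor in B, acceptor in A)
    directions are scanned.

    Acceptance: donor-acceptor distance <= ``d_max`` AND donor-H-acceptor
    angle >= ``theta_min`` (boundary inclusive).  A declared donor without a
    hydrogen raises unless ``distance_only`` is set.
    """
    criteria = criteria or HBondCriteria()
    records: list[InteractionRecord] = []
    for side, (s_don, ann_don, s_acc, ann_acc) in (
        ("a", (structure_a, annotation_a, structure_b, annotation_b)),
        ("b", (structure_b, annotation_b, structure_a, annotation_a)),
    ):
        for x_idx, h_idx in ann_don.donors:
            x = s_don.atoms[x_idx]
            if h_idx is None and not criteria.distance_only:
                raise ValueError(
                    f"donor {x.name} ({x.residue_label}) has no attached hydrogen; "
                    "use distance_only criteria or provide hydrogens")
            for a_idx in ann_acc.acceptors:
                acc = s_acc.atoms[a_idx]
                d_da = float(np.linalg.norm(x.coords - acc.coords))
                if d_da > criteria.d_max:
                    continue
                geometry = {"d_donor_acceptor": d_da}
                if not criteria.distance_only:
                    h = s_don.atoms[h_idx]
                    theta = _angle_deg(x.coords - h.coords, acc.coords - h.coords)
                    if theta < criteria.theta_min:
                        continue
                    geometry["theta_dha"] = theta
                records.append(InteractionRecord(
                    kind="hbond",
                    participants={
                        "donor_side": side,
                        "donor": x.name, "donor_residue": x.residue_label,
                        "acceptor": acc.name, "acceptor_residue": acc.residue_label,
                        "donor_index": x_idx, "acceptor_index": a_idx,
                    },
                    geometry=geometry,
                ))
    return records


# ---------------------------------------------------------------------------
# Aromatic classifiers
# ---------------------------------------------------------------------------

def classify_aromatic(r1: AromaticRing, r2: AromaticRing,
                      criteria: InteractionCriteria | None = None) -> InteractionRecord | None:
    """Classify a ring pair as parallel stacking, T-shaped, or neither.

    Parallel: centroid distance <= 5.5 A and interplanar angle <= 30 deg.
    T-shaped: centroid distance <= 6.0 A and interplanar angle >= 60 deg.
    """
    criteria = criteria or InteractionCriteria()
    d = float(np.linalg.norm(r1.centroid - r2.centroid))
    alpha = _interplanar_angle(r1.normal, r2.normal)
    geometry = {"d_centroid": d, "alpha_interplanar": alpha}
    participants = {"ring1": r1.source, "ring2": r2.source}
    if d <= criteria.pi_pi_parallel_d_max and alpha <= criteria.pi_pi_parallel_alpha_max:
        return InteractionRecord("pi_pi_parallel", participants, geometry)
    if d <= criteria.pi_pi_tshaped_d_max and alpha >= criteria.pi_pi_tshaped_alpha_min:
        return InteractionRecord("pi_pi_tshaped", participants, geometry)
    return None


def classify_xh_pi(x_atom: Atom, h_atom: Atom | None, ring: AromaticRing,
                   criteria: InteractionCriteria | None = None) -> InteractionRecord | None:
    """XH-pi contact (X in {C, N, O}): the H sits over the ring face.

    Acceptance: H-centroid distance <= 3.0 A, the in-plane projection of H
    falls within ring radius + 0.5 A of the centroid, and the X-H bond
    points at the ring (angle between X->H and H->centroid <= 60 deg).
    """
    criteria = criteria or InteractionCriteria()
    if x_atom.element not in ("C", "N", "O"):
        raise ValueError(f"XH-pi donor element must be C, N or O, got {x_atom.element}")
    if h_atom is None:
        raise ValueError(f"XH-pi donor {x_atom.name} has no attached hydrogen")
    to_centroid = ring.centroid - h_atom.coords
    d_hc = float(np.linalg.norm(to_centroid))
    if d_hc > criteria.xh_pi_h_centroid_max:
        return None
    axial = float(np.dot(h_atom.coords - ring.centroid, ring.normal))
    lateral = float(np.linalg.norm((h_atom.coords - ring.centroid) - axial * ring.normal))
    if lateral > ring.radius + criteria.xh_pi_lateral_slack:
        return None
    approach = _angle_deg(h_atom.coords - x_atom.coords, to_centroid)
    if approach > criteria.xh_pi_approach_max:
        return None
    return InteractionRecord(
        "xh_pi",
        {"x": x_atom.name, "x_residue": x_atom.residue_label, "ring": ring.source,
         "x_element": x_atom.element},
        {"d_h_centroid": d_hc, "lateral_offset": lateral, "approach_angle": approach},
    )


def classify_lonepair_pi(acceptor_atom: Atom, ring: AromaticRing,
                         criteria: InteractionCriteria | None = None) -> InteractionRecord | None:
    """Lone-pair-pi contact: an O/N lone-pair carrier sits on the ring axis.

    Acceptance: atom-centroid distance <= 3.5 A and the atom lies within
    25 deg of the ring normal through the centroid.
    """
    criteria = criteria or InteractionCriteria()
    if acceptor_atom.element not in ("O", "N"):
        raise ValueError(f"lone-pair donor element must be O or N, got {acceptor_atom.element}")
    v = acceptor_atom.coords - ring.centroid
    d = float(np.linalg.norm(v))
    if d > criteria.lonepair_pi_d_max:
        return None
    axial_angle = _angle_deg(v, ring.normal)
    axial_angle = min(axial_angle, 180.0 - axial_angle)  # normal sign ambiguity
    if axial_angle > criteria.lonepair_pi_axial_max:
        return None
    return InteractionRecord(
        "lonepair_pi",
        {"atom": acceptor_atom.name, "atom_residue": acceptor_atom.residue_label,
         "ring": ring.source},
        {"d_centroid": d, "axial_angle": axial_angle},
    )


# ---------------------------------------------------------------------------
# Self-consistency audit & complex-level driver
# ---------------------------------------------------------------------------

def audit_record(record: InteractionRecord,
                 criteria: InteractionCriteria | None = None) -> bool:
    """Re-check a record's stored geometry against the classifier thresholds."""
    c = criteria or InteractionCriteria()
    g = record.geometry
    if record.kind == "hbond":
        ok = g["d_donor_acceptor"] <= c.hbond.d_max
        if "theta_dha" in g:
            ok = ok and g["theta_dha"] >= c.hbond.theta_min
        return ok
    if record.kind == "pi_pi_parallel":
        return (g["d_centroid"] <= c.pi_pi_parallel_d_max
                and g["alpha_interplanar"] <= c.pi_pi_parallel_alpha_max)
    if record.kind == "pi_pi_tshaped":
        return (g["d_centroid"] <= c.pi_pi_tshaped_d_max
                and g["alpha_interplanar"] >= c.pi_pi_tshaped_alpha_min)
    if record.kind == "xh_pi":
        return (g["d_h_centroid"] <= c.xh_pi_h_centroid_max
                and g["approach_angle"] <= c.xh_pi_approach_max)
    if record.kind == "lonepair_pi":
        return (g["d_centroid"] <= c.lonepair_pi_d_max
                and g["axial_angle"] <= c.lonepair_pi_axial_max)
    raise ValueError(f"unknown interaction kind {record.kind!r}")


def build_protein_annotation(structure: Structure) -> MoleculeAnnotation:
    """Donor/acceptor/ring annotation for a standard-residue protein.

    Backbone N donates (when an amide H is present) and backbone O accepts;
    side-chain donors/acceptors follow fixed per-residue tables.  Donor
    hydrogens are matched by proximity (< 1.3 A) when present; donors
    without hydrogens are recorded with ``None`` (usable in distance-only
    mode).
    """
    ann = MoleculeAnnotation(label=structure.label)
    coords = structure.coords
    hydrogens = [i for i, a in enumerate(structure.atoms) if a.element == "H"]

    def _attached_h(i: int) -> int | None:
        best, best_d = None, 1.3
        for h in hydrogens:
            d = float(np.linalg.norm(coords[h] - coords[i]))
            if d < best_d:
                best, best_d = h, d
        return best

    for key, indices in structure.residues():
        resname = key[3]
        by_name = {structure.atoms[i].name: i for i in indices}
        donor_names = (["N"] if "N" in by_name else []) + [
            n for n in _SIDECHAIN_DONORS.get(resname, []) if n in by_name]
        for n in donor_names:
            i = by_name[n]
            ann.donors.append((i, _attached_h(i)))
        acceptor_names = (["O"] if "O" in by_name else []) + [
            n for n in _SIDECHAIN_ACCEPTORS.get(resname, []) if n in by_name]
        ann.acceptors.extend(by_name[n] for n in acceptor_names)
    for ring in detect_rings(structure):
        ann.rings.append(ring.member_indices)
    return ann


def classify_complex(receptor: Structure, ligand: Structure,
                     receptor_annotation: MoleculeAnnotation,
                     ligand_annotation: MoleculeAnnotation,
                     criteria: InteractionCriteria | None = None) -> list[InteractionRecord]:
    """Run every classifier over a receptor-ligand pair and collect records."""
    criteria = criteria or InteractionCriteria()
    records = detect_hbonds(receptor, ligand, receptor_annotation,
                            ligand_annotation, criteria.hbond)

    def _rings(structure, ann):
        out = []
        for k, members in enumerate(ann.rings):
            ring = _ring_from_indices(structure, members,
                                      f"{ann.label or 'mol'}:ring{k}",
                                      criteria.ring_planarity_tol)
            if ring is not None:
                out.append(ring)
        return out

    rec_rings = _rings(receptor, receptor_annotation)
    lig_rings = _rings(ligand, ligand_annotation)
    for r1 in rec_rings:
        for r2 in lig_rings:
            rec = classify_aromatic(r1, r2, criteria)
            if rec is not None:
                records.append(rec)
    # XH-pi and lone-pair-pi, both directions.
    for rings, structure, ann_other, structure_other in (
        (lig_rings, ligand, receptor_annotation, receptor),
        (rec_rings, receptor, ligand_annotation, ligand),
    ):
        for ring in rings:
            for x_idx, h_idx in ann_other.donors:
                if h_idx is None:
                    continue
                x = structure_other.atoms[x_idx]
                if x.element not in ("C", "N", "O"):
                    continue
                rec = classify_xh_pi(x, structure_other.atoms[h_idx], ring, criteria)
                if rec is not None:
                    records.append(rec)
            for a_idx in ann_other.acceptors:
                acc = structure_other.atoms[a_idx]
                if acc.element not in ("O", "N"):
                    continue
                rec = classify_lonepair_pi(acc, ring, criteria)
                if rec is not None:
                    records.append(rec)
    return records
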