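"""Synthetic inputs for the whole pipeline.

Everything the pipeline consumes can be generated here deterministically
from a seed: toy bead-chain peptide conformers (with an amyloid-beta-like
sequence so residue labels such as TYR10/PHE19/PHE20 are meaningful),
a rigid two-ring toy ligand with annotated donors and acceptors, Vina-format
multi-pose result files with controlled affinity gaps and planted
residue-contact distances, minimal geometric fixtures for every interaction
class (each with a "negative twin" violating exactly one threshold), and
noisy trajectories with scripted hydrogen-bond events.

All outputs are plain text in standard formats, so the fixtures double as
format-conformance tests; identical seeds give byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contact_analysis import residue_min_distances
from .interaction_geometry import MoleculeAnnotation
from .structure_io import Atom, PoseBlock, Structure
from .trajectory_metrics import Trajectory

__all__ = [
    "AB42_SEQUENCE",
    "FixtureSpec",
    "FixtureError",
    "make_toy_peptide",
    "toy_ligand",
    "make_pose_set",
    "write_pose_set",
    "InteractionFixture",
    "make_interaction_fixture",
    "make_trajectory",
    "INTERACTION_KINDS",
]

# 42-residue amyloid-beta sequence (DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA)
# as 3-letter codes; used cyclically for other chain lengths.
AB42_SEQUENCE = (
    "ASP ALA GLU PHE ARG HIS ASP SER GLY TYR GLU VAL HIS HIS GLN LYS LEU VAL "
    "PHE PHE ALA GLU ASP VAL GLY SER ASN LYS GLY ALA ILE ILE GLY LEU MET VAL "
    "GLY GLY VAL VAL ILE ALA"
).split()

BOND_LENGTH = 3.8  # A, consecutive-bead spacing

INTERACTION_KINDS = ("hbond", "pi_pi_parallel", "pi_pi_tshaped", "xh_pi", "lonepair_pi")


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of one synthetic docking-result fixture."""

    seed: int = 0
    n_receptors: int = 1
    poses_per_run: int = 9
    affinity_top: float = -8.0  # kcal/mol
    gap_distribution: tuple = ("uniform", 0.0, 0.3)  # name + parameters
    planted_contacts: list = field(default_factory=list)  # (residue_number, (lo, hi])
    planted_interactions: list = field(default_factory=list)
    pose_jitter: float = 0.0  # A, rigid perturbation of poses 2..n

    def __post_init__(self):
        if self.n_receptors < 1 or self.poses_per_run < 1:
            raise FixtureError("counts must be positive")
        name = self.gap_distribution[0]
        if name not in ("constant", "uniform", "exponential"):
            raise FixtureError(f"unknown gap distribution {name!r}")

    def draw_gaps(self, rng: np.random.Generator) -> np.ndarray:
        """Non-negative affinity gaps between consecutive ranks."""
        n = self.poses_per_run - 1
        kind = self.gap_distribution[0]
        if kind == "constant":
            gaps = np.full(n, float(self.gap_distribution[1]))
        elif kind == "uniform":
            lo, hi = float(self.gap_distribution[1]), float(self.gap_distribution[2])
            gaps = rng.uniform(lo, hi, size=n)
        else:
            gaps = rng.exponential(float(self.gap_distribution[1]), size=n)
        if np.any(gaps < 0):
            raise FixtureError("gap distribution produced negative gaps")
        return gaps


def _bead(i: int, coords, resname: str, chain: str = "A") -> Atom:
    return Atom(serial=i + 1, name="CA", element="C", residue_name=resname,
                residue_number=i + 1, chain_id=chain,
                coords=np.asarray(coords, float))


def make_toy_peptide(n_residues: int, conformation: str = "extended",
                     seed: int = 0) -> Structure:
    """One bead (a CA pseudo-atom) per residue, sequence from the
    amyloid-beta template.

    ``extended``: planar zig-zag with 120-degree bead angles (monotone x);
    ``collapsed``: compact spherical spiral with near-bond-length spacing;
    ``random``: fixed-step random walk with soft self-avoidance.
    """
    if n_residues < 2:
        raise FixtureError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    if conformation == "extended":
        dx = BOND_LENGTH * math.sin(math.radians(60.0))
        dy = BOND_LENGTH * math.cos(math.radians(60.0))
        for i in range(1, n_residues):
            coords[i] = coords[i - 1] + (dx, dy if i % 2 else -dy, 0.0)
    elif conformation == "collapsed":
        # spherical spiral sized for ~bead-volume packing
        radius = 0.6 * BOND_LENGTH * n_residues ** (1.0 / 3.0) + 2.0
        k = np.arange(n_residues)
        z = 1.0 - 2.0 * (k + 0.5) / n_residues
        phi = math.pi * (3.0 - math.sqrt(5.0)) * k
        r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        coords = radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    elif conformation == "random":
        for i in range(1, n_residues):
            for _ in range(200):
                step = rng.standard_normal(3)
                step *= BOND_LENGTH / np.linalg.norm(step)
                candidate = coords[i - 1] + step
                if i < 2 or np.min(np.linalg.norm(coords[:i - 1] - candidate, axis=1)) > 2.5:
                    break
            coords[i] = candidate
    else:
        raise FixtureError(f"unknown conformation {conformation!r}")
    atoms = [_bead(i, coords[i], AB42_SEQUENCE[i % len(AB42_SEQUENCE)])
             for i in range(n_residues)]
    return Structure(atoms, label=f"toy_{conformation}_{seed}")


# ---------------------------------------------------------------------------
# Toy ligand
# ---------------------------------------------------------------------------

def _hexagon(center, normal, radius: float = 1.39) -> np.ndarray:
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.radians(np.arange(6) * 60.0)
    return np.asarray(center, float) + radius * (
        np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def toy_ligand() -> tuple[Structure, MoleculeAnnotation]:
    """A rigid 14-heavy-atom two-ring fragment with hydroxyl donors.

    Two coplanar six-membered carbon rings bridged ring-edge to ring-edge
    (biphenyl-like), one hydroxyl (O-H) on each ring, and the hydroxyl
    oxygens double as acceptors.  The annotation carries donors, acceptors
    and both ring atom groups.
    """
    ring_a = _hexagon((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    ring_b = _hexagon((4.2, 0.0, 0.0), (0.0, 0.0, 1.0))
    atoms: list[Atom] = []

    def _add(name, element, xyz):
        atoms.append(Atom(serial=len(atoms) + 1, name=name, element=element,
                          residue_name="LIG", residue_number=1, chain_id="L",
                          coords=np.asarray(xyz, float), record="HETATM"))

    for k, xyz in enumerate(ring_a):
        _add(f"C{k + 1}", "C", xyz)
    for k, xyz in enumerate(ring_b):
        _add(f"C{k + 7}", "C", xyz)
    # hydroxyls: O bonded outward from a ring carbon, H beyond it
    o1 = ring_a[3] + np.array([-1.36, 0.0, 0.0])
    _add("O1", "O", o1)
    _add("H1", "H", o1 + np.array([-0.95, 0.0, 0.0]))
    o2 = ring_b[0] + np.array([1.36, 0.0, 0.0])
    _add("O2", "O", o2)
    _add("H2", "H", o2 + np.array([0.95, 0.0, 0.0]))
    structure = Structure(atoms, label="toy_ligand")
    annotation = MoleculeAnnotation(
        donors=[(12, 13), (14, 15)],
        acceptors=[12, 14],
        rings=[list(range(0, 6)), list(range(6, 12))],
        label="LIG",
    )
    return structure, annotation


# ---------------------------------------------------------------------------
# Pose sets (Vina-dialect PDBQT)
# ---------------------------------------------------------------------------

_AD_TYPE = {"H": "HD", "O": "OA", "N": "NA"}


def _format_pdbqt_atom(atom: Atom) -> str:
    x, y, z = atom.coords
    adtype = _AD_TYPE.get(atom.element, atom.element)
    return (
        f"HETATM{atom.serial:>5d}  {atom.name:<3.3s} {atom.residue_name:>3s} "
        f"{atom.chain_id:1s}{atom.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}    {0.000:6.3f} {adtype:<2s}\n"
    )


def _rotation_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation sending unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        return _rotation_from_axis_angle(axis, math.pi)
    axis = np.cross(a, b)
    return _rotation_from_axis_angle(axis, math.acos(c))


def _place_ligand(receptor: Structure, ligand: Structure,
                  planted_contacts: list) -> np.ndarray:
    """Rigidly place the ligand so each planted (residue, (lo, hi]) band
    holds for that residue's minimum heavy-atom distance."""
    lig_coords = ligand.coords
    centroid_rec = receptor.heavy_coords().mean(axis=0)
    if not planted_contacts:
        # park the ligand just outside the receptor, on the +z side
        span = receptor.heavy_coords()[:, 2].max()
        offset = np.array([0.0, 0.0, span + 8.0])
        return lig_coords - lig_coords.mean(axis=0) + centroid_rec + offset

    resnum, band = planted_contacts[0]
    lo, hi = band
    target_d = 0.5 * (lo + hi)
    anchor = None
    for atom in receptor.atoms:
        if atom.residue_number == resnum and atom.is_heavy:
            anchor = atom.coords
            break
    if anchor is None:
        raise FixtureError(f"receptor has no heavy atom in residue {resnum}")
    # contact atom: the extreme heavy atom along the ligand's principal axis,
    # oriented so every other heavy atom sits at or beyond the target
    # distance from the anchor once the axis points away from the receptor.
    heavy_idx = [i for i, a in enumerate(ligand.atoms) if a.is_heavy]
    heavy = lig_coords[heavy_idx]
    centred = heavy - heavy.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    axis = vt[0]
    proj = centred @ axis
    if proj.max() < -proj.min():
        axis, proj = -axis, -proj
    contact_idx = heavy_idx[int(np.argmin(proj))]
    directions = [np.array([0, 0, 1.0]), np.array([0, 0, -1.0]),
                  anchor - centroid_rec, np.array([0, 1.0, 0]), np.array([1.0, 0, 0])]
    for direction in directions:
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        u = direction / norm
        R = _align_rotation(axis, u)
        rotated = (lig_coords - lig_coords[contact_idx]) @ R.T
        placed = rotated + anchor + target_d * u
        pose = PoseBlock(pose_rank=1, affinity=-1.0,
                         atoms=[a.moved_to(c) for a, c in
                                zip(ligand.atoms, placed)])
        dmin = residue_min_distances(receptor, pose)
        ok = True
        for rn, (blo, bhi) in planted_contacts:
            label = next((a.residue_label for a in receptor.atoms
                          if a.residue_number == rn), None)
            d = dmin.get(label, float("inf"))
            if not (blo < d <= bhi):
                ok = False
                break
        if ok:
            return placed
    raise FixtureError(
        f"cannot satisfy planted contacts {planted_contacts}: constraints overlap "
        "or exceed the ligand's reach")


def make_pose_set(receptor: Structure, spec: FixtureSpec,
                  ligand: Structure | None = None) -> str:
    """Vina-dialect PDBQT content: ``poses_per_run`` MODEL blocks whose
    affinities are ``affinity_top`` plus cumulative non-negative gaps, with
    pose 1 satisfying every planted contact band."""
    if ligand is None:
        ligand, _ = toy_ligand()
    rng = np.random.default_rng(spec.seed)
    gaps = spec.draw_gaps(rng)
    affinities = spec.affinity_top + np.concatenate([[0.0], np.cumsum(gaps)])
    base = _place_ligand(receptor, ligand, spec.planted_contacts)
    blocks = []
    for rank in range(1, spec.poses_per_run + 1):
        coords = base
        if rank > 1 and spec.pose_jitter > 0:
            axis = rng.standard_normal(3)
            R = _rotation_from_axis_angle(axis, rng.uniform(0, 0.2))
            shift = rng.uniform(-spec.pose_jitter, spec.pose_jitter, size=3)
            pivot = base.mean(axis=0)
            coords = (base - pivot) @ R.T + pivot + shift
        lines = [f"MODEL {rank}\n",
                 f"REMARK VINA RESULT:    {affinities[rank - 1]:8.3f}      0.000      0.000\n"]
        for atom, xyz in zip(ligand.atoms, coords):
            lines.append(_format_pdbqt_atom(atom.moved_to(xyz)))
        lines.append("ENDMDL\n")
        blocks.append("".join(lines))
    return "".join(blocks)


def write_pose_set(receptor: Structure, spec: FixtureSpec, path,
                   ligand: Structure | None = None) -> Path:
    path = Path(path)
    path.write_text(make_pose_set(receptor, spec, ligand))
    return path


# ---------------------------------------------------------------------------
# Interaction fixtures
# ---------------------------------------------------------------------------

@dataclass
class InteractionFixture:
    """A minimal positive example of one interaction kind plus a negative
    twin in which exactly one acceptance threshold is violated."""

    kind: str
    structure: Structure            # positive example
    negative: Structure             # violates one threshold
    rings: list[list[int]]          # ring atom-index groups (may be empty)
    donor: tuple[int, int] | None = None     # (X, H) indices
    acceptor: int | None = None
    partner_acceptor: int | None = None      # acceptor on the second fragment


def _ring_atoms(center, normal, resname="PHE", resnum=1, chain="A",
                serial_start=1, names=("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
    coords = _hexagon(center, normal)
    return [Atom(serial=serial_start + k, name=names[k], element=names[k][0],
                 residue_name=resname, residue_number=resnum, chain_id=chain,
                 coords=c) for k, c in enumerate(coords)]


def _simple_atom(serial, name, element, xyz, resname="LIG", resnum=2, chain="L"):
    return Atom(serial=serial, name=name, element=element, residue_name=resname,
                residue_number=resnum, chain_id=chain,
                coords=np.asarray(xyz, float), record="HETATM")


def make_interaction_fixture(kind: str, **overrides) -> InteractionFixture:
    """Construct the canonical geometry of one interaction kind.

    Geometry overrides (e.g. ``distance=...``) shift the positive example;
    values outside the representable geometry raise :class:`FixtureError`.
    """
    if kind not in INTERACTION_KINDS:
        raise FixtureError(f"unknown interaction kind {kind!r}")
    if kind == "pi_pi_parallel":
        d = float(overrides.get("distance", 3.5))
        if d <= 0:
            raise FixtureError("ring separation must be positive")
        ring1 = _ring_atoms((0, 0, 0), (0, 0, 1))
        pos = ring1 + _ring_atoms((0, 0, d), (0, 0, 1), resname="LIG", resnum=2,
                                  chain="L", serial_start=7,
                                  names=("C1", "C2", "C3", "C4", "C5", "C6"))
        neg = ring1 + _ring_atoms((0, 0, 6.5), (0, 0, 1), resname="LIG", resnum=2,
                                  chain="L", serial_start=7,
                                  names=("C1", "C2", "C3", "C4", "C5", "C6"))
        return InteractionFixture(kind, Structure(pos, "pi_pi_parallel"),
                                  Structure(neg, "pi_pi_parallel_neg"),
                                  rings=[list(range(6)), list(range(6, 12))])
    if kind == "pi_pi_tshaped":
        d = float(overrides.get("distance", 5.0))
        ring1 = _ring_atoms((0, 0, 0), (0, 0, 1))
        pos = ring1 + _ring_atoms((0, 0, d), (1, 0, 0), resname="LIG", resnum=2,
                                  chain="L", serial_start=7,
                                  names=("C1", "C2", "C3", "C4", "C5", "C6"))
        neg = ring1 + _ring_atoms((0, 0, 7.0), (1, 0, 0), resname="LIG", resnum=2,
                                  chain="L", serial_start=7,
                                  names=("C1", "C2", "C3", "C4", "C5", "C6"))
        return InteractionFixture(kind, Structure(pos, "pi_pi_tshaped"),
                                  Structure(neg, "pi_pi_tshaped_neg"),
                                  rings=[list(range(6)), list(range(6, 12))])
    if kind == "hbond":
        d = float(overrides.get("distance", 2.9))
        if not 1.5 < d:
            raise FixtureError("donor-acceptor distance too short")
        donor_o = _simple_atom(1, "OG", "O", (0, 0, 0), resname="SER", resnum=1, chain="A")
        h = _simple_atom(2, "HG", "H", (0.95, 0, 0), resname="SER", resnum=1, chain="A")
        pos_acc = _simple_atom(3, "O1", "O", (d, 0, 0))
        # negative twin: same D...A distance, D-H-A angle 90 degrees
        neg_h = _simple_atom(2, "HG", "H", (0, 0.95, 0), resname="SER", resnum=1, chain="A")
        return InteractionFixture(
            kind,
            Structure([donor_o, h, pos_acc], "hbond"),
            Structure([donor_o, neg_h, pos_acc], "hbond_neg"),
            rings=[], donor=(0, 1), acceptor=2, partner_acceptor=2)
    if kind == "xh_pi":
        h_height = float(overrides.get("distance", 2.6))
        if h_height <= 0:
            raise FixtureError("H height must be positive")
        ring = _ring_atoms((0, 0, 0), (0, 0, 1))
        h = _simple_atom(7, "H1", "H", (0, 0, h_height))
        x = _simple_atom(8, "C7", "C", (0, 0, h_height + 1.09))
        neg_h = _simple_atom(7, "H1", "H", (3.0, 0, h_height))  # 3 A lateral offset
        neg_x = _simple_atom(8, "C7", "C", (3.0, 0, h_height + 1.09))
        return InteractionFixture(
            kind,
            Structure(ring + [h, x], "xh_pi"),
            Structure(ring + [neg_h, neg_x], "xh_pi_neg"),
            rings=[list(range(6))], donor=(7, 6))
    # lonepair_pi
    d = float(overrides.get("distance", 3.0))
    ring = _ring_atoms((0, 0, 0), (0, 0, 1))
    o = _simple_atom(7, "O1", "O", (0, 0, d))
    neg_o = _simple_atom(7, "O1", "O", (0, 0, 4.5))
    return InteractionFixture(
        "lonepair_pi",
        Structure(ring + [o], "lonepair_pi"),
        Structure(ring + [neg_o], "lonepair_pi_neg"),
        rings=[list(range(6))], acceptor=6)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def make_trajectory(base: Structure, n_frames: int, noise_amplitude: float = 0.0,
                    planted_events: list | None = None, seed: int = 0) -> Trajectory:
    """Gaussian positional noise around a base structure, plus scripted
    events.

    Each event is a dict: ``{"kind": "hbond", "donor": i, "hydrogen": j,
    "acceptor": k, "frames": iterable}`` — in listed frames the acceptor is
    placed colinear with the X-H bond at 2.9 A from the donor (ideal
    hydrogen bond); in all other frames it is moved to 6.0 A (no bond).
    Deterministic per seed.
    """
    if n_frames < 1:
        raise FixtureError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    base_coords = base.coords
    frames = []
    events = planted_events or []
    for t in range(n_frames):
        coords = base_coords.copy()
        if noise_amplitude > 0:
            coords = coords + rng.normal(scale=noise_amplitude, size=coords.shape)
        for event in events:
            if event.get("kind") != "hbond":
                raise FixtureError(f"unknown planted event kind {event.get('kind')!r}")
            i, j, k = event["donor"], event["hydrogen"], event["acceptor"]
            u = coords[j] - coords[i]
            u = u / np.linalg.norm(u)
            dist = 2.9 if t in event["frames"] else 6.0
            coords[k] = coords[i] + dist * u
        frames.append(base.with_coords(coords, label=f"{base.label}_frame{t}"))
    return Trajectory(frames)
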