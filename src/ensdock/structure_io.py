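"""Structure I/O: fixed-column PDB and Vina-dialect PDBQT result files.

All downstream modules consume the flat :class:`Atom` / :class:`Structure`
containers defined here.  The PDB reader follows the v3.3 fixed-column
layout for ``ATOM``/``HETATM``/``MODEL``/``ENDMDL`` records; the PDBQT
reader accepts only the AutoDock Vina *output* dialect (``MODEL`` blocks
carrying a ``REMARK VINA RESULT:`` affinity line).

Conventions
-----------
* Residue numbering is taken verbatim from the file (1-based in practice);
  residues are reported downstream as NAME+NUMBER, e.g. ``TYR10``.
* Element inference when the element column (77-78) is blank: leading
  digits of the atom name are stripped and the first alphabetic character
  is taken as the element symbol (so ``1HG1`` -> H, ``CA`` -> C).  Files
  with real two-letter elements should carry the element column.
* Alternate locations: altloc ``'A'`` or blank is kept, every other altloc
  is dropped, so heavy-atom sets are deterministic.
* Hydrogens are identified by element ``H``; ``Atom.is_heavy`` is the
  single source of truth for heavy-atom selections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "PoseBlock",
    "PDBParseError",
    "read_pdb",
    "read_vina_pdbqt",
    "write_pdb",
    "format_pdb_atom_line",
]


class PDBParseError(ValueError):
    """Raised for malformed PDB/PDBQT input; carries the offending line number."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line_number is not None:
            loc += f":{line_number}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line_number = line_number


# AutoDock atom types that do not map to an element by first letter.
_AUTODOCK_TYPE_TO_ELEMENT = {
    "A": "C",   # aromatic carbon
    "OA": "O",
    "NA": "N",
    "SA": "S",
    "HD": "H",
    "HS": "H",
    "NS": "N",
    "OS": "O",
}


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``coords`` are in Angstrom.  ``residue_number`` and ``chain_id`` are
    preserved exactly as read; ``insertion_code`` participates in residue
    identity so inserted residues are never merged.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    insertion_code: str = ""
    altloc: str = ""
    record: str = "ATOM"

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        """(chain, number, insertion code, name) — identity of the parent residue."""
        return (self.chain_id, self.residue_number, self.insertion_code, self.residue_name)

    @property
    def residue_label(self) -> str:
        """NAME+NUMBER label, e.g. ``TYR10``."""
        return f"{self.residue_name}{self.residue_number}{self.insertion_code}"

    def moved_to(self, coords) -> "Atom":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Structure:
    """An ordered set of atoms: one conformer or one trajectory frame."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("Structure requires at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def heavy_coords(self) -> np.ndarray:
        idx = self.heavy_indices
        if idx.size == 0:
            raise ValueError(f"structure {self.label!r} has no heavy atoms")
        return self.coords[idx]

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape {(len(self.atoms), 3)}, got {coords.shape}")
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, label=self.label if label is None else label)

    def residues(self) -> list[tuple[tuple, list[int]]]:
        """Residues in order of first appearance: (residue_key, atom indices)."""
        order: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            order.setdefault(a.residue_key, []).append(i)
        return list(order.items())

    def residue_labels(self) -> list[str]:
        return [f"{key[3]}{key[1]}{key[2]}" for key, _ in self.residues()]


@dataclass
class PoseBlock:
    """One docked ligand pose: rank (file order, 1-based) and Vina affinity."""

    pose_rank: int
    affinity: float  # kcal/mol, more negative = better
    atoms: list[Atom]

    def __post_init__(self):
        if self.pose_rank < 1:
            raise ValueError("pose_rank must be >= 1")
        if not math.isfinite(self.affinity):
            raise ValueError("affinity must be finite")
        if not self.atoms:
            raise ValueError("pose has no atoms")

    def as_structure(self, label: str = "") -> Structure:
        return Structure(list(self.atoms), label=label or f"pose{self.pose_rank}")


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def _parse_atom_line(line: str, path, lineno: int, *, pdbqt: bool = False) -> Atom | None:
    """Parse one ATOM/HETATM line; returns None for dropped altlocs."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        residue_name = line[17:20].strip() or line[17:21].strip()
        chain_id = line[21:22].strip() or " "
        residue_number = int(line[22:26])
        insertion_code = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record ({exc})", path, lineno) from None
    if altloc not in ("", "A"):
        return None
    element = ""
    if pdbqt:
        adtype = line[77:79].strip() if len(line) >= 78 else ""
        if adtype:
            element = _AUTODOCK_TYPE_TO_ELEMENT.get(adtype, adtype[0].upper())
    else:
        if len(line) >= 78:
            element = line[76:78].strip().upper()
    if not element:
        try:
            element = _infer_element(name)
        except ValueError as exc:
            raise PDBParseError(str(exc), path, lineno) from None
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain_id=chain_id,
        coords=np.array([x, y, z]),
        insertion_code=insertion_code,
        altloc=altloc,
        record=line[:6].strip(),
    )


def read_pdb(path, model_policy: str = "first"):
    """Read a PDB file.

    Parameters
    ----------
    path : path-like
    model_policy : {"first", "all"}
        ``"first"`` returns a single :class:`Structure` (the first MODEL, or
        the whole file when no MODEL records are present); ``"all"`` returns
        a list with one Structure per MODEL.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    path = Path(path)
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    seen_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                seen_model_record = True
                if current:
                    models.append(current)
                current = []
                in_model = True
            elif rec.startswith("ENDMDL"):
                models.append(current)
                current = []
                in_model = False
                if model_policy == "first" and models and models[0]:
                    break
            elif rec.startswith(("ATOM  ", "HETATM")):
                atom = _parse_atom_line(line, path, lineno)
                if atom is not None:
                    current.append(atom)
    if current or not models:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError("no ATOM/HETATM records found", path)
    label = path.stem
    if model_policy == "first":
        return Structure(models[0], label=label)
    if seen_model_record:
        return [Structure(m, label=f"{label}_model{i + 1}") for i, m in enumerate(models)]
    return [Structure(models[0], label=label)]


def read_vina_pdbqt(path) -> list[PoseBlock]:
    """Read an AutoDock Vina multi-pose output PDBQT file.

    Each ``MODEL`` block must carry a ``REMARK VINA RESULT:`` line whose
    first numeric field is the binding affinity in kcal/mol.  Poses are
    returned in file order (rank 1 = first MODEL); affinity ordering is
    *not* enforced here — it is validated downstream.

    AutoDock flexible-residue / grid-map dialects are rejected.
    """
    path = Path(path)
    poses: list[PoseBlock] = []
    atoms: list[Atom] = []
    affinity: float | None = None
    in_model = False
    model_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("BEGIN_RES", "END_RES")):
                raise PDBParseError(
                    "AutoDock flexible-residue dialect is not supported; "
                    "only Vina output files (MODEL + REMARK VINA RESULT) are accepted",
                    path, lineno,
                )
            if line.startswith("MODEL"):
                if in_model:
                    raise PDBParseError("nested MODEL record", path, lineno)
                in_model = True
                model_line = lineno
                atoms = []
                affinity = None
            elif line.startswith("REMARK VINA RESULT:"):
                fields = line[len("REMARK VINA RESULT:"):].split()
                if not fields:
                    raise PDBParseError("empty VINA RESULT remark", path, lineno)
                try:
                    affinity = float(fields[0])
                except ValueError:
                    raise PDBParseError(
                        f"non-numeric affinity {fields[0]!r} in VINA RESULT remark",
                        path, lineno,
                    ) from None
            elif line.startswith(("ATOM  ", "HETATM")):
                if not in_model:
                    raise PDBParseError(
                        "atom record outside MODEL block: not a Vina output file",
                        path, lineno,
                    )
                atom = _parse_atom_line(line, path, lineno, pdbqt=True)
                if atom is not None:
                    atoms.append(atom)
            elif line.startswith("ENDMDL"):
                if affinity is None:
                    raise PDBParseError(
                        "MODEL block without a REMARK VINA RESULT line",
                        path, model_line,
                    )
                poses.append(PoseBlock(pose_rank=len(poses) + 1, affinity=affinity, atoms=atoms))
                in_model = False
    if in_model:
        raise PDBParseError("unterminated MODEL block", path, model_line)
    if not poses:
        raise PDBParseError("no MODEL blocks found", path)
    return poses


def format_pdb_atom_line(atom: Atom) -> str:
    name = atom.name
    # PDB alignment rule: 1-3 char names start in column 14 unless they
    # begin with a 2-letter element written flush-left.
    if len(name) < 4 and (len(atom.element) == 1 or not name.startswith(atom.element)):
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    record = "HETATM" if atom.record == "HETATM" else "ATOM"
    x, y, z = atom.coords
    return (
        f"{record:<6s}{atom.serial:>5d} {name_field}{atom.altloc or ' ':1s}"
        f"{atom.residue_name:>3s} {atom.chain_id:1s}{atom.residue_number:>4d}"
        f"{atom.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element:>2s}\n"
    )


def write_pdb(structure, path) -> None:
    """Write a Structure (or a sequence of them, as MODEL blocks) to PDB.

    Round-trip guarantee: :func:`read_pdb` on the output reproduces atom
    count, names, residue identity and coordinates to 3 decimals.
    """
    path = Path(path)
    if isinstance(structure, Structure):
        frames: Sequence[Structure] = [structure]
        multimodel = False
    else:
        frames = list(structure)
        if not frames:
            raise ValueError("no structures to write")
        multimodel = True
    with open(path, "w") as fh:
        for i, frame in enumerate(frames, start=1):
            if multimodel:
                fh.write(f"MODEL     {i:>4d}\n")
            for atom in frame.atoms:
                fh.write(format_pdb_atom_line(atom))
            if multimodel:
                fh.write("ENDMDL\n")
        fh.write("END\n")
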