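"""Structures, trajectories, generic residue numbering, and result tables.

Coordinates are in Angstrom throughout.  Structures are read from PDB-dialect
text (``ATOM``/``HETATM`` records), trajectories from multi-model PDB files
(``MODEL``/``ENDMDL``).  Every atom carries a *role* (protein, ligand, water,
lipid, ion) assigned from configurable residue-name rules; the role drives all
downstream selections (contact analysis, water counting, SASA occluders).

Residue numbering follows the PDB sequence field verbatim (1-based, no
renumbering).  On top of it, a membrane-transporter *generic numbering* can be
assigned: the most conserved residue of each transmembrane helix (TM) is
position 50, and residue ``r`` in TM ``t`` with anchor ``a`` is labelled
``t.(50 + r - a)``; loop residues are labelled with the loop name (e.g.
``EL4``).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Role",
    "Atom",
    "Structure",
    "Trajectory",
    "NumberingMap",
    "StructureParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "assign_generic_numbers",
    "write_table",
    "ATOMIC_MASSES",
    "AMINO_ACIDS",
]


class Role(enum.Enum):
    protein = "protein"
    ligand = "ligand"
    water = "water"
    lipid = "lipid"
    ion = "ion"


#: The 20 standard amino acids (3-letter codes).
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residue names recognised without explicit rules.
DEFAULT_ROLE_RULES: dict[str, frozenset[str]] = {
    "water": frozenset({"HOH", "TIP3", "WAT", "SOL", "SPC", "TIP"}),
    "ion": frozenset({"NA", "SOD", "CL", "CLA", "K", "POT", "ZN", "MG", "CA2"}),
    "lipid": frozenset({"POPC", "POPE", "DPPC", "DMPC", "LIP"}),
    "ligand": frozenset({"LDA", "DOP", "LIG"}),
}

#: Standard atomic masses (u) for center-of-mass calculations.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "NA": 22.990, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "ZN": 65.38, "FE": 55.845, "BR": 79.904,
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Atom:
    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str
    role: Role
    coord: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.atom_id}: coordinate must be a finite 3-vector")


class Structure:
    """An ordered collection of atoms with role tags and an optional box."""

    def __init__(self, atoms: Sequence[Atom], box: np.ndarray | None = None,
                 allow_empty: bool = False):
        if len(atoms) == 0 and not allow_empty:
            raise ValueError("a Structure must contain at least one atom")
        self.atoms: list[Atom] = list(atoms)
        self.box = None if box is None else np.asarray(box, dtype=float)
        seen_ids = set()
        resnames: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            if a.atom_id in seen_ids:
                raise ValueError(f"duplicate atom_id {a.atom_id}")
            seen_ids.add(a.atom_id)
            key = (a.chain, a.residue_id)
            if resnames.setdefault(key, a.residue_name) != a.residue_name:
                raise ValueError(
                    f"residue {a.residue_id} chain {a.chain!r} maps to multiple residue names"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [dataclasses.replace(a, coord=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, box=self.box)

    # ---- selections (atom index arrays) -------------------------------

    def indices(
        self,
        role: Role | None = None,
        residue_id: int | None = None,
        residue_ids: Iterable[int] | None = None,
        chain: str | None = None,
        atom_name: str | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        wanted_res = None if residue_ids is None else set(residue_ids)
        out = []
        for i, a in enumerate(self.atoms):
            if role is not None and a.role is not role:
                continue
            if residue_id is not None and a.residue_id != residue_id:
                continue
            if wanted_res is not None and a.residue_id not in wanted_res:
                continue
            if chain is not None and a.chain != chain:
                continue
            if atom_name is not None and a.name != atom_name:
                continue
            if heavy_only and a.element.upper() == "H":
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    def residue_ids(self, role: Role = Role.protein) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.role is role:
                seen.setdefault(a.residue_id, None)
        return list(seen)

    def atom_index(self, atom_id: int) -> int:
        for i, a in enumerate(self.atoms):
            if a.atom_id == atom_id:
                return i
        raise KeyError(f"atom_id {atom_id} not found")


@dataclass
class Trajectory:
    """Frame-indexed coordinate sets over a fixed topology.

    ``frames`` is a list of (n_atoms, 3) arrays; ``frame_times`` in ps,
    strictly increasing.
    """

    topology: Structure
    frames: list[np.ndarray]
    frame_times: list[float]

    def __post_init__(self) -> None:
        n = len(self.topology)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {k}: expected {n} atoms, got {f.shape[0]}")
        t = np.asarray(self.frame_times, dtype=float)
        if len(t) != len(self.frames):
            raise ValueError("frame_times length must match number of frames")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, k: int) -> Structure:
        return self.topology.with_coords(self.frames[k])


@dataclass
class NumberingMap:
    """Generic residue labels ``T.P`` plus loop names, per the anchor-50 rule."""

    labels: dict[int, str]
    anchors: dict[str, int]

    def label(self, residue_id: int) -> str:
        return self.labels.get(residue_id, str(residue_id))


# ----------------------------------------------------------------------
# PDB-dialect reading / writing
# ----------------------------------------------------------------------

def _infer_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    # Two-letter elements only for known ions/metals; otherwise first alpha char.
    stripped = name.lstrip("0123456789")
    if residue_name.strip().upper() in DEFAULT_ROLE_RULES["ion"] and len(stripped) <= 2:
        return stripped.upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _assign_role(residue_name: str, role_rules: Mapping[str, Iterable[str]] | None) -> Role:
    rn = residue_name.strip().upper()
    rules = dict(DEFAULT_ROLE_RULES)
    if role_rules:
        for key, names in role_rules.items():
            rules[key] = frozenset(str(n).upper() for n in names) | rules.get(key, frozenset())
    for role_name in ("water", "lipid", "ligand", "ion"):
        if rn in rules.get(role_name, ()):
            return Role(role_name)
    if rn in AMINO_ACIDS:
        return Role.protein
    return Role.ion


def _parse_atom_line(line: str, lineno: int, role_rules) -> Atom:
    try:
        atom_id = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise StructureParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name, resname)
    return Atom(
        atom_id=atom_id,
        name=name,
        element=element,
        residue_id=resid,
        residue_name=resname,
        chain=chain,
        role=_assign_role(resname, role_rules),
        coord=np.array([x, y, z]),
    )


def read_structure(path: str | Path, role_rules: Mapping[str, Iterable[str]] | None = None) -> Structure:
    """Read a single-structure PDB file, assigning roles from ``role_rules``.

    ``role_rules`` maps role names (``water``/``lipid``/``ligand``/``ion``) to
    residue-name sets; built-in common names are always recognised.  Unknown
    residue names default to protein if they are standard amino acids, else ion.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_atom_line(line, lineno, role_rules))
            elif line.startswith("ENDMDL"):
                break  # single-structure read stops after the first model
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms)


def read_trajectory(
    path: str | Path,
    topology: Structure,
    dt: float,
    role_rules: Mapping[str, Iterable[str]] | None = None,
) -> Trajectory:
    """Read a multi-model PDB into a Trajectory with uniform frame spacing ``dt`` (ps)."""
    path = Path(path)
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                saw_model = True
                current = []
            elif line.startswith("ENDMDL"):
                if current is None:
                    raise StructureParseError(f"line {lineno}: ENDMDL without MODEL")
                frames.append(np.asarray(current, dtype=float))
                current = None
            elif line.startswith(("ATOM", "HETATM")):
                atom = _parse_atom_line(line, lineno, role_rules)
                if current is None:
                    if saw_model:
                        raise StructureParseError(f"line {lineno}: coordinates outside MODEL block")
                    current = []
                    saw_model = False
                current.append(list(atom.coord))
    if current is not None and current:
        frames.append(np.asarray(current, dtype=float))
    if not frames:
        raise StructureParseError(f"{path}: no coordinate frames found")
    n = len(topology)
    for k, f in enumerate(frames, start=1):
        if f.shape[0] != n:
            raise StructureParseError(
                f"model {k}: expected {n} atoms matching topology, found {f.shape[0]}"
            )
    times = [dt * k for k in range(len(frames))]
    return Trajectory(topology=topology, frames=frames, frame_times=times)


_PDB_FMT = (
    "{rec:<6}{serial:>5} {name:<4}{resname:>4}{chain:>2}{resid:>4}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}\n"
)


def _format_atom(a: Atom, coord: np.ndarray) -> str:
    rec = "ATOM" if a.role is Role.protein else "HETATM"
    name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
    return _PDB_FMT.format(
        rec=rec, serial=a.atom_id % 100000, name=name, resname=a.residue_name,
        chain=a.chain, resid=a.residue_id % 10000,
        x=coord[0], y=coord[1], z=coord[2], occ=1.0, b=0.0, element=a.element[:2],
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in structure.atoms:
            fh.write(_format_atom(a, a.coord))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {k:>4}\n")
            for a, c in zip(traj.topology.atoms, frame):
                fh.write(_format_atom(a, c))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ----------------------------------------------------------------------
# Generic numbering
# ----------------------------------------------------------------------

def assign_generic_numbers(
    structure: Structure,
    tm_ranges: Mapping[str, tuple[int, int]],
    anchors: Mapping[str, int],
    loops: Mapping[str, tuple[int, int]] | None = None,
) -> NumberingMap:
    """Assign ``T.P`` generic labels from TM ranges and position-50 anchors.

    ``tm_ranges`` maps a TM name (e.g. ``"1"``) to an inclusive residue-id
    range; ``anchors[t]`` is the residue assigned position 50 in TM ``t``.
    ``loops`` maps loop names (e.g. ``"EL4"``) to ranges; loop residues are
    labelled with the loop name.
    """
    labels: dict[int, str] = {}
    for tm, (lo, hi) in tm_ranges.items():
        if tm not in anchors:
            raise ValueError(f"TM {tm!r} has no numbering anchor")
        a = anchors[tm]
        if not (lo <= a <= hi):
            raise ValueError(f"anchor {a} for TM {tm!r} lies outside its range {lo}-{hi}")
        for r in range(lo, hi + 1):
            labels[r] = f"{tm}.{50 + r - a}"
    if loops:
        for name, (lo, hi) in loops.items():
            for r in range(lo, hi + 1):
                labels.setdefault(r, name)
    return NumberingMap(labels=labels, anchors=dict(anchors))


# ----------------------------------------------------------------------
# Result tables
# ----------------------------------------------------------------------

def _format_value(name: str, value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        lname = name.lower()
        if "fraction" in lname or "percentage" in lname or lname.endswith("_pct"):
            return str(int(round(value * 100)))  # percentages as integers 0-100
        if "deg" in lname or "angle" in lname or "bend" in lname or "shift" in lname:
            return f"{value:.1f}"
        return f"{value:.3f}"
    return str(value)


def write_table(
    records: Sequence,
    path: str | Path,
    provenance: Mapping[str, str] | None = None,
    record_type: type | None = None,
) -> None:
    """Write homogeneous result records as a TSV table with a header row.

    Fractions are rendered as integer percentages 0-100 and angles to one
    decimal, mirroring the published table layout.  Optional ``provenance``
    key/value pairs are written as ``#``-prefixed header lines.  For an empty
    record list, ``record_type`` supplies the schema for the header row.
    """
    records = list(records)
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError(f"heterogeneous record kinds: {sorted(k.__name__ for k in kinds)}")
    if records:
        record_type = type(records[0])
    if record_type is None or not dataclasses.is_dataclass(record_type):
        raise ValueError("records must be dataclasses sharing one schema")
    names = [f.name for f in dataclasses.fields(record_type)]
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(names) + "\n")
        for r in records:
            row = [_format_value(n, getattr(r, n)) for n in names]
            fh.write("\t".join(row) + "\n")
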