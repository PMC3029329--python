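"""Pairwise nonbonded (Coulomb + Lennard-Jones) group-group interaction energies.

The per-pair energy uses the CHARMM-style functional form

    E(r) = C q1 q2 / r + eps_ij [ (rmin_ij / r)^12 - 2 (rmin_ij / r)^6 ]

with C = 332.0636 kcal A / (mol e^2), dielectric 1, and Lorentz-Berthelot
combination eps_ij = sqrt(eps_i eps_j), rmin_ij = (rmin/2)_i + (rmin/2)_j.
Group-group energies sum every cross-group pair; no cutoff, switching
function, or periodic images are applied by default (metadata records the
convention).  Parameters come from a plain-text file, one atom type per line:
``TYPE charge epsilon rmin_half``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import Structure, Trajectory

__all__ = [
    "COULOMB_CONST",
    "AtomType",
    "NonbondedParams",
    "EnergySeries",
    "pair_energy",
    "group_interaction_energy",
    "energy_series",
    "builtin_test_params",
]

#: Coulomb constant, kcal*A/(mol*e^2).
COULOMB_CONST = 332.0636


@dataclass(frozen=True)
class AtomType:
    name: str
    charge: float      # e
    epsilon: float     # kcal/mol, >= 0
    rmin_half: float   # A, > 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"type {self.name}: epsilon must be >= 0")
        if self.rmin_half <= 0:
            raise ValueError(f"type {self.name}: rmin/2 must be > 0")


@dataclass
class NonbondedParams:
    """Atom types plus a (residue_name, atom_name) -> type assignment."""

    types: dict[str, AtomType]
    assignment: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "NonbondedParams":
        types = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"line {lineno}: expected 'TYPE charge epsilon rmin_half'")
                name, q, eps, rh = parts
                types[name] = AtomType(name, float(q), float(eps), float(rh))
        return cls(types=types)

    def type_of(self, structure: Structure, atom_index: int) -> AtomType:
        a = structure.atoms[atom_index]
        key = (a.residue_name, a.name)
        tname = self.assignment.get(key)
        if tname is None:
            raise ValueError(f"no atom type assigned for residue {a.residue_name} atom {a.name}")
        return self.types[tname]


@dataclass
class EnergySeries:
    energies: np.ndarray      # kcal/mol per frame
    running_mean: np.ndarray
    frame_times: np.ndarray
    group_a: np.ndarray
    group_b: np.ndarray


def pair_energy(r: float, q1: float, q2: float, eps_ij: float, rmin_ij: float) -> float:
    """Coulomb + LJ energy (kcal/mol) of one atom pair at distance ``r`` (A)."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    s = rmin_ij / r
    return COULOMB_CONST * q1 * q2 / r + eps_ij * (s**12 - 2.0 * s**6)


def _group_params(structure: Structure, group: np.ndarray, params: NonbondedParams):
    q = np.empty(group.size)
    eps = np.empty(group.size)
    rh = np.empty(group.size)
    for k, i in enumerate(group):
        t = params.type_of(structure, int(i))
        q[k], eps[k], rh[k] = t.charge, t.epsilon, t.rmin_half
    return q, eps, rh


def group_interaction_energy(
    frame: np.ndarray,
    structure: Structure,
    group_a: np.ndarray,
    group_b: np.ndarray,
    params: NonbondedParams,
    cutoff: float | None = None,
) -> float:
    """Sum of pair energies over all cross-group pairs (kcal/mol).

    ``group_a``/``group_b`` are disjoint atom-index arrays into ``structure``;
    ``frame`` supplies the coordinates.  ``cutoff`` (A), if given, drops pairs
    beyond it; ``None`` sums every pair.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if group_a.size == 0 or group_b.size == 0:
        return 0.0
    frame = np.asarray(frame, dtype=float)
    qa, ea, ra = _group_params(structure, group_a, params)
    qb, eb, rb = _group_params(structure, group_b, params)
    d = cdist(frame[group_a], frame[group_b])
    if np.any(d <= 0):
        raise ValueError("coincident atoms across groups")
    eps_ij = np.sqrt(np.outer(ea, eb))
    rmin_ij = ra[:, None] + rb[None, :]
    s6 = (rmin_ij / d) ** 6
    e = COULOMB_CONST * np.outer(qa, qb) / d + eps_ij * (s6**2 - 2.0 * s6)
    if cutoff is not None and math.isfinite(cutoff):
        e = np.where(d <= cutoff, e, 0.0)
    return float(e.sum())


def energy_series(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    params: NonbondedParams,
    cutoff: float | None = None,
    mean_window: int = 1,
) -> EnergySeries:
    """Per-frame group-group interaction energy with a running mean."""
    if mean_window < 1:
        raise ValueError("mean_window must be >= 1")
    e = np.array(
        [
            group_interaction_energy(traj.frames[f], traj.topology, group_a, group_b, params, cutoff)
            for f in range(traj.n_frames)
        ]
    )
    if mean_window == 1:
        rm = e.copy()
    else:
        kernel = np.ones(mean_window)
        rm = np.convolve(e, kernel, mode="same") / np.convolve(np.ones_like(e), kernel, mode="same")
    return EnergySeries(
        energies=e,
        running_mean=rm,
        frame_times=np.asarray(traj.frame_times),
        group_a=np.asarray(group_a, dtype=int),
        group_b=np.asarray(group_b, dtype=int),
    )


def builtin_test_params() -> NonbondedParams:
    """Small built-in parameter set: TIP3P-like water plus a neutral dummy ligand."""
    types = {
        "OT": AtomType("OT", -0.834, 0.1521, 1.7682),
        "HT": AtomType("HT", 0.417, 0.0460, 0.2245),
        "LC": AtomType("LC", 0.0, 0.0550, 2.0000),
    }
    p = NonbondedParams(types=types)
    p.assignment.update({
        ("HOH", "O"): "OT", ("HOH", "H1"): "HT", ("HOH", "H2"): "HT",
        ("TIP3", "OH2"): "OT", ("TIP3", "H1"): "HT", ("TIP3", "H2"): "HT",
        ("LIG", "C1"): "LC", ("LIG", "C2"): "LC", ("LIG", "C3"): "LC",
        ("LIG", "C4"): "LC", ("LIG", "C5"): "LC",
    })
    return p
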