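"""Dihedral angles, rotamer states, and rank statistics for torsion series.

Torsions are signed per the IUPAC convention and reported in degrees on
``(-180, 180]``.  Side-chain chi1/chi2 rotamer states use the standard
g+ / t / g- partition around +60, 180, -60 degrees.  Correlation between two
angle series uses Spearman's rank coefficient computed on mid-ranks; angle
series are unwrapped (+/-360 corrections at jumps larger than 180 degrees)
before ranking so that a physical rotation crossing the +/-180 seam is not
read as a rank reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .model_io import Structure, Trajectory

__all__ = [
    "DihedralSeries",
    "RotamerStateSeries",
    "dihedral",
    "dihedral_series",
    "rotamer_states",
    "spearman_rho",
    "permutation_pvalue",
    "wrap_angle",
    "unwrap_degrees",
]


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    w = np.asarray(a, dtype=float)
    w = ((w + 180.0) % 360.0) - 180.0
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    return float(w) if w.ndim == 0 else w


def unwrap_degrees(series: np.ndarray) -> np.ndarray:
    """Remove +/-360-degree jumps so the series varies continuously."""
    return np.degrees(np.unwrap(np.radians(np.asarray(series, dtype=float))))


@dataclass
class DihedralSeries:
    residue_id: int
    angle_name: str  # phi, psi, chi1 or chi2
    values: np.ndarray  # degrees, (-180, 180]
    frame_times: np.ndarray  # ps

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must have equal length")


@dataclass
class RotamerStateSeries:
    states: list[str]  # "g+", "t", "g-"
    boundaries: tuple[float, float]  # (0, 120) convention


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (deg) of the four points, IUPAC sign convention.

    Raises ``ValueError`` when three consecutive points are collinear (the
    torsion is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("collinear points: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2n)
    return wrap_angle(math.degrees(math.atan2(y, x)))


# Atom quadruples per angle; chi names allow the common gamma/delta variants.
_CHI1_G = ("CG", "CG1", "OG", "OG1", "SG")
_CHI2_D = ("CD", "CD1", "SD", "OD1", "ND1")


def _find_atom(struct: Structure, residue_id: int, names: tuple[str, ...] | str) -> int:
    if isinstance(names, str):
        names = (names,)
    for nm in names:
        idx = struct.indices(residue_id=residue_id, atom_name=nm)
        if idx.size:
            return int(idx[0])
    raise ValueError(f"residue {residue_id}: missing atom {'/'.join(names)}")


def _quad_indices(struct: Structure, residue_id: int, angle_name: str) -> list[int]:
    r = residue_id
    if angle_name == "phi":
        return [
            _find_atom(struct, r - 1, "C"),
            _find_atom(struct, r, "N"),
            _find_atom(struct, r, "CA"),
            _find_atom(struct, r, "C"),
        ]
    if angle_name == "psi":
        return [
            _find_atom(struct, r, "N"),
            _find_atom(struct, r, "CA"),
            _find_atom(struct, r, "C"),
            _find_atom(struct, r + 1, "N"),
        ]
    if angle_name == "chi1":
        return [
            _find_atom(struct, r, "N"),
            _find_atom(struct, r, "CA"),
            _find_atom(struct, r, "CB"),
            _find_atom(struct, r, _CHI1_G),
        ]
    if angle_name == "chi2":
        return [
            _find_atom(struct, r, "CA"),
            _find_atom(struct, r, "CB"),
            _find_atom(struct, r, _CHI1_G),
            _find_atom(struct, r, _CHI2_D),
        ]
    raise ValueError(f"unknown angle name {angle_name!r}")


def dihedral_series(
    traj: Trajectory,
    residue_id: int,
    angle_name: str,
    stride: int = 1,
) -> DihedralSeries:
    """Per-frame phi/psi/chi1/chi2 series for one residue, at frame ``stride``."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    try:
        quad = _quad_indices(traj.topology, residue_id, angle_name)
    except ValueError as exc:
        # terminal residues lack the i-1 / i+1 neighbor needed for phi / psi
        raise ValueError(str(exc)) from exc
    values, times = [], []
    for k in range(0, traj.n_frames, stride):
        f = traj.frames[k]
        values.append(dihedral(*(f[i] for i in quad)))
        times.append(traj.frame_times[k])
    return DihedralSeries(
        residue_id=residue_id,
        angle_name=angle_name,
        values=np.asarray(values),
        frame_times=np.asarray(times),
    )


def rotamer_states(series: DihedralSeries, boundaries: tuple[float, float] = (0.0, 120.0)) -> RotamerStateSeries:
    """Assign g+/t/g- states: (0,120] -> g+, (120,180] u (-180,-120] -> t, (-120,0] -> g-."""
    lo, hi = boundaries
    states = []
    for v in series.values:
        if lo < v <= hi:
            states.append("g+")
        elif v > hi or v <= -hi:
            states.append("t")
        else:
            states.append("g-")
    return RotamerStateSeries(states=states, boundaries=boundaries)


def spearman_rho(x, y, unwrap: bool = True) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, ties averaged).

    Angle series are unwrapped before ranking by default.  A constant series
    has no defined rank correlation; NaN is returned (never 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("at least 3 observations are required")
    if unwrap:
        x = unwrap_degrees(x)
        y = unwrap_degrees(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def permutation_pvalue(x, y, n_perm: int = 10_000, seed: int = 0, unwrap: bool = True) -> float:
    """Two-sided permutation p-value for ``spearman_rho`` (seeded, optional)."""
    rng = np.random.default_rng(seed)
    x = unwrap_degrees(x) if unwrap else np.asarray(x, dtype=float)
    y = unwrap_degrees(y) if unwrap else np.asarray(y, dtype=float)
    obs = spearman_rho(x, y, unwrap=False)
    if math.isnan(obs):
        return math.nan
    count = 0
    for _ in range(n_perm):
        rho = spearman_rho(x, rng.permutation(y), unwrap=False)
        if abs(rho) >= abs(obs) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
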