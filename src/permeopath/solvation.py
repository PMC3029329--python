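"""Water-penetration profiles and solvent-accessible surface area.

Water profiles count water oxygens in bins along the membrane normal (z; the
convention is z = 0 at the membrane center), averaged over selected late
frames of an aligned trajectory, optionally restricted to a lateral cylinder
around the permeation pathway.

SASA uses the Shrake-Rupley sphere-point quadrature with Bondi van der Waals
radii, a 1.4 A water probe, and a Fibonacci point set: a quadrature point on
atom i's probe-inflated sphere is accessible iff it lies outside the
probe-inflated sphere of every occluding atom.  Occluders are all protein and
ligand atoms plus the configured roles (lipids by default, so membrane-facing
surface counts as buried); waters never occlude.  Per-residue SASA fractions
are normalized by the same residue type's SASA in an extended (phi = psi =
180 deg) Gly-X-Gly tripeptide computed with the same engine, which keeps the
fractions internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .model_io import Atom, Role, Structure, Trajectory
from .superpose import kabsch_fit

__all__ = [
    "WaterProfile",
    "SASASeries",
    "water_profile",
    "shrake_rupley_sasa",
    "gly_x_gly_reference",
    "residue_sasa_series",
    "BONDI_RADII",
]

#: Bondi van der Waals radii (A).
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "NA": 2.27, "K": 2.75, "ZN": 1.39,
    "MG": 1.73, "CA": 2.31, "SE": 1.90,
}

PROBE_RADIUS_A = 1.4
N_QUADRATURE_POINTS = 960


@dataclass
class WaterProfile:
    bin_edges: np.ndarray  # A, along z
    mean_counts: np.ndarray  # per bin, averaged over frames
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class SASASeries:
    residue_id: int
    sasa: np.ndarray      # A^2 per frame
    fraction: np.ndarray  # sasa / Gly-X-Gly reference
    frame_times: np.ndarray


def water_profile(
    traj: Trajectory,
    bin_width: float = 1.0,
    z_range: tuple[float, float] = (-30.0, 30.0),
    last: float | None = None,
    every: float | None = None,
    region: tuple[float, float, float] | None = None,
) -> WaterProfile:
    """Mean water-oxygen count per z bin over the selected frames.

    ``last`` keeps only the final ``last`` ps of the trajectory and ``every``
    subsamples it (ps); ``region`` = (cx, cy, radius) restricts counting to a
    lateral cylinder.  The trajectory should already be aligned to a common
    reference (see ``superpose.align_trajectory``).
    """
    t = np.asarray(traj.frame_times)
    keep = np.arange(traj.n_frames)
    if last is not None:
        keep = keep[t[keep] >= t[-1] - last]
    if every is not None and keep.size > 1:
        dt = t[keep[1]] - t[keep[0]]
        keep = keep[:: max(1, int(round(every / dt)))]
    if keep.size == 0:
        raise ValueError("no frames selected for the water profile")

    wat_o = np.asarray(
        [
            i
            for i, a in enumerate(traj.topology.atoms)
            if a.role is Role.water and a.element.upper() == "O"
        ],
        dtype=int,
    )
    lo, hi = z_range
    nbins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts = np.zeros(nbins)
    for f in keep:
        if wat_o.size == 0:
            continue
        xyz = traj.frames[f][wat_o]
        if region is not None:
            cx, cy, rad = region
            lateral = np.hypot(xyz[:, 0] - cx, xyz[:, 1] - cy) <= rad
            xyz = xyz[lateral]
        hist, _ = np.histogram(xyz[:, 2], bins=edges)
        counts += hist
    return WaterProfile(bin_edges=edges, mean_counts=counts / keep.size, n_frames=int(keep.size))


@lru_cache(maxsize=8)
def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit sphere points (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radius(element: str) -> float:
    try:
        return BONDI_RADII[element.upper()]
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {element!r}") from exc


def shrake_rupley_sasa(
    structure: Structure,
    probe: float = PROBE_RADIUS_A,
    n_points: int = N_QUADRATURE_POINTS,
    occluders: frozenset[Role] = frozenset({Role.lipid, Role.ion}),
) -> np.ndarray:
    """Per-atom SASA (A^2) for protein and ligand atoms.

    Atoms of other roles get SASA 0.  Occluding atoms are protein + ligand +
    the roles in ``occluders`` (waters are never occluders, so their volume
    counts as solvent).
    """
    atoms = structure.atoms
    coords = structure.coords
    compute = np.array([a.role in (Role.protein, Role.ligand) for a in atoms])
    occlude = np.array(
        [a.role in (Role.protein, Role.ligand) or a.role in occluders for a in atoms]
    )
    radii = np.array([_radius(a.element) if (compute[i] or occlude[i]) else 1.5
                      for i, a in enumerate(atoms)])
    occ_idx = np.flatnonzero(occlude)
    if occ_idx.size == 0:
        return np.zeros(len(atoms))
    tree = cKDTree(coords[occ_idx])
    max_r = radii[occ_idx].max()
    pts = _fibonacci_sphere(n_points)

    out = np.zeros(len(atoms))
    for i in np.flatnonzero(compute):
        ri = radii[i] + probe
        neigh = occ_idx[tree.query_ball_point(coords[i], ri + max_r + probe)]
        neigh = neigh[neigh != i]
        sphere = coords[i] + ri * pts
        if neigh.size:
            d2 = np.sum((sphere[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (radii[neigh] + probe) ** 2, axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        out[i] = 4.0 * math.pi * ri**2 * accessible / n_points
    return out


# ----------------------------------------------------------------------
# Extended Gly-X-Gly reference
# ----------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Next chain atom from bond length, bond angle at ``c`` and torsion a-b-c-new."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor), bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _extended_backbone(n_res: int = 3) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """(N, CA, C) coordinates per residue for an all-trans extended chain."""
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c1 = ca1 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    chain = [n1, ca1, c1]
    specs = [(_BOND_C_N, _ANG_CA_C_N), (_BOND_N_CA, _ANG_C_N_CA), (_BOND_CA_C, _ANG_N_CA_C)]
    while len(chain) < 3 * n_res:
        bond, angle = specs[len(chain) % 3]
        chain.append(_place_atom(chain[-3], chain[-2], chain[-1], bond, angle, 180.0))
    return [(chain[3 * i], chain[3 * i + 1], chain[3 * i + 2]) for i in range(n_res)]


def _residue_template(resname: str):
    """Idealized heavy-atom coordinates for one residue from biotite's CCD set."""
    from biotite.structure.info import residue as ccd_residue

    arr = ccd_residue(resname)
    if arr is None:
        raise ValueError(f"no idealized template for residue {resname!r}")
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    arr = arr[keep]
    return list(arr.atom_name), arr.coord.astype(float)


def _build_gxg(resname: str) -> Structure:
    backbone = _extended_backbone(3)
    names3 = ["GLY", resname.upper(), "GLY"]
    atoms: list[Atom] = []
    serial = 1
    for i, rn in enumerate(names3):
        names, coords = _residue_template(rn)
        try:
            tmpl_bb = np.array([coords[names.index(nm)] for nm in ("N", "CA", "C")])
        except ValueError as exc:
            raise ValueError(f"{rn}: template lacks backbone atoms") from exc
        target = np.asarray(backbone[i])
        rot, trans, _ = kabsch_fit(tmpl_bb, target)
        placed = coords @ rot.T + trans
        for nm, xyz in zip(names, placed):
            el = nm[0] if nm[0].isalpha() else nm[1]
            atoms.append(Atom(serial, nm, el, i + 1, rn, "A", Role.protein, xyz))
            serial += 1
    return Structure(atoms)


@lru_cache(maxsize=32)
def gly_x_gly_reference(
    residue_type: str,
    probe: float = PROBE_RADIUS_A,
    n_points: int = N_QUADRATURE_POINTS,
) -> float:
    """SASA (A^2) of residue X inside an extended Gly-X-Gly tripeptide.

    Values are computed with the package's own Shrake-Rupley engine and
    cached, so per-residue fractions are internally consistent.
    """
    rn = residue_type.upper()
    from .model_io import AMINO_ACIDS

    if rn not in AMINO_ACIDS:
        raise ValueError(f"{residue_type!r} is not a standard amino acid")
    gxg = _build_gxg(rn)
    sasa = shrake_rupley_sasa(gxg, probe=probe, n_points=n_points)
    mid = gxg.indices(residue_id=2)
    return float(sasa[mid].sum())


def residue_sasa_series(
    traj: Trajectory,
    residues: list[int],
    probe: float = PROBE_RADIUS_A,
    n_points: int = N_QUADRATURE_POINTS,
    occluders: frozenset[Role] = frozenset({Role.lipid, Role.ion}),
) -> list[SASASeries]:
    """Per-frame per-residue SASA and Gly-X-Gly fraction for ``residues``."""
    topo = traj.topology
    res_idx = {}
    res_ref = {}
    for rid in residues:
        idx = topo.indices(residue_id=rid, role=Role.protein)
        if idx.size == 0:
            raise ValueError(f"residue {rid} not found")
        res_idx[rid] = idx
        res_ref[rid] = gly_x_gly_reference(topo.atoms[int(idx[0])].residue_name,
                                           probe=probe, n_points=n_points)
    per_res = {rid: [] for rid in residues}
    for f in range(traj.n_frames):
        sasa = shrake_rupley_sasa(traj.frame_structure(f), probe=probe,
                                  n_points=n_points, occluders=occluders)
        for rid in residues:
            per_res[rid].append(float(sasa[res_idx[rid]].sum()))
    times = np.asarray(traj.frame_times)
    out = []
    for rid in residues:
        s = np.asarray(per_res[rid])
        out.append(SASASeries(residue_id=rid, sasa=s, fraction=s / res_ref[rid], frame_times=times))
    return out
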