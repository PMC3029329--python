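"""Synthetic structures and trajectories with known ground truth.

Every analysis stage in the package is exercised against constructions whose
answer is known by design: ideal alpha-helices with imposed kinks of chosen
bend and face shift, ligands whose residue contacts are scripted frame by
frame, water slabs with exact per-bin counts, two-domain ensembles with a
rigid core and a hinge-rotated arm, and coupled dihedral series with designed
monotone relationships.  All generators are deterministic given their seed and
never emit non-finite coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .model_io import Atom, Role, Structure, Trajectory
from .torsions import DihedralSeries, wrap_angle

__all__ = [
    "KinkSpec",
    "build_ideal_helix",
    "impose_kink",
    "make_spaced_residue_protein",
    "make_scripted_ligand_trajectory",
    "make_water_slab",
    "make_two_domain_ensemble",
    "make_coupled_dihedral_series",
    "rotation_about_axis",
]

_GOLDEN = 0.6180339887498949


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, Rodrigues form."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    k = axis / n
    t = math.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(t) * kx + (1 - math.cos(t)) * (kx @ kx)


@dataclass
class KinkSpec:
    """Ground truth for an imposed helix kink at ``pivot`` (residue id)."""

    pivot: int
    bend_deg: float
    face_shift_deg: float

    def __post_init__(self) -> None:
        if not (0 <= self.bend_deg < 180):
            raise ValueError("bend_deg must lie in [0, 180)")
        self.face_shift_deg = wrap_angle(self.face_shift_deg)


def build_ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    residue_name: str = "ALA",
    chain: str = "A",
    first_residue_id: int = 1,
    with_cb: bool = False,
) -> Structure:
    """Ideal alpha-helix along +z: CA plus idealized N and C backbone atoms.

    Consecutive CA-CA distances are constant by construction.  ``with_cb``
    adds a CB atom pointing outward (useful for SASA and chi fixtures).
    """
    if n_res < 8:
        raise ValueError("an ideal helix needs at least 8 residues")
    atoms: list[Atom] = []
    serial = 1
    for i in range(n_res):
        rid = first_residue_id + i
        th = math.radians(twist * i)
        z = rise * i
        ca = np.array([radius * math.cos(th), radius * math.sin(th), z])
        # idealized backbone neighbors: smaller radius, offset in phase and z
        th_n = th - math.radians(26.0)
        th_c = th + math.radians(26.0)
        n_at = np.array([1.65 * math.cos(th_n), 1.65 * math.sin(th_n), z - 0.9])
        c_at = np.array([1.65 * math.cos(th_c), 1.65 * math.sin(th_c), z + 0.9])
        for name, el, coord in (("N", "N", n_at), ("CA", "C", ca), ("C", "C", c_at)):
            atoms.append(Atom(serial, name, el, rid, residue_name, chain, Role.protein, coord))
            serial += 1
        if with_cb:
            cb = np.array([(radius + 1.5) * math.cos(th), (radius + 1.5) * math.sin(th), z])
            atoms.append(Atom(serial, "CB", "C", rid, residue_name, chain, Role.protein, cb))
            serial += 1
    return Structure(atoms)


def impose_kink(helix: Structure, spec: KinkSpec) -> Structure:
    """Rigidly kink a +z ideal helix after ``spec.pivot``.

    Residues beyond the pivot are rotated by ``bend_deg`` about an axis
    perpendicular to the pre-pivot (+z) axis through the pivot CA, then by
    ``face_shift_deg`` about the bent image of the helix central axis, so the
    two ground truths are independently controllable.  Pre-pivot atoms (and
    the pivot residue itself) are unchanged; all intra-segment distances are
    preserved exactly (rigid motion).
    """
    resids = sorted({a.residue_id for a in helix.atoms})
    if spec.pivot not in resids:
        raise ValueError(f"pivot residue {spec.pivot} not in helix")
    k = resids.index(spec.pivot)
    if k < 6 or k > len(resids) - 7:
        raise ValueError("pivot must be at least 6 residues from either terminus")
    ca_idx = helix.indices(residue_id=spec.pivot, atom_name="CA")
    pivot_ca = helix.atoms[int(ca_idx[0])].coord

    bend_axis = np.array([1.0, 0.0, 0.0])  # perpendicular to the +z pre axis
    r_bend = rotation_about_axis(bend_axis, spec.bend_deg)
    # image of the helix central axis (the z-axis line) under the bend
    axis_point = pivot_ca + r_bend @ (np.array([0.0, 0.0, pivot_ca[2]]) - pivot_ca)
    axis_dir = r_bend @ np.array([0.0, 0.0, 1.0])
    r_face = rotation_about_axis(axis_dir, spec.face_shift_deg)

    coords = helix.coords
    post = np.array([a.residue_id > spec.pivot for a in helix.atoms])
    moved = coords[post]
    moved = pivot_ca + (moved - pivot_ca) @ r_bend.T
    moved = axis_point + (moved - axis_point) @ r_face.T
    out = coords.copy()
    out[post] = moved
    return helix.with_coords(out)


def make_spaced_residue_protein(
    n_residues: int,
    spacing: float = 20.0,
    residue_name: str = "ALA",
) -> Structure:
    """Well-separated dummy residues on a line; each has 3 heavy atoms.

    Residue separation much larger than any contact cutoff guarantees that a
    ligand in contact with one residue is far from all others, which makes
    scripted-contact trajectories exactly realizable.
    """
    atoms = []
    serial = 1
    for i in range(n_residues):
        rid = i + 1
        base = np.array([0.0, 0.0, spacing * i])
        for name, off in (
            ("N", [0.8, -0.9, 0]),
            ("CA", [0, 0, 0]),
            ("CB", [1.0, 0.8, 0.3]),
            ("CG", [-1.0, 0.8, -0.3]),
        ):
            el = "N" if name == "N" else "C"
            atoms.append(
                Atom(serial, name, el, rid, residue_name, "A", Role.protein, base + np.asarray(off, float))
            )
            serial += 1
    return Structure(atoms)


_LIGAND_LOCAL = np.array(
    [
        [0.0, 0.0, 0.0],     # tip: the designated contact atom
        [1.4, 0.0, 0.0],
        [2.8, 0.0, 0.0],
        [1.4, 1.2, 0.0],
        [1.4, -1.2, 0.0],
    ]
)


def _ligand_atoms(start_serial: int) -> list[Atom]:
    return [
        Atom(start_serial + i, f"C{i + 1}", "C", 9999, "LIG", "L", Role.ligand, c)
        for i, c in enumerate(_LIGAND_LOCAL)
    ]


def _orient_ligand(tip_pos: np.ndarray, away: np.ndarray) -> np.ndarray:
    """Ligand coordinates with the tip at ``tip_pos`` and body extending along ``away``."""
    d = away / np.linalg.norm(away)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(d, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(d, e2)
    rot = np.column_stack([d, e2, e3])
    return tip_pos + _LIGAND_LOCAL @ rot.T


def make_scripted_ligand_trajectory(
    protein: Structure,
    script: Mapping[int, set[int]],
    n_frames: int,
    cutoff: float = 3.5,
    dt: float = 10.0,
) -> Trajectory:
    """Trajectory whose ligand-residue contacts follow ``script`` exactly.

    ``script`` maps residue ids to the frame indices in which the ligand must
    lie within ``cutoff`` of that residue.  In a scripted frame the ligand's
    nearest heavy atom sits at ``cutoff - 0.5`` A from the residue; in every
    other frame the ligand is at least ``cutoff + 2`` A away from it.  Raises
    on geometrically unsatisfiable scripts.
    """
    resids = set(protein.residue_ids(Role.protein))
    for rid, frames in script.items():
        if rid not in resids:
            raise ValueError(f"scripted residue {rid} not in protein")
        bad = [f for f in frames if not (0 <= f < n_frames)]
        if bad:
            raise ValueError(f"residue {rid}: frame indices {bad} outside [0, {n_frames})")

    frame_residues: dict[int, list[int]] = {f: [] for f in range(n_frames)}
    for rid, frames in script.items():
        for f in frames:
            frame_residues[f].append(rid)

    res_coords = {
        rid: protein.coords[protein.indices(residue_id=rid, heavy_only=True)]
        for rid in resids
    }
    centroid = protein.coords.mean(axis=0)
    park = protein.coords.max(axis=0) + 100.0

    ligand = _ligand_atoms(max(a.atom_id for a in protein.atoms) + 1)
    topo = Structure(list(protein.atoms) + ligand)
    prot_xyz = protein.coords

    frames_out = []
    for f in range(n_frames):
        targets = sorted(frame_residues[f])
        if not targets:
            lig = _LIGAND_LOCAL + park
        elif len(targets) == 1:
            rid = targets[0]
            rc = res_coords[rid]
            away = rc.mean(axis=0) - centroid
            if np.linalg.norm(away) < 1e-9:
                away = np.array([0.0, 0.0, 1.0])
            away = away / np.linalg.norm(away)
            anchor = rc[np.argmax(rc @ away)]  # outermost residue atom
            lig = _orient_ligand(anchor + away * (cutoff - 0.5), away)
        else:
            for i, ra in enumerate(targets):
                for rb in targets[i + 1:]:
                    d = np.min(
                        np.linalg.norm(res_coords[ra][:, None] - res_coords[rb][None], axis=2)
                    )
                    if d > 2 * cutoff:
                        raise ValueError(
                            f"frame {f}: residues {ra} and {rb} are {d:.1f} A apart, "
                            f"farther than 2 x cutoff; script unsatisfiable"
                        )
            mid = np.mean([res_coords[r].mean(axis=0) for r in targets], axis=0)
            away = mid - centroid
            if np.linalg.norm(away) < 1e-9:
                away = np.array([0.0, 0.0, 1.0])
            lig = _orient_ligand(mid, away)
        # verify the scripted contract for this frame
        for rid in resids:
            dmin = np.min(np.linalg.norm(res_coords[rid][:, None] - lig[None], axis=2))
            if rid in targets:
                if dmin > cutoff - 1e-6:
                    raise ValueError(f"frame {f}: cannot place ligand in contact with residue {rid}")
            elif dmin < cutoff + 2.0:
                raise ValueError(
                    f"frame {f}: ligand placed for {targets} is only {dmin:.2f} A from "
                    f"unscripted residue {rid}; script unsatisfiable"
                )
        frames_out.append(np.vstack([prot_xyz, lig]))

    return Trajectory(topology=topo, frames=frames_out, frame_times=[dt * k for k in range(n_frames)])


def make_water_slab(
    bin_counts: Sequence[int],
    bin_edges: Sequence[float],
    xy_extent: float = 30.0,
) -> Structure:
    """Water oxygens with exactly ``bin_counts[k]`` in ``[edge_k, edge_k+1)``.

    Placement is deterministic (golden-ratio lateral scatter, even z spacing
    strictly inside each bin).  All-zero counts yield an empty structure.
    """
    bin_counts = list(bin_counts)
    bin_edges = [float(e) for e in bin_edges]
    if len(bin_counts) != len(bin_edges) - 1:
        raise ValueError("need len(bin_counts) == len(bin_edges) - 1")
    if any(c < 0 for c in bin_counts):
        raise ValueError("bin counts must be non-negative")
    atoms = []
    serial = 1
    rid = 1
    seq = 0
    for k, c in enumerate(bin_counts):
        lo, hi = bin_edges[k], bin_edges[k + 1]
        for i in range(c):
            x = ((seq * _GOLDEN) % 1.0 - 0.5) * xy_extent
            y = (((seq * _GOLDEN**2) % 1.0) - 0.5) * xy_extent
            z = lo + (hi - lo) * (i + 0.5) / c
            atoms.append(Atom(serial, "O", "O", rid, "HOH", "W", Role.water, np.array([x, y, z])))
            serial += 1
            rid += 1
            seq += 1
    return Structure(atoms, allow_empty=True)


def make_two_domain_ensemble(
    core_size: int,
    arm_size: int,
    n_frames: int,
    arm_rotation: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Rigid-core / hinge-rotated-arm ensemble for superposition tests.

    The topology is an ideal helix of ``core_size + arm_size`` residues; in
    frame ``f`` the arm residues are rotated by ``arm_rotation[f]`` degrees
    about a hinge through the last core CA, and isotropic Gaussian noise of
    ``noise_sigma`` A is added to every atom.  Deterministic given ``seed``.
    """
    if core_size < 5 or arm_size < 5:
        raise ValueError("core and arm must each have at least 5 residues")
    arm_rotation = list(arm_rotation)
    if len(arm_rotation) == 0:
        raise ValueError("empty arm-rotation schedule")
    if len(arm_rotation) == 1:
        arm_rotation = arm_rotation * n_frames
    if len(arm_rotation) != n_frames:
        raise ValueError("arm_rotation schedule length must equal n_frames")

    base = build_ideal_helix(core_size + arm_size)
    hinge = base.atoms[int(base.indices(residue_id=core_size, atom_name="CA")[0])].coord
    arm_mask = np.array([a.residue_id > core_size for a in base.atoms])
    coords = base.coords
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        rot = rotation_about_axis(np.array([1.0, 0.0, 0.0]), arm_rotation[f])
        frame = coords.copy()
        frame[arm_mask] = hinge + (frame[arm_mask] - hinge) @ rot.T
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
        frames.append(frame)
    return Trajectory(topology=base, frames=frames, frame_times=[10.0 * k for k in range(n_frames)])


def make_lipid_shell(
    structure: Structure,
    inner: float = 2.0,
    outer: float = 4.0,
    spacing: float = 1.8,
    margin: float = 6.0,
) -> Structure:
    """Add a dense shell of dummy lipid carbons around a structure.

    Grid points whose distance to the nearest structure atom lies in
    ``(inner, outer)`` become lipid atoms, producing a tight occluder cage for
    burial tests.  Returns a new Structure (original atoms first).
    """
    coords = structure.coords
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    axes = [np.arange(lo[k], hi[k], spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    from scipy.spatial import cKDTree

    dmin, _ = cKDTree(coords).query(grid)
    shell = grid[(dmin > inner) & (dmin < outer)]
    atoms = list(structure.atoms)
    serial = max(a.atom_id for a in atoms) + 1
    rid = max(a.residue_id for a in atoms) + 1
    for k, pos in enumerate(shell):
        atoms.append(Atom(serial + k, "C", "C", rid + k, "LIP", "M", Role.lipid, pos))
    return Structure(atoms)


def make_coupled_dihedral_series(
    n: int,
    relation: Callable[[np.ndarray], np.ndarray],
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[DihedralSeries, DihedralSeries]:
    """Two dihedral series with ``y = relation(x) + noise`` (degrees).

    With zero noise and a strictly increasing relation the Spearman rank
    correlation of the pair is exactly +1.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-90.0, 90.0, size=n)
    y = np.asarray(relation(x), dtype=float) + rng.normal(0.0, noise, size=n)
    times = 5.0 * np.arange(n)
    sx = DihedralSeries(residue_id=0, angle_name="chi1", values=wrap_angle(x), frame_times=times)
    sy = DihedralSeries(residue_id=0, angle_name="chi1", values=wrap_angle(y), frame_times=times)
    return sx, sy
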