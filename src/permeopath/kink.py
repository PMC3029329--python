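"""Helix kink geometry: bend angle and face shift around a pivot residue.

A transmembrane helix distorted at a Pro/Gly/Ser/Thr pivot is described by
two angles.  The *bend angle* is the angle between the long axes of the
pre-pivot and post-pivot helical segments.  The *face shift* measures the
rotation of the helical register across the kink: after the post segment is
rotated so the two segments share a long axis, it is the angle (in the plane
perpendicular to that axis) between where the post-segment residues actually
sit and where the pre-segment's helical phase predicts them, anchored at the
mean of the (pivot-3) and (pivot-4) C-alpha positions.

A segment's long axis is the first principal component of its C-alpha trace
after 4-point sliding-average smoothing, which suppresses the ~100 deg/residue
helical wobble; the axis is oriented N-to-C.  Both angles are invariant under
rigid motion of the whole structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_io import Structure, Trajectory
from .superpose import kabsch_fit
from .torsions import wrap_angle

__all__ = [
    "KinkSeries",
    "fit_helix_axis",
    "kink_parameters",
    "kink_series",
    "default_windows",
]

#: Default pre/post segment length (residues) around the pivot.
SEGMENT_LENGTH = 7


@dataclass
class KinkSeries:
    pivot: int
    bend_deg: np.ndarray
    face_shift_deg: np.ndarray
    bend_mean: float
    bend_std: float
    face_shift_mean: float
    face_shift_std: float


def default_windows(pivot: int, length: int = SEGMENT_LENGTH) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pre/post residue ranges: ``length`` residues ending/starting adjacent to the pivot."""
    return (pivot - length, pivot - 1), (pivot + 1, pivot + length)


def fit_helix_axis(ca_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Long axis of a helical C-alpha trace: (unit direction, centroid).

    The direction is the mean of cross products of successive second
    differences of the trace: the second difference at each residue points
    from the C-alpha toward the helix axis, so consecutive ones span the
    perpendicular plane and their cross product lies along the axis.  This is
    exact on ideal helices of any length >= 6 and insensitive to the
    ~100 deg/residue helical wobble that biases a plain principal-component
    fit on short segments.  The direction is oriented from N- to C-terminus.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("ca_coords must be an (n, 3) array")
    if ca.shape[0] < 6:
        raise ValueError("at least 6 C-alpha atoms are needed for an axis fit")
    d2 = ca[:-2] - 2.0 * ca[1:-1] + ca[2:]  # centripetal vectors
    cross = np.cross(d2[:-1], d2[1:])
    norms = np.linalg.norm(cross, axis=1)
    good = norms > 1e-9
    if not np.any(good):
        raise ValueError("degenerate (straight-line) trace: no helical axis")
    direction = (cross[good] / norms[good, None]).mean(axis=0)
    n = np.linalg.norm(direction)
    if n < 1e-9:
        raise ValueError("inconsistent curvature: no helical axis")
    direction /= n
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    return direction, ca.mean(axis=0)


def _segment_cas(structure: Structure, lo: int, hi: int) -> np.ndarray:
    coords = []
    for rid in range(lo, hi + 1):
        idx = structure.indices(residue_id=rid, atom_name="CA")
        if idx.size == 0:
            raise ValueError(f"residue {rid}: no CA atom")
        coords.append(structure.atoms[int(idx[0])].coord)
    return np.asarray(coords)


def _azimuth_phase(
    ca: np.ndarray,
    first_index: float,
    e1: np.ndarray,
    e2: np.ndarray,
    eval_index: float,
) -> float:
    """Linear fit of unwrapped C-alpha azimuths about the axis, evaluated at a residue index.

    The axis location in the (e1, e2) plane is the least-squares (Kasa)
    circle center of the projected trace, so azimuths are measured about the
    true helix axis rather than the (slightly off-axis) segment centroid.
    """
    u = np.column_stack([ca @ e1, ca @ e2])
    a = np.column_stack([2.0 * u, np.ones(len(u))])
    b = np.sum(u**2, axis=1)
    (cx, cy, _), *_ = np.linalg.lstsq(a, b, rcond=None)
    rel = u - np.array([cx, cy])
    az = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    az = np.degrees(np.unwrap(np.radians(az)))
    idx = first_index + np.arange(len(ca))
    slope, intercept = np.polyfit(idx, az, 1)
    return slope * eval_index + intercept


def kink_parameters(
    structure: Structure,
    pivot: int,
    pre_range: tuple[int, int] | None = None,
    post_range: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Bend angle [0, 180] and face shift (-180, 180] (degrees) at ``pivot``.

    ``pre_range`` / ``post_range`` are inclusive residue-id ranges flanking
    the pivot (the pivot itself belongs to neither); they default to the 7
    residues on each side.
    """
    if pre_range is None or post_range is None:
        d_pre, d_post = default_windows(pivot)
        pre_range = pre_range or d_pre
        post_range = post_range or d_post
    if pre_range[1] >= pivot or post_range[0] <= pivot:
        raise ValueError("pre range must end before the pivot and post range start after it")
    if pre_range[1] - pre_range[0] + 1 < 6 or post_range[1] - post_range[0] + 1 < 6:
        raise ValueError("pre and post segments need at least 6 residues each")

    ca_pre = _segment_cas(structure, *pre_range)
    ca_post = _segment_cas(structure, *post_range)
    u_pre, c_pre = fit_helix_axis(ca_pre)
    u_post, c_post = fit_helix_axis(ca_post)

    cosb = float(np.clip(np.dot(u_pre, u_post), -1.0, 1.0))
    bend = math.degrees(math.acos(cosb))

    # Straighten: rotate the post segment about the pivot CA so its axis
    # coincides in direction with the pre axis (minimal rotation, which
    # parallel-transports the register without adding spurious twist).
    pivot_idx = structure.indices(residue_id=pivot, atom_name="CA")
    if pivot_idx.size == 0:
        raise ValueError(f"pivot residue {pivot}: no CA atom")
    pivot_ca = structure.atoms[int(pivot_idx[0])].coord
    axis = np.cross(u_post, u_pre)
    if np.linalg.norm(axis) > 1e-12 and bend > 1e-9:
        from .synthetic import rotation_about_axis

        rot = rotation_about_axis(axis, bend)
        ca_post_s = pivot_ca + (ca_post - pivot_ca) @ rot.T
    else:
        ca_post_s = ca_post

    # Shared perpendicular frame about the pre axis.
    ref = np.array([0.0, 0.0, 1.0]) if abs(u_pre[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u_pre, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u_pre, e1)

    # The pre-segment register is anchored at the mean of the (pivot-3) and
    # (pivot-4) CA positions, i.e. the phase evaluated at index pivot - 3.5;
    # the post-segment phase is extrapolated back to the same anchor.
    eval_idx = pivot - 3.5
    phase_pre = _azimuth_phase(ca_pre, pre_range[0], e1, e2, eval_idx)
    phase_post = _azimuth_phase(ca_post_s, post_range[0], e1, e2, eval_idx)
    face_shift = wrap_angle(phase_post - phase_pre)
    return bend, float(face_shift)


def kink_series(
    traj: Trajectory,
    pivot: int,
    pre_range: tuple[int, int] | None = None,
    post_range: tuple[int, int] | None = None,
    reference: Structure | None = None,
) -> KinkSeries:
    """Per-frame kink parameters after fitting each frame onto ``reference``.

    The fit (uniform-weight, on all protein CA atoms) removes global rigid
    motion before the angles are measured; both angles are rigid-motion
    invariant anyway, so the fit mainly standardizes the reported frames.
    Mean and sample std are reported; the face-shift mean is taken after
    re-centering the series on its first value to avoid the +/-180 seam.
    """
    reference = reference or traj.frame_structure(0)
    ca_sel = traj.topology.indices(atom_name="CA")
    ref_ca = reference.coords[ca_sel] if len(reference) == len(traj.topology) else None

    bends, shifts = [], []
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        if ref_ca is not None:
            rot, trans, _ = kabsch_fit(frame[ca_sel], ref_ca)
            frame = frame @ rot.T + trans
        b, s = kink_parameters(traj.topology.with_coords(frame), pivot, pre_range, post_range)
        bends.append(b)
        shifts.append(s)
    bends = np.asarray(bends)
    shifts = np.asarray(shifts)

    centered = wrap_angle(shifts - shifts[0])
    fs_mean = wrap_angle(float(np.mean(centered)) + shifts[0])
    fs_std = float(np.std(centered, ddof=1)) if len(shifts) > 1 else 0.0
    return KinkSeries(
        pivot=pivot,
        bend_deg=bends,
        face_shift_deg=shifts,
        bend_mean=float(bends.mean()),
        bend_std=float(bends.std(ddof=1)) if len(bends) > 1 else 0.0,
        face_shift_mean=float(fs_mean),
        face_shift_std=fs_std,
    )
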