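"""Ligand contact occupancy, pathway classification, and pulling-force profiles.

Binding-site composition is measured as contact occupancy: a residue belongs
to a site if it spends more than a threshold fraction (default 5%) of the
analyzed frames within a cutoff (default 3.5 A) of the substrate.  Contacts
use heavy atoms only by default: the minimum distance over all ligand-atom x
residue-atom pairs.

Translocation-pathway residues are classified from pulling trajectories by
the windowed contact percentage: for each residue and trajectory,
``n_contact_frames / (last_frame - first_frame + 1)`` over the window between
its first and last substrate contact, with a single-frame contact counting as
100%; a residue joins the pathway if the maximum over trajectories exceeds
the threshold, after excluding residues already assigned to a binding site.

Steered-pulling force series are smoothed with a centered moving average and
scanned for strict local minima, which mark pockets along the pulling path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import ATOMIC_MASSES, NumberingMap, Role, Structure, Trajectory

__all__ = [
    "OccupancyRecord",
    "PathwayRecord",
    "TrajectoryContactStats",
    "ForceProfile",
    "contact_frames",
    "site_occupancy",
    "classify_pathway",
    "distance_series",
    "com_z_series",
    "hbond_present",
    "force_profile",
]

#: Default contact cutoff (A) and site-membership threshold.
CONTACT_CUTOFF_A = 3.5
MIN_SITE_FRACTION = 0.05


@dataclass
class OccupancyRecord:
    residue_id: int
    label: str
    ca_z: float
    occupancy_fraction: float  # rendered as integer % in tables

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy_fraction <= 1.0):
            raise ValueError("occupancy_fraction must lie in [0, 1]")
        if not np.isfinite(self.ca_z):
            raise ValueError("ca_z must be finite")


@dataclass
class TrajectoryContactStats:
    first_contact_frame: int
    last_contact_frame: int
    n_contact_frames: int
    percentage: float  # of the first..last window, in [0, 1]

    def __post_init__(self) -> None:
        if self.first_contact_frame > self.last_contact_frame:
            raise ValueError("first contact frame after last")
        window = self.last_contact_frame - self.first_contact_frame + 1
        if self.n_contact_frames > window:
            raise ValueError("more contact frames than window frames")


@dataclass
class PathwayRecord:
    residue_id: int
    label: str
    ca_z: float
    max_percentage: float
    per_trajectory: list[TrajectoryContactStats] = field(default_factory=list)


@dataclass
class ForceProfile:
    raw: np.ndarray
    smoothed: np.ndarray
    minima: list[int]
    window: int
    velocity_A_per_ns: float | None = None
    spring_kcal_per_molA2: float | None = None


def _heavy(struct: Structure, idx: np.ndarray) -> np.ndarray:
    return np.asarray([i for i in idx if struct.atoms[i].element.upper() != "H"], dtype=int)


def contact_frames(
    traj: Trajectory,
    ligand: np.ndarray,
    residue_id: int,
    cutoff: float = CONTACT_CUTOFF_A,
    heavy_only: bool = True,
    frame_indices: np.ndarray | None = None,
) -> set[int]:
    """Frames in which the ligand-residue minimum atom distance is <= cutoff."""
    ligand = np.asarray(ligand, dtype=int)
    res = traj.topology.indices(residue_id=residue_id, role=Role.protein)
    if heavy_only:
        ligand = _heavy(traj.topology, ligand)
        res = _heavy(traj.topology, res)
    if ligand.size == 0 or res.size == 0:
        raise ValueError("empty ligand or residue selection")
    if set(ligand) & set(res):
        raise ValueError("ligand and residue selections overlap")
    if frame_indices is None:
        frame_indices = np.arange(traj.n_frames)
    out = set()
    for f in frame_indices:
        d = cdist(traj.frames[f][ligand], traj.frames[f][res])
        if d.min() <= cutoff:
            out.add(int(f))
    return out


def _analysis_frames(traj: Trajectory, discard: float, stride: float) -> np.ndarray:
    """Frame indices with t >= discard, subsampled to one per ``stride`` ps."""
    t = np.asarray(traj.frame_times)
    keep = np.flatnonzero(t >= discard)
    if keep.size == 0:
        raise ValueError("discard interval removes every frame")
    if stride > 0 and keep.size > 1:
        dt = t[keep[1]] - t[keep[0]]
        step = max(1, int(round(stride / dt)))
        keep = keep[::step]
    return keep


def site_occupancy(
    traj: Trajectory,
    ligand: np.ndarray,
    cutoff: float = CONTACT_CUTOFF_A,
    min_fraction: float = MIN_SITE_FRACTION,
    discard: float = 0.0,
    stride: float = 0.0,
    numbering: NumberingMap | None = None,
) -> list[OccupancyRecord]:
    """Binding-site composition: residues in contact > ``min_fraction`` of frames.

    Frames before ``discard`` (ps) are dropped and the remainder subsampled at
    ``stride`` (ps).  The occupancy fraction is contact frames / analyzed
    frames; only residues strictly above the threshold are returned, sorted by
    generic label (when a numbering is given) else by residue id.
    """
    frames = _analysis_frames(traj, discard, stride)
    records = []
    for rid in traj.topology.residue_ids(Role.protein):
        hits = contact_frames(traj, ligand, rid, cutoff, frame_indices=frames)
        frac = len(hits) / frames.size
        if frac > min_fraction:
            ca = traj.topology.indices(residue_id=rid, atom_name="CA")
            ca_z = float(np.mean([traj.frames[f][ca, 2] for f in frames])) if ca.size else 0.0
            label = numbering.label(rid) if numbering else str(rid)
            records.append(OccupancyRecord(rid, label, ca_z, frac))
    records.sort(key=lambda r: r.label)
    return records


def classify_pathway(
    trajs: list[Trajectory],
    ligand: np.ndarray,
    cutoff: float = CONTACT_CUTOFF_A,
    min_fraction: float = MIN_SITE_FRACTION,
    exclude: set[int] | None = None,
    numbering: NumberingMap | None = None,
) -> list[PathwayRecord]:
    """Pathway residues from one or more pulling trajectories.

    Per residue and trajectory the contact percentage is computed over the
    window between first and last contact (inclusive denominator); the residue
    is classified as pathway if its maximum percentage over trajectories
    strictly exceeds ``min_fraction``.  Residues in ``exclude`` (binding-site
    members) are removed.
    """
    if not trajs:
        raise ValueError("at least one trajectory is required")
    exclude = exclude or set()
    topo = trajs[0].topology
    records = []
    for rid in topo.residue_ids(Role.protein):
        if rid in exclude:
            continue
        stats = []
        for traj in trajs:
            hits = sorted(contact_frames(traj, ligand, rid, cutoff))
            if not hits:
                continue
            first, last = hits[0], hits[-1]
            pct = len(hits) / (last - first + 1)
            stats.append(TrajectoryContactStats(first, last, len(hits), pct))
        if not stats:
            continue
        max_pct = max(s.percentage for s in stats)
        if max_pct > min_fraction:
            ca = topo.indices(residue_id=rid, atom_name="CA")
            ca_z = float(trajs[0].frames[0][ca, 2].mean()) if ca.size else 0.0
            label = numbering.label(rid) if numbering else str(rid)
            records.append(PathwayRecord(rid, label, ca_z, max_pct, stats))
    records.sort(key=lambda r: r.label)
    return records


def distance_series(traj: Trajectory, atom_a: int, atom_b: int) -> tuple[np.ndarray, float, float]:
    """Per-frame distance between two atoms (by atom_id); returns (series, mean, sample std)."""
    ia = traj.topology.atom_index(atom_a)
    ib = traj.topology.atom_index(atom_b)
    d = np.array([float(np.linalg.norm(f[ia] - f[ib])) for f in traj.frames])
    std = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return d, float(d.mean()), std


def com_z_series(
    traj: Trajectory,
    selection: np.ndarray,
    masses: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-frame mass-weighted mean z of the selection (A)."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    table = ATOMIC_MASSES if masses is None else masses
    try:
        m = np.array([table[traj.topology.atoms[i].element.upper()] for i in selection])
    except KeyError as exc:
        raise ValueError(f"no mass for element {exc.args[0]!r}") from exc
    m = m / m.sum()
    return np.array([float(m @ f[selection, 2]) for f in traj.frames])


def hbond_present(
    frame: np.ndarray,
    donor: int,
    acceptor: int,
    hydrogen: int | None = None,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
) -> bool:
    """Geometric H-bond test: donor-acceptor distance and optional D-H-A angle."""
    frame = np.asarray(frame, dtype=float)
    d = float(np.linalg.norm(frame[donor] - frame[acceptor]))
    if d > d_cut:
        return False
    if hydrogen is None:
        return True
    v1 = frame[donor] - frame[hydrogen]
    v2 = frame[acceptor] - frame[hydrogen]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return angle >= angle_cut


def force_profile(
    force_series: np.ndarray,
    window: int = 1,
    velocity_A_per_ns: float | None = None,
    spring_kcal_per_molA2: float | None = None,
) -> ForceProfile:
    """Smooth a pulling-force series and locate strict local minima.

    ``window`` (odd, >= 1) is the centered moving-average width; reported
    minima are strict local minima of the smoothed series at least ``window``
    frames apart (deepest first when competing).
    """
    raw = np.asarray(force_series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > raw.size:
        raise ValueError("window longer than the force series")
    if window == 1:
        smoothed = raw.copy()
    else:
        kernel = np.ones(window)
        smoothed = np.convolve(raw, kernel, mode="same") / np.convolve(
            np.ones_like(raw), kernel, mode="same"
        )
    candidates = [
        i
        for i in range(1, raw.size - 1)
        if smoothed[i] < smoothed[i - 1] and smoothed[i] < smoothed[i + 1]
    ]
    candidates.sort(key=lambda i: smoothed[i])
    minima: list[int] = []
    for i in candidates:
        if all(abs(i - j) >= window for j in minima):
            minima.append(i)
    minima.sort()
    return ForceProfile(
        raw=raw,
        smoothed=smoothed,
        minima=minima,
        window=window,
        velocity_A_per_ns=velocity_A_per_ns,
        spring_kcal_per_molA2=spring_kcal_per_molA2,
    )
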