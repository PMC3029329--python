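"""Kabsch fits, iterative weighted superposition, trajectory alignment, DDM."""

import numpy as np
import pytest

from permeopath import synthetic
from permeopath.model_io import Role, Trajectory
from permeopath.superpose import (
    align_trajectory,
    difference_distance_matrix,
    iterative_weighted_fit,
    kabsch_fit,
    label_rigidity,
)
from permeopath.synthetic import rotation_about_axis


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestKabsch:
    def test_recovers_random_rigid_transforms(self, rng):
        ref = rng.uniform(0, 20, size=(30, 3))
        for _ in range(100):
            rot = _random_rotation(rng)
            t = rng.uniform(-10, 10, 3)
            mobile = ref @ rot.T + t
            r, tr, rmsd = kabsch_fit(mobile, ref)
            assert rmsd <= 1e-8
            np.testing.assert_allclose(mobile @ r.T + tr, ref, atol=1e-8)

    def test_identity_on_identical_inputs(self, rng):
        ref = rng.uniform(0, 10, size=(10, 3))
        r, t, rmsd = kabsch_fit(ref, ref)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert rmsd <= 1e-10

    def test_collinear_configuration_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_fit(line, line + 1.0)

    def test_fewer_than_three_atoms_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError):
            kabsch_fit(pts, pts)

    def test_rotation_is_proper_on_mirrored_inputs(self, rng):
        for _ in range(20):
            ref = rng.uniform(0, 10, size=(15, 3))
            mirrored = ref * np.array([-1.0, 1.0, 1.0])
            r, _, _ = kabsch_fit(mirrored, ref)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
            assert np.linalg.norm(r.T @ r - np.eye(3)) < 1e-8

    def test_noisy_fit_matches_rotation_search_oracle(self, rng):
        """SVD minimum agrees (within 10%) with an SVD-free rotation search.

        The oracle scans random quaternions, then polishes the best one with a
        derivative-free simplex search over the axis-angle vector; it never
        touches the production code path.
        """
        from scipy.optimize import minimize

        ref = rng.uniform(0, 20, size=(500, 3))
        mobile = ref + rng.normal(0, 0.5, size=ref.shape)
        _, _, rmsd = kabsch_fit(mobile, ref)

        mob_c = mobile - mobile.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)

        def rotvec_rmsd(v):
            theta = np.linalg.norm(v)
            if theta < 1e-12:
                r = np.eye(3)
            else:
                k = v / theta
                kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
                r = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
            return np.sqrt(np.mean(np.sum((mob_c @ r.T - ref_c) ** 2, axis=1)))

        best_v, best = None, np.inf
        for _ in range(2000):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w = np.clip(abs(q[0]), -1, 1)
            theta = 2 * np.arccos(w)
            axis = q[1:] * np.sign(q[0]) if np.linalg.norm(q[1:]) > 1e-12 else np.array([1.0, 0, 0])
            v = axis / max(np.linalg.norm(axis), 1e-12) * theta
            val = rotvec_rmsd(v)
            if val < best:
                best, best_v = val, v
        res = minimize(rotvec_rmsd, best_v, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        oracle = min(best, float(res.fun))
        assert rmsd <= oracle + 1e-9  # SVD is the true optimum
        assert abs(rmsd - oracle) / oracle < 0.10

    def test_weighted_rmsd_never_exceeds_unaligned_rmsd(self, rng):
        for _ in range(20):
            ref = rng.uniform(0, 10, size=(25, 3))
            mobile = ref + rng.normal(0, 1.0, size=ref.shape)
            w = rng.uniform(0.1, 2.0, size=25)
            _, _, fitted = kabsch_fit(mobile, ref, w)
            wn = w / w.sum()
            unaligned = np.sqrt(np.sum(wn * np.sum((mobile - ref) ** 2, axis=1)))
            assert fitted <= unaligned + 1e-12


class TestIterativeWeightedFit:
    def test_identical_structures_have_zero_rmsd_everywhere(self, ideal_helix):
        res = iterative_weighted_fit(ideal_helix, ideal_helix, n_iter=1)
        assert all(v <= 1e-10 for v in res.per_residue_rmsd.values())

    def test_two_domain_split_into_rigid_and_mobile(self, two_domain_trajectory):
        traj = two_domain_trajectory
        res = iterative_weighted_fit(traj.frame_structure(2), traj.frame_structure(0))
        labels = label_rigidity(res.per_residue_rmsd)
        assert all(labels[r] == "rigid" for r in range(1, 17))
        assert all(res.per_residue_rmsd[r] < 1.0 for r in range(1, 17))
        assert all(labels[r] == "mobile" for r in range(17, 25))
        assert all(res.per_residue_rmsd[r] > 2.0 for r in range(17, 25))

    def test_core_global_rmsd_non_increasing_over_iterations(self, two_domain_trajectory):
        traj = two_domain_trajectory
        res = iterative_weighted_fit(traj.frame_structure(2), traj.frame_structure(0))
        core_global = [
            np.sqrt(np.mean([t[r] ** 2 for r in range(1, 17)]))
            for t in res.per_residue_trace
        ]
        assert all(b <= a + 1e-9 for a, b in zip(core_global, core_global[1:]))

    def test_core_weighted_fit_zeroes_core_exactly(self):
        """With weights restricted to the rigid core, core deviation vanishes."""
        traj = synthetic.make_two_domain_ensemble(16, 8, 3, [0.0, 0.0, 25.0], 0.0, seed=1)
        mob, ref = traj.frames[2], traj.frames[0]
        core = np.flatnonzero([a.residue_id <= 16 for a in traj.topology.atoms])
        r, t, rmsd = kabsch_fit(mob[core], ref[core])
        assert rmsd <= 1e-9

    def test_mismatched_residue_lists_rejected(self, ideal_helix):
        other = synthetic.build_ideal_helix(40, first_residue_id=5)
        with pytest.raises(ValueError, match="match"):
            iterative_weighted_fit(ideal_helix, other)


class TestAlignTrajectory:
    def test_rigid_copies_align_onto_reference(self, ideal_helix, rng):
        frames = []
        for _ in range(4):
            rot = _random_rotation(rng)
            frames.append(ideal_helix.coords @ rot.T + rng.uniform(-5, 5, 3))
        traj = Trajectory(ideal_helix, frames, [10.0 * k for k in range(4)])
        sel = ideal_helix.indices(role=Role.protein)
        aligned = align_trajectory(traj, ideal_helix, sel)
        for f in aligned.frames:
            np.testing.assert_allclose(f, ideal_helix.coords, atol=1e-6)

    def test_alignment_is_idempotent(self, two_domain_trajectory):
        traj = two_domain_trajectory
        sel = traj.topology.indices(role=Role.protein)
        once = align_trajectory(traj, traj.frame_structure(0), sel)
        twice = align_trajectory(once, once.frame_structure(0), sel)
        for a, b in zip(once.frames, twice.frames):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_empty_selection_rejected(self, two_domain_trajectory):
        with pytest.raises(ValueError, match="empty"):
            align_trajectory(two_domain_trajectory, two_domain_trajectory.frame_structure(0), np.array([]))


class TestDifferenceDistanceMatrix:
    def test_rigid_transform_gives_zero_matrix(self, ideal_helix, rng):
        rot = _random_rotation(rng)
        moved = ideal_helix.with_coords(ideal_helix.coords @ rot.T + [1, 2, 3])
        ddm = difference_distance_matrix(ideal_helix, moved)
        assert np.abs(ddm.matrix).max() < 1e-9

    def test_two_angstrom_separation_reads_plus_two(self, ideal_helix):
        coords = ideal_helix.coords.copy()
        ca = ideal_helix.indices(atom_name="CA")
        i, j = int(ca[0]), int(ca[-1])
        direction = (coords[i] - coords[j]) / np.linalg.norm(coords[i] - coords[j])
        # move every atom of the first residue so distances stay residue-consistent
        first_res = ideal_helix.indices(residue_id=1)
        coords[first_res] += 2.0 * direction
        moved = ideal_helix.with_coords(coords)
        ddm = difference_distance_matrix(ideal_helix, moved)
        assert ddm.entry(1, 40) == pytest.approx(2.0, abs=1e-9)

    def test_state_swap_negates_matrix(self, ideal_helix):
        kinked = synthetic.impose_kink(ideal_helix, synthetic.KinkSpec(20, 30.0, 0.0))
        ab = difference_distance_matrix(ideal_helix, kinked)
        ba = difference_distance_matrix(kinked, ideal_helix)
        np.testing.assert_allclose(ab.matrix, -ba.matrix, atol=1e-12)
        assert np.all(np.diag(ab.matrix) == 0)

    def test_residue_mismatch_rejected(self, ideal_helix):
        other = synthetic.build_ideal_helix(40, first_residue_id=2)
        with pytest.raises(ValueError, match="differ"):
            difference_distance_matrix(ideal_helix, other)
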