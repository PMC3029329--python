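"""Occupancy statistics, pathway classification, series, and force profiles."""

import numpy as np
import pytest

from permeopath import contacts, synthetic
from permeopath.contacts import (
    classify_pathway,
    com_z_series,
    contact_frames,
    distance_series,
    force_profile,
    hbond_present,
    site_occupancy,
)
from permeopath.model_io import Atom, Role, Structure, Trajectory


def _static_traj(atoms, n_frames=1):
    s = Structure(atoms)
    return Trajectory(s, [s.coords] * n_frames, [10.0 * k for k in range(n_frames)])


class TestContactFrames:
    def test_cutoff_zero_gives_empty_set(self, scripted_trajectory, ligand_selection):
        assert contact_frames(scripted_trajectory, ligand_selection, 1, cutoff=0.0) == set()

    def test_overlapping_selection_rejected(self, scripted_trajectory):
        prot = scripted_trajectory.topology.indices(residue_id=1)
        with pytest.raises(ValueError, match="overlap"):
            contact_frames(scripted_trajectory, prot, 1)

    def test_matches_naive_double_loop_oracle(self, rng):
        """Production min-distance contact equals the all-pairs oracle."""
        for _ in range(100):
            n_prot = int(rng.integers(3, 30))
            atoms = []
            serial = 1
            for i in range(n_prot):
                atoms.append(
                    Atom(serial, "CA", "C", 1 + i % 3, "ALA", "A", Role.protein,
                         rng.uniform(0, 15, 3))
                )
                serial += 1
            for j in range(int(rng.integers(1, 6))):
                atoms.append(
                    Atom(serial, f"C{j+1}", "C", 999, "LIG", "L", Role.ligand,
                         rng.uniform(0, 15, 3))
                )
                serial += 1
            traj = _static_traj(atoms)
            lig = traj.topology.indices(role=Role.ligand)
            res = traj.topology.indices(residue_id=1, role=Role.protein)
            cutoff = float(rng.uniform(1, 8))
            got = contact_frames(traj, lig, 1, cutoff=cutoff)
            dmin = min(
                float(np.linalg.norm(traj.frames[0][i] - traj.frames[0][j]))
                for i in lig
                for j in res
            )
            assert got == ({0} if dmin <= cutoff else set())


class TestSiteOccupancy:
    def test_fractions_equal_scripted_fractions_exactly(
        self, scripted_trajectory, ligand_selection, contact_script
    ):
        recs = site_occupancy(scripted_trajectory, ligand_selection)
        got = {r.residue_id: r.occupancy_fraction for r in recs}
        assert got == {1: 0.30, 4: 0.10, 7: 0.20}  # residue 9 at 4% excluded

    def test_four_percent_is_below_threshold(self, scripted_trajectory, ligand_selection):
        recs = site_occupancy(scripted_trajectory, ligand_selection, min_fraction=0.05)
        assert 9 not in {r.residue_id for r in recs}
        # with a lower threshold it reappears at exactly 4%
        recs = site_occupancy(scripted_trajectory, ligand_selection, min_fraction=0.01)
        got = {r.residue_id: r.occupancy_fraction for r in recs}
        assert got[9] == 0.04

    def test_permanent_contact_is_fraction_one(self):
        protein = synthetic.make_spaced_residue_protein(3)
        traj = synthetic.make_scripted_ligand_trajectory(protein, {2: set(range(10))}, 10)
        lig = traj.topology.indices(role=Role.ligand)
        recs = site_occupancy(traj, lig)
        assert {r.residue_id: r.occupancy_fraction for r in recs} == {2: 1.0}

    def test_discarding_all_frames_is_an_error(self, scripted_trajectory, ligand_selection):
        with pytest.raises(ValueError, match="discard"):
            site_occupancy(scripted_trajectory, ligand_selection, discard=1e6)


class TestClassifyPathway:
    def test_windowed_percentage_formula(self, scripted_trajectory, ligand_selection):
        recs = classify_pathway([scripted_trajectory], ligand_selection)
        by_id = {r.residue_id: r for r in recs}
        # residue 9 seen in 4 frames between frames 60 and 66 -> 4/7
        assert by_id[9].max_percentage == pytest.approx(4 / 7)
        st = by_id[9].per_trajectory[0]
        assert (st.first_contact_frame, st.last_contact_frame, st.n_contact_frames) == (60, 66, 4)

    def test_forty_of_fiftyone_window(self):
        protein = synthetic.make_spaced_residue_protein(3)
        frames = set(range(10, 50)) | {60}  # first 10, last 60, 41 frames seen
        traj = synthetic.make_scripted_ligand_trajectory(protein, {2: frames}, 70)
        lig = traj.topology.indices(role=Role.ligand)
        rec = classify_pathway([traj], lig)[0]
        assert rec.max_percentage == pytest.approx(41 / 51)

    def test_single_frame_contact_is_one_hundred_percent(self):
        protein = synthetic.make_spaced_residue_protein(3)
        traj = synthetic.make_scripted_ligand_trajectory(protein, {2: {5}}, 10)
        lig = traj.topology.indices(role=Role.ligand)
        rec = classify_pathway([traj], lig)[0]
        assert rec.max_percentage == 1.0

    def test_excluded_site_residue_absent_despite_full_contact(self):
        protein = synthetic.make_spaced_residue_protein(3)
        traj = synthetic.make_scripted_ligand_trajectory(protein, {2: set(range(10))}, 10)
        lig = traj.topology.indices(role=Role.ligand)
        recs = classify_pathway([traj], lig, exclude={2})
        assert recs == []

    def test_adding_contact_inside_window_never_decreases_percentage(self):
        protein = synthetic.make_spaced_residue_protein(3)
        base = {10, 20}
        lig_of = lambda t: t.topology.indices(role=Role.ligand)
        traj = synthetic.make_scripted_ligand_trajectory(protein, {2: base}, 30)
        p0 = classify_pathway([traj], lig_of(traj))[0].max_percentage
        for extra in (12, 15, 19):
            traj = synthetic.make_scripted_ligand_trajectory(protein, {2: base | {extra}}, 30)
            p1 = classify_pathway([traj], lig_of(traj))[0].max_percentage
            assert p1 >= p0
            assert 0 < p1 <= 1
            base = base | {extra}
            p0 = p1


class TestSeries:
    def test_static_distance_mean_and_std(self):
        atoms = [
            Atom(1, "CA", "C", 1, "ALA", "A", Role.protein, [0, 0, 0]),
            Atom(2, "CA", "C", 2, "ALA", "A", Role.protein, [5, 0, 0]),
            Atom(3, "CB", "C", 2, "ALA", "A", Role.protein, [5, 1, 0]),
        ]
        traj = _static_traj(atoms, n_frames=4)
        d, mean, std = distance_series(traj, 1, 2)
        assert mean == pytest.approx(5.0)
        assert std == 0.0

    def test_same_atom_distance_is_zero(self):
        atoms = [
            Atom(1, "CA", "C", 1, "ALA", "A", Role.protein, [0, 0, 0]),
            Atom(2, "CA", "C", 2, "ALA", "A", Role.protein, [5, 0, 0]),
            Atom(3, "CB", "C", 2, "ALA", "A", Role.protein, [5, 1, 0]),
        ]
        traj = _static_traj(atoms, n_frames=2)
        d, mean, std = distance_series(traj, 1, 1)
        assert np.all(d == 0)

    def test_two_frame_closed_form(self):
        s = Structure(
            [
                Atom(1, "CA", "C", 1, "ALA", "A", Role.protein, [0, 0, 0]),
                Atom(2, "CA", "C", 2, "ALA", "A", Role.protein, [3, 0, 0]),
                Atom(3, "CB", "C", 2, "ALA", "A", Role.protein, [3, 1, 0]),
            ]
        )
        f2 = s.coords.copy()
        f2[1] = [5, 0, 0]
        traj = Trajectory(s, [s.coords, f2], [0.0, 10.0])
        _, mean, std = distance_series(traj, 1, 2)
        assert mean == pytest.approx(4.0)
        assert std == pytest.approx(np.sqrt(2.0))

    def test_com_z_symmetry_and_mass_weighting(self):
        atoms = [
            Atom(1, "C1", "C", 1, "LIG", "L", Role.ligand, [0, 0, -1]),
            Atom(2, "C2", "C", 1, "LIG", "L", Role.ligand, [0, 0, 1]),
        ]
        traj = _static_traj(atoms)
        assert com_z_series(traj, np.array([0, 1]))[0] == pytest.approx(0.0)

        atoms = [
            Atom(1, "C1", "C", 1, "LIG", "L", Role.ligand, [0, 0, 0]),
            Atom(2, "H1", "H", 1, "LIG", "L", Role.ligand, [0, 0, 13]),
        ]
        traj = _static_traj(atoms)
        z = com_z_series(traj, np.array([0, 1]), masses={"C": 12.0, "H": 1.0})
        assert z[0] == pytest.approx(1.0)

    def test_com_z_shift_equivariance(self, scripted_trajectory, ligand_selection):
        z0 = com_z_series(scripted_trajectory, ligand_selection)
        shifted = Trajectory(
            scripted_trajectory.topology,
            [f + np.array([0.0, 0.0, 2.0]) for f in scripted_trajectory.frames],
            list(scripted_trajectory.frame_times),
        )
        z1 = com_z_series(shifted, ligand_selection)
        np.testing.assert_allclose(z1 - z0, 2.0, atol=1e-9)

    def test_unknown_element_mass_rejected(self):
        atoms = [Atom(1, "X1", "XX", 1, "LIG", "L", Role.ligand, [0, 0, 0])]
        traj = _static_traj(atoms)
        with pytest.raises(ValueError, match="mass"):
            com_z_series(traj, np.array([0]))


class TestHbond:
    FRAME = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.8, 0, 0], [4.0, 0, 0]])

    def test_close_and_linear_is_bonded(self):
        assert hbond_present(self.FRAME, donor=0, acceptor=2, hydrogen=1)

    def test_long_distance_is_not(self):
        assert not hbond_present(self.FRAME, donor=0, acceptor=3, d_cut=3.5)

    def test_bent_geometry_is_not(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 2.6, 0]])
        assert not hbond_present(frame, donor=0, acceptor=2, hydrogen=1, angle_cut=120.0)


class TestForceProfile:
    def test_constant_series_has_no_minima(self):
        assert force_profile(np.full(50, 3.0), window=5).minima == []

    def test_v_shaped_dip_located(self):
        x = np.arange(100.0)
        series = np.abs(x - 50.0) + 5.0
        prof = force_profile(series, window=7)
        assert len(prof.minima) == 1
        assert abs(prof.minima[0] - 50) <= 3  # within window/2

    def test_window_one_is_identity(self):
        series = np.sin(np.arange(30) / 3.0)
        prof = force_profile(series, window=1)
        np.testing.assert_array_equal(prof.smoothed, series)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            force_profile(np.zeros(5), window=7)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            force_profile(np.zeros(10), window=4)
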