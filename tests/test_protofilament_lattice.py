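"""Docking, contact rotation, axial registration and microtubule metrics."""

import numpy as np
import pytest

from mig import protofilament_lattice as pl
from mig import synthetic_assembly as syn
from mig.pipeline import lattice_model_from_synthetic


@pytest.fixture(scope="module")
def lattice():
    return syn.make_mt_lattice(syn.LatticeParams(n_layers=6))


@pytest.fixture(scope="module")
def lattice_model(lattice):
    return lattice_model_from_synthetic(lattice)


@pytest.fixture(scope="module")
def subunit(lattice_model):
    m = lattice_model.model
    return m.subset([a for a in m.atoms if a.chain_id == "A" and a.residue_number == 1])


@pytest.fixture(scope="module")
def subunit_map(subunit):
    return syn.synthesize_density(subunit, voxel_size=1.5, sigma=4.0, pad=8.0)


class TestLatticeModel:
    def test_indexing_from_residue_level_annotation(self, lattice_model):
        assert lattice_model.n_pf == 13
        assert lattice_model.layers_of[1] == list(range(1, 7))
        assert lattice_model.species[(1, 1)] == "alpha"
        assert lattice_model.species[(1, 2)] == "beta"

    def test_interfaces_are_cyclic(self, lattice_model):
        ifaces = lattice_model.interfaces()
        assert len(ifaces) == 13
        assert ifaces[-1] == (13, 1)

    def test_monomer_repeat_estimated_from_heights(self, lattice_model):
        est = pl.LatticeModel(lattice_model.model).estimated_monomer_repeat()
        assert est == pytest.approx(41.0, abs=1e-9)


class TestDockRigidBody:
    def test_identity_pose_for_self_map(self, subunit, subunit_map):
        pose, cc = pl.dock_rigid_body(subunit, subunit_map, sigma=4.0,
                                      translation_range=2.0, translation_step=1.0,
                                      rotation_range=0.0, rotation_step=0.0)
        assert cc >= 0.999
        np.testing.assert_allclose(pose.translation, 0.0, atol=1e-6)
        np.testing.assert_allclose(pose.rotation, np.eye(3), atol=1e-9)

    def test_known_shift_recovered_within_half_grid_step(self, subunit, subunit_map):
        shift = np.array([1.4, -0.8, 0.6])
        moved = subunit.with_positions(subunit.positions + shift)
        pose, cc = pl.dock_rigid_body(moved, subunit_map, sigma=4.0,
                                      translation_range=3.0, translation_step=1.0,
                                      rotation_range=0.0, rotation_step=0.0)
        assert np.abs(pose.translation + shift).max() <= 0.5
        assert cc > 0.99

    def test_returned_cc_matches_recomputation(self, subunit, subunit_map):
        from mig.ring_geometry import model_map_correlation

        moved = subunit.with_positions(subunit.positions + np.array([1.0, 0.0, -1.0]))
        pose, cc = pl.dock_rigid_body(moved, subunit_map, sigma=4.0,
                                      translation_range=2.0, translation_step=1.0,
                                      rotation_range=4.0, rotation_step=2.0)
        recomputed = model_map_correlation(moved.transformed(pose), subunit_map, 4.0)
        assert cc == pytest.approx(recomputed, abs=1e-9)

    def test_no_fit_below_floor(self, subunit, subunit_map):
        far = subunit.with_positions(subunit.positions + np.array([40.0, 40.0, 0.0]))
        with pytest.raises(pl.NoFitError):
            pl.dock_rigid_body(far, subunit_map, sigma=4.0,
                               translation_range=2.0, translation_step=1.0,
                               rotation_range=0.0, rotation_step=0.0)


class TestOptimizeContactRotation:
    def test_ideal_lattice_stays_put(self, lattice_model):
        _, angles = pl.optimize_contact_rotation(lattice_model)
        assert max(abs(v) for v in angles.values()) <= 0.01

    def test_pre_rotated_pf_corrected(self, lattice_model):
        pos = lattice_model.model.positions
        idx = lattice_model.pf_atom_indices(5)
        center = lattice_model.pf_axis_point(5)
        pos[idx] = pl._rotate_about(pos[idx], np.array([0.0, 0, 1]), center, 10.0)
        pert = lattice_model.replaced(lattice_model.model.with_positions(pos))
        _, angles = pl.optimize_contact_rotation(pert)
        assert angles[5] == pytest.approx(-10.0, abs=0.02)
        assert max(abs(v) for k, v in angles.items() if k != 5) <= 0.02

    def test_matches_exhaustive_grid_search(self, lattice_model):
        """Sweep result agrees with a brute-force 0.01 deg grid per pf."""
        pos = lattice_model.model.positions
        idx = lattice_model.pf_atom_indices(3)
        center = lattice_model.pf_axis_point(3)
        pos[idx] = pl._rotate_about(pos[idx], np.array([0.0, 0, 1]), center, -6.0)
        pert = lattice_model.replaced(lattice_model.model.with_positions(pos))
        _, angles = pl.optimize_contact_rotation(pert)

        east = pl._contact_positions(pert, 3, pl.ContactSpec(), "east")
        west = pl._contact_positions(pert, 3, pl.ContactSpec(), "west")
        e2 = pl._contact_positions(pert, 2, pl.ContactSpec(), "east")
        w4 = pl._contact_positions(pert, 4, pl.ContactSpec(), "west")
        grid = np.arange(-10.0, 10.0, 0.01)
        vals = []
        for a in grid:
            e = pl._rotate_about(east, np.array([0.0, 0, 1]), center, a)
            w = pl._rotate_about(west, np.array([0.0, 0, 1]), center, a)
            vals.append(pl._facing_pair_distance(e2, w) + pl._facing_pair_distance(e, w4))
        best = grid[int(np.argmin(vals))]
        assert angles[3] == pytest.approx(best, abs=0.02)

    def test_monotone_descent_of_total_contact_distance(self, lattice_model, rng):
        # random small rotations on three pfs; optimizer must not end worse
        pos = lattice_model.model.positions
        for pf in (2, 7, 11):
            idx = lattice_model.pf_atom_indices(pf)
            center = lattice_model.pf_axis_point(pf)
            pos[idx] = pl._rotate_about(pos[idx], np.array([0.0, 0, 1]), center,
                                        float(rng.uniform(-12, 12)))
        pert = lattice_model.replaced(lattice_model.model.with_positions(pos))

        def total(lm):
            return sum(pl.interface_contact_distance(lm, a, b)
                       for a, b in lm.interfaces())

        before = total(pert)
        out, _ = pl.optimize_contact_rotation(pert)
        assert total(out) <= before + 1e-9


class TestAxialRegister:
    def test_zero_and_known_shifts_recovered(self, lattice_model):
        pf1 = lattice_model.model.subset(
            [a for a in lattice_model.model.atoms if a.chain_id == "A"]
        )
        axis = pl.mt_axis_from_layers(lattice_model)
        dmap = syn.synthesize_density(pf1, 2.0, 5.0, pad=10.0)
        for true_shift in (0.0, 7.0, -13.0):
            moved = pf1.with_positions(pf1.positions - true_shift * axis.direction)
            prof = pl.axial_register(moved, dmap, axis, shift_range=60.0, step=1.0,
                                     sigma=5.0)
            assert abs(prof.chosen_shift - true_shift) <= 0.5
            assert abs(prof.chosen_shift - true_shift) <= 0.1   # Gaussian-refined
            # peaks repeat at the monomer register
            means = sorted(g.mean for g in prof.gaussians)
            if len(means) >= 2:
                gaps = np.diff(means)
                assert np.allclose(gaps, 41.0, atol=1.5)

    def test_constructed_gaussian_mixture_recovered(self, rng):
        x = np.arange(-60.0, 61.0, 1.0)
        true = [(0.9, -30.0, 6.0), (1.0, 5.0, 7.0), (0.7, 40.0, 5.0)]
        y = sum(a * np.exp(-((x - m) ** 2) / (2 * s**2)) for a, m, s in true)
        y = y + rng.normal(0.0, 0.01, len(x))
        peaks, _ = pl.fit_gaussian_mixture(x, y, [-30.0, 5.0, 40.0])
        got = sorted(g.mean for g in peaks)
        for fitted, (_, mu, _) in zip(got, true):
            assert fitted == pytest.approx(mu, abs=0.05)

    def test_short_range_rejected(self, lattice_model):
        pf1 = lattice_model.pf_model(1)
        axis = pl.mt_axis_from_layers(lattice_model)
        dmap = syn.synthesize_density(pf1, 2.0, 5.0, pad=10.0)
        with pytest.raises(ValueError):
            pl.axial_register(pf1, dmap, axis, shift_range=20.0)

    def test_cc_profile_symmetric_under_joint_mirroring(self, lattice_model):
        """Mirroring both map and model leaves the correlation curve unchanged."""
        pf1 = lattice_model.pf_model(1)
        axis = pl.mt_axis_from_layers(lattice_model)
        dmap = syn.synthesize_density(pf1, 2.0, 5.0, pad=10.0)
        prof = pl.axial_register(pf1, dmap, axis, shift_range=50.0, step=2.0, sigma=5.0)
        # mirror through z -> -z: flip model, map grid and axis together
        flipped = pf1.with_positions(pf1.positions * np.array([1.0, 1.0, -1.0]))
        m_grid = dmap.grid[:, :, ::-1]
        m_origin = dmap.origin.copy()
        # flipped voxel i sits at minus the original centre of voxel n-1-i
        m_origin[2] = -(dmap.origin[2] + (dmap.shape[2] - 1) * dmap.voxel_size)
        m_map = syn.DensityMap(m_grid, dmap.voxel_size, m_origin)
        m_axis = pl.HelicalAxis(axis.origin * np.array([1.0, 1, -1]),
                                axis.direction * np.array([1.0, 1, -1]))
        prof_m = pl.axial_register(flipped, m_map, m_axis, shift_range=50.0,
                                   step=2.0, sigma=5.0)
        # the mirrored axis direction flips the sign of the shift as well, so
        # joint mirroring leaves the correlation-vs-shift curve unchanged
        np.testing.assert_allclose(prof_m.cc, prof.cc, atol=1e-6)


class TestLatticeMetrics:
    def test_ideal_lattice_radii_equal_parameter(self, lattice_model, lattice):
        metrics = pl.lattice_metrics(lattice_model)
        np.testing.assert_allclose(metrics.radii.to_numpy(),
                                   lattice.params.radius, atol=1e-6)

    def test_radial_displacement_shifts_one_radius(self, lattice):
        from mig.ring_geometry import HelicalAxis

        moved = syn.displace_protofilament(lattice, 4, radial=3.0)
        lm = lattice_model_from_synthetic(moved)
        truth = HelicalAxis(lattice.axis_origin, lattice.axis_direction)
        metrics = pl.lattice_metrics(lm, axis=truth)
        base = lattice.params.radius
        assert metrics.radii[4] - base == pytest.approx(3.0, abs=1e-9)
        others = metrics.radii.drop(4) - base
        assert others.abs().max() < 1e-9

    def test_capped_assembly_offsets_zero_by_construction(self):
        cap_lat, cap_ring = syn.make_capped_assembly()
        lm = lattice_model_from_synthetic(cap_lat)
        metrics = pl.lattice_metrics(lm, cap_ring.model)
        assert metrics.gamma_alpha_offsets.abs().max() < 1e-6
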