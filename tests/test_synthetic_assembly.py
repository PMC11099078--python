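"""Generators: lattice arithmetic, ring interpolation, maps, projections, profiles."""

import numpy as np
import pytest

from mig import synthetic_assembly as syn
from mig.model_io import RigidTransform


class TestLatticeParams:
    def test_default_lateral_rise_matches_13pf_value(self):
        p = syn.LatticeParams()
        assert p.lateral_rise == pytest.approx(3 * 41 / 13)
        assert round(p.lateral_rise, 2) == 9.46
        assert p.twist_deg == pytest.approx(360 / 13)

    def test_ring_closure_arithmetic(self):
        p = syn.LatticeParams(n_pf=13)
        # accumulated axial offset around the ring equals the start number
        # of monomer repeats exactly (the lattice closes)
        assert p.n_pf * p.lateral_rise == pytest.approx(3 * p.monomer_repeat, abs=1e-12)
        assert p.twist_deg * p.n_pf == pytest.approx(360.0)

    @pytest.mark.parametrize("n_pf", [11, 12, 14, 15, 16])
    def test_closure_holds_for_any_pf_number(self, n_pf):
        p = syn.LatticeParams(n_pf=n_pf)
        assert p.n_pf * p.lateral_rise == pytest.approx(
            p.start_number * p.monomer_repeat, abs=1e-12
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.LatticeParams(n_pf=7)
        with pytest.raises(ValueError):
            syn.LatticeParams(start_number=2)


class TestMakeMtLattice:
    def test_single_subunit_at_radius(self):
        lat = syn.make_mt_lattice(syn.LatticeParams(n_pf=8, n_layers=1, radius=100.0))
        first = lat.subunit_centers[(1, 1)]
        np.testing.assert_allclose(first, [100.0, 0.0, 0.0], atol=1e-12)

    def test_subunit_grid_geometry(self):
        p = syn.LatticeParams(n_layers=4)
        lat = syn.make_mt_lattice(p)
        c = lat.subunit_centers
        # along-pf spacing is the monomer repeat, across-pf rise the lateral rise
        assert c[(1, 2)][2] - c[(1, 1)][2] == pytest.approx(p.monomer_repeat)
        assert c[(2, 1)][2] - c[(1, 1)][2] == pytest.approx(p.lateral_rise)
        r = np.linalg.norm(c[(5, 3)][:2])
        assert r == pytest.approx(p.radius)

    def test_species_alternate_along_pf_with_single_seam(self):
        lat = syn.make_mt_lattice(syn.LatticeParams(n_layers=4))
        names = {}
        for a in lat.model.atoms:
            names[(a.chain_id, a.residue_number)] = a.residue_name
        assert names[("A", 1)] == "ATB" and names[("A", 2)] == "BTB"
        assert names[("A", 3)] == "ATB"

    def test_determinism_and_seed_sensitivity(self):
        a = syn.make_mt_lattice(perturbation_sigma=1.0, seed=7)
        b = syn.make_mt_lattice(perturbation_sigma=1.0, seed=7)
        c = syn.make_mt_lattice(perturbation_sigma=1.0, seed=8)
        np.testing.assert_array_equal(a.model.positions, b.model.positions)
        assert np.abs(a.model.positions - c.model.positions).max() > 0


class TestMakeRing:
    def test_fully_closed_ring_separation_zero(self):
        ring = syn.make_ring(syn.RingParams(closure=1.0))
        inplane = ring.gamma_centers[:, :2]
        assert np.linalg.norm(inplane[13] - inplane[0]) < 1e-9

    def test_open_ring_separation_equals_default(self):
        ring = syn.make_ring(syn.RingParams(closure=0.0))
        inplane = ring.gamma_centers[:, :2]
        assert np.linalg.norm(inplane[13] - inplane[0]) == pytest.approx(47.0, abs=1e-9)

    def test_separation_strictly_decreasing_in_closure(self):
        seps = []
        for c in np.linspace(0, 1, 11):
            ring = syn.make_ring(syn.RingParams(closure=float(c)))
            inplane = ring.gamma_centers[:, :2]
            seps.append(np.linalg.norm(inplane[13] - inplane[0]))
        assert all(a > b for a, b in zip(seps, seps[1:]))

    def test_every_spoke_annotated_with_gamma_and_gcp(self):
        ring = syn.make_ring()
        ann = ring.model.annotation.spoke_of_chain
        gammas = {a.spoke for a in ann.values() if a.component == "gamma_tubulin"}
        gcps = {a.spoke for a in ann.values() if a.component != "gamma_tubulin"}
        assert gammas == set(range(1, 15)) and gcps == set(range(1, 15))

    def test_closure_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            syn.RingParams(closure=1.5)


class TestSynthesizeDensity:
    def test_single_atom_peak_at_atom(self, two_chain_model):
        sub = two_chain_model.subset([two_chain_model.atoms[0]])
        dm = syn.synthesize_density(sub, voxel_size=1.0, sigma=3.0)
        peak = np.unravel_index(np.argmax(dm.grid), dm.shape)
        voxel_pos = dm.origin + np.array(peak) * dm.voxel_size
        assert np.abs(voxel_pos - sub.atoms[0].position).max() <= dm.voxel_size

    def test_map_integral_matches_analytic_gaussian(self, two_chain_model):
        sigma, voxel = 4.0, 1.5
        dm = syn.synthesize_density(two_chain_model, voxel, sigma, pad=5 * sigma)
        total_mass = two_chain_model.masses.sum()
        expected_sum = total_mass * (2 * np.pi) ** 1.5 * sigma**3 / voxel**3
        assert dm.grid.sum() == pytest.approx(expected_sum, rel=0.01)

    def test_mirror_symmetric_atoms_give_mirror_map(self):
        from mig.model_io import AtomRecord, StructureModel

        atoms = [
            AtomRecord("C", "CA", "ALA", 1, "A", np.array([-10.0, 0, 0]), 12.0),
            AtomRecord("C", "CA", "ALA", 2, "A", np.array([10.0, 0, 0]), 12.0),
        ]
        m = StructureModel(atoms)
        # voxel centres chosen symmetric about x = 0
        dm = syn.synthesize_density(m, 2.0, 4.0, box=([-19, -8, -8], [21, 8, 8]))
        np.testing.assert_allclose(dm.grid, dm.grid[::-1, :, :], atol=1e-10)

    def test_box_excluding_all_atoms_is_an_error(self, two_chain_model):
        with pytest.raises(syn.EmptyMapError):
            syn.synthesize_density(two_chain_model, 2.0, 3.0,
                                   box=([500, 500, 500], [550, 550, 550]))

    def test_mrc_round_trip(self, two_chain_model, tmp_path):
        dm = syn.synthesize_density(two_chain_model, 2.0, 4.0)
        path = tmp_path / "map.mrc"
        dm.to_mrc(path)
        back = syn.DensityMap.from_mrc(path)
        assert back.voxel_size == pytest.approx(dm.voxel_size, rel=1e-6)
        np.testing.assert_allclose(back.grid, dm.grid, rtol=1e-6)
        np.testing.assert_allclose(back.origin, dm.origin, atol=1e-4)


class TestProjectImage:
    def test_single_atom_projects_to_2d_gaussian(self, two_chain_model):
        sub = two_chain_model.subset([two_chain_model.atoms[0]])
        img = syn.project_image(sub, "z", pixel_size=1.0, sigma=3.0)
        peak = np.unravel_index(np.argmax(img), img.shape)
        # symmetric about the peak
        assert img[peak[0] - 2, peak[1]] == pytest.approx(img[peak[0] + 2, peak[1]], rel=1e-6)

    def test_projection_conserves_mass_vs_map(self, two_chain_model):
        sigma = 6.0
        box = (two_chain_model.positions.min(0) - 5 * sigma,
               two_chain_model.positions.max(0) + 5 * sigma)
        dm = syn.synthesize_density(two_chain_model, 1.5, sigma, box=box)
        img = syn.project_image(two_chain_model, "y", pixel_size=1.5, sigma=sigma, box=box)
        map_total = dm.grid.sum() * dm.voxel_size**3
        img_total = img.sum() * 1.5**2
        assert img_total == pytest.approx(map_total, rel=1e-6)

    def test_axial_view_of_13pf_lattice_is_13fold_symmetric(self):
        lat = syn.make_mt_lattice(syn.LatticeParams(n_layers=3))
        half = 160.0
        box = ([-half, -half, -40.0], [half, half, 160.0])
        img = syn.project_image(lat.model, "z", pixel_size=2.0, sigma=6.0, box=box)
        rotated_model = lat.model.transformed(
            RigidTransform.about_axis((0, 0, 1), 360.0 / 13)
        )
        rot = syn.project_image(rotated_model, "z", pixel_size=2.0, sigma=6.0, box=box)
        cc = np.corrcoef(img.ravel(), rot.ravel())[0, 1]
        assert cc >= 0.999


class TestFluorescenceProfiles:
    def test_flat_profile_at_unit_enrichment(self):
        pset = syn.make_fluorescence_profiles(syn.SyntheticProfileParams(
            n_filaments=3, enrichment=1.0, noise_sigma=0.0))
        for p in pset:
            np.testing.assert_allclose(p.probe, 1.0)

    def test_window_ratio_exact_without_noise(self):
        pset = syn.make_fluorescence_profiles(syn.SyntheticProfileParams(
            n_filaments=2, enrichment=3.0, noise_sigma=0.0))
        p = pset.profiles[0]
        mask = np.abs(p.positions_um - p.anchor_um) <= pset.end_window_um
        assert p.probe[mask].mean() / p.probe[~mask].mean() == pytest.approx(3.0)

    def test_sample_count_and_step(self):
        pset = syn.make_fluorescence_profiles(syn.SyntheticProfileParams(
            n_filaments=1, length_um=1.3, step_um=0.13, noise_sigma=0.0))
        assert len(pset.profiles[0].positions_um) == 11

    def test_seeded_determinism(self):
        a = syn.make_fluorescence_profiles(syn.SyntheticProfileParams(seed=3, n_filaments=4))
        b = syn.make_fluorescence_profiles(syn.SyntheticProfileParams(seed=3, n_filaments=4))
        np.testing.assert_array_equal(a.profiles[2].probe, b.profiles[2].probe)


class TestGroundTruthMetadata:
    def test_generators_emit_axis_and_truth(self):
        lat = syn.make_mt_lattice()
        np.testing.assert_allclose(lat.axis_direction, [0, 0, 1])
        assert lat.seam_interface == (13, 1)
        ring = syn.make_ring()
        assert ring.gamma_centers.shape == (14, 3)
        pset = syn.make_fluorescence_profiles()
        assert pset.true_enrichment == 3.0
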