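"""Structural observables: profiles, regions, depths and orientations."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from emulsiphase.droplet import SPECIES_MASSES, DropletFrame, DropletTrajectory
from emulsiphase.errors import (
    BoundaryEstimationError,
    MissingSpeciesError,
)
from emulsiphase.synthetic_data import AngleLaws, Law, SpeciesSpec, sample_trajectory
from emulsiphase.trajectory_analysis import (
    RadialProfile,
    RegionBoundaries,
    angle_distribution,
    droplet_com,
    estimate_regions,
    joint_angle_distribution,
    orientation_angles,
    orientation_records,
    oxygen_distances,
    radial_profile,
    region_fractions,
    surfactant_profiles,
)

from conftest import place_molecule


def _toy_frame(coords, species="OLE", label="COM"):
    n = len(coords)
    return DropletFrame(np.array([species] * n, dtype=object), np.arange(n),
                        np.array([label] * n, dtype=object), np.asarray(coords, float),
                        np.full(n, SPECIES_MASSES[(species, label)]))


class TestDropletCom:
    def test_symmetric_frame_centred_at_origin(self):
        fr = _toy_frame([[3, 0, 0], [-3, 0, 0], [0, 4, 0], [0, -4, 0]])
        np.testing.assert_allclose(droplet_com(fr), 0.0, atol=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        fr = _toy_frame(rng.normal(size=(50, 3)))
        shift = np.array([10.0, 0.0, 0.0])
        np.testing.assert_allclose(droplet_com(fr.translated(shift)),
                                   droplet_com(fr) + shift, atol=1e-12)

    def test_matches_naive_mass_weighted_loop(self, small_traj):
        fr = small_traj[0]
        m = fr.mask("OLE")
        num = np.zeros(3)
        tot = 0.0
        for xyz, w in zip(fr.coords[m], fr.mass[m]):
            num += w * xyz
            tot += w
        np.testing.assert_allclose(droplet_com(fr), num / tot, atol=1e-12)

    def test_missing_oil_raises(self):
        fr = _toy_frame([[0, 0, 31.0]], species="HOH", label="O")
        with pytest.raises(MissingSpeciesError):
            droplet_com(fr)


class TestRadialProfile:
    def test_single_radius_occupies_one_bin(self):
        spec = SpeciesSpec(n_oleic=64, n_water=10,
                           antioxidant_radial_law=Law.delta(31.5), seed=2)
        traj = sample_trajectory(spec, 3)
        prof = radial_profile(traj, "GAL", bin_width=1.0)
        nz = np.nonzero(prof.density)[0]
        assert nz.size == 1
        assert prof.bin_edges[nz[0]] <= 31.5 < prof.bin_edges[nz[0] + 1]
        assert prof.density[nz[0]] == pytest.approx(1.0, rel=1e-12)  # 1/bin_width

    def test_matches_hand_tallied_histogram(self, small_traj):
        two = DropletTrajectory(small_traj.frames[:2])
        prof = radial_profile(two, "GAL", bin_width=2.0)
        radii = []
        for fr in two:
            c = droplet_com(fr)
            for mol in fr.molecule_ids("GAL"):
                xyz = fr.molecule_coords("GAL", mol)
                m = fr.mass[fr.mask("GAL") & (fr.mol_id == mol)]
                com = m @ xyz / m.sum()
                radii.append(np.linalg.norm(com - c))
        counts, _ = np.histogram(radii, bins=prof.bin_edges)
        np.testing.assert_allclose(prof.density, counts / (len(radii) * 2.0),
                                   atol=1e-12)

    @pytest.mark.parametrize("species", ["OLE", "GAL", "HOH", "TW80:RNG",
                                         "TW80:EOH", "TW80:TAIL"])
    def test_densities_integrate_to_one(self, small_traj, species):
        prof = radial_profile(small_traj, species, bin_width=1.0)
        assert (prof.density * prof.bin_width).sum() == pytest.approx(1.0, abs=1e-9)

    def test_volume_corrected_variant_integrates_to_one(self, small_traj):
        prof = radial_profile(small_traj, "HOH", bin_width=1.0, volume_corrected=True)
        assert (prof.density * prof.bin_width).sum() == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_mode_recovered(self, small_traj):
        prof = radial_profile(small_traj, "GAL", bin_width=1.0)
        assert abs(prof.mode() - 31.0) <= 1.5  # mode bin contains the generating mean

    def test_surfactant_sites_layered(self, small_traj):
        profs = surfactant_profiles(small_traj)
        order = [profs[s].mode() for s in ("TAIL", "RNG", "EOH")]
        assert order[0] < order[1] < order[2]


class TestEstimateRegions:
    def test_step_function_toy_profiles_exact(self):
        edges = np.arange(61.0)
        oleic = np.zeros(60)
        oleic[:20] = 1.0 / 20.0  # uniform per-A density on [0, 20]
        water = np.zeros(60)
        water[37:] = 1.0 / 23.0  # uniform on [37, 60]
        b = estimate_regions(RadialProfile("OLE", edges, oleic, 1000),
                             RadialProfile("HOH", edges, water, 1000))
        assert b.core_radius == 20.0
        assert b.interface_thickness == 17.0

    def test_generator_round_trip_within_one_bin(self, small_traj):
        ole = radial_profile(small_traj, "OLE", 1.0)
        hoh = radial_profile(small_traj, "HOH", 1.0)
        b = estimate_regions(ole, hoh)
        assert abs(b.core_radius - 20.0) <= 1.0
        assert abs(b.interface_thickness - 17.0) <= 1.0

    def test_rising_water_profile_rejected(self):
        edges = np.arange(41.0)
        oleic = np.zeros(40)
        oleic[:20] = 1.0 / 20.0
        rising = np.arange(40, dtype=float)
        rising /= rising.sum()  # still climbing at the box edge
        with pytest.raises(BoundaryEstimationError):
            estimate_regions(RadialProfile("OLE", edges, oleic, 100),
                             RadialProfile("HOH", edges, rising, 100))


class TestRegionFractions:
    BOUNDS = RegionBoundaries(20.0, 17.0)

    def test_one_molecule_per_region(self):
        fr = _toy_frame([[1, 0, 0], [-1, 0, 0]])  # oil core defining the COM
        gal = []
        for i, r in enumerate((5.0, 25.0, 50.0)):
            gal.append(_toy_frame([[0, 0, r]], species="HOH", label="O"))
        species = np.concatenate([fr.species] + [g.species for g in gal])
        mols = np.concatenate([fr.mol_id, [10], [11], [12]])
        labels = np.concatenate([fr.label] + [g.label for g in gal])
        coords = np.vstack([fr.coords] + [g.coords for g in gal])
        mass = np.concatenate([fr.mass] + [g.mass for g in gal])
        frame = DropletFrame(species, mols, labels, coords, mass)
        traj = DropletTrajectory([frame])
        pcts = region_fractions(traj, self.BOUNDS, species="HOH")
        assert pcts == pytest.approx((100 / 3, 100 / 3, 100 / 3), abs=1e-9)

    def test_delta_placement_fully_interfacial(self):
        spec = SpeciesSpec(n_oleic=100, n_water=20,
                           antioxidant_radial_law=Law.delta(31.0), seed=6)
        traj = sample_trajectory(spec, 5)
        assert region_fractions(traj, self.BOUNDS) == pytest.approx((0.0, 100.0, 0.0))

    def test_gaussian_occupancy_matches_generating_masses(self, small_traj):
        # generating law: Gaussian(31, 6); boundaries at 20 / 37 A
        p_core = norm.cdf((20.0 - 31.0) / 6.0)
        p_aq = 1.0 - norm.cdf((37.0 - 31.0) / 6.0)
        p_int = 1.0 - p_core - p_aq
        pcts = region_fractions(small_traj, self.BOUNDS)
        n = 8 * len(small_traj)
        for got, p in zip(pcts, (p_core, p_int, p_aq)):
            tol = 4.0 * 100.0 * math.sqrt(p * (1 - p) / n)  # 4-sigma CLT band
            assert abs(got - 100.0 * p) < tol

    def test_percentages_sum_to_100(self, small_traj):
        assert sum(region_fractions(small_traj, self.BOUNDS)) == pytest.approx(
            100.0, abs=1e-9)


class TestOxygenDistances:
    def test_para_axis_radial_ordering(self, template):
        # alpha = 180 deg: the O4 -> C7 axis points away from the COM,
        # i.e. the para hydroxyl O4 points at the oil core
        spec = SpeciesSpec(
            n_oleic=100, n_water=20,
            antioxidant_radial_law=Law.delta(31.0),
            antioxidant_angle_laws=AngleLaws(alpha=Law.delta(180.0)),
            seed=8)
        traj = sample_trajectory(spec, 10)
        d = oxygen_distances(traj)
        assert d.loc["O4", "mean_A"] < d.loc["O1", "mean_A"]
        assert d.loc["O4", "mean_A"] < d.loc["O2", "mean_A"]

    def test_single_frame_has_zero_spread(self):
        spec = SpeciesSpec(n_oleic=50, n_water=20, n_antioxidant=1, seed=4)
        traj = sample_trajectory(spec, 1)
        d = oxygen_distances(traj)
        assert (d["sd_A"] == 0.0).all()

    def test_matches_naive_per_atom_loop(self, small_traj):
        d = oxygen_distances(small_traj)
        for label in ("O0", "O4"):
            pool = []
            for fr in small_traj:
                c = droplet_com(fr)
                sel = fr.mask("GAL") & (fr.label == label)
                pool.extend(np.linalg.norm(fr.coords[sel] - c, axis=1))
            assert d.loc[label, "mean_A"] == pytest.approx(np.mean(pool), abs=1e-12)
            assert d.loc[label, "sd_A"] == pytest.approx(np.std(pool), abs=1e-12)


class TestOrientationAngles:
    def test_para_axis_aligned_with_radial_vector(self, template):
        # place the molecule so O4 -> C7 points from the COM position toward
        # the origin: alpha must be 0
        pos = np.array([0.0, 0.0, 31.0])
        rot = Rotation.align_vectors([-pos / 31.0], [template.a_axis])[0].as_matrix()
        fr = place_molecule(template, rot, pos)
        rec = orientation_angles(fr, 100)
        assert rec.alpha == pytest.approx(0.0, abs=1e-6)

    def test_ring_parallel_to_surface_gives_gamma_90(self, template):
        pos = np.array([0.0, 0.0, 31.0])
        rot = Rotation.align_vectors([[0, 0, 1]], [template.normal])[0].as_matrix()
        fr = place_molecule(template, rot, pos)
        rec = orientation_angles(fr, 100)
        assert rec.gamma == pytest.approx(90.0, abs=1e-6)

    def test_random_rotations_match_rotation_matrix_oracle(self, template):
        rng = np.random.default_rng(12)
        for _ in range(300):
            rot = Rotation.random(random_state=rng)
            pos = rng.normal(size=3)
            pos *= (25.0 + 10.0 * rng.random()) / np.linalg.norm(pos)
            fr = place_molecule(template, rot.as_matrix(), pos)
            rec = orientation_angles(fr, 100)
            r_hat = -pos / np.linalg.norm(pos)

            def ang(u, v):
                return math.degrees(math.acos(np.clip(
                    np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

            alpha = ang(r_hat, rot.apply(template.a_axis))
            beta = ang(r_hat, rot.apply(template.b_axis))
            gamma = 90.0 - min(ang(r_hat, rot.apply(template.normal)),
                               180.0 - ang(r_hat, rot.apply(template.normal)))
            assert rec.alpha == pytest.approx(alpha, abs=1e-9)
            assert rec.beta == pytest.approx(beta, abs=1e-9)
            assert rec.gamma == pytest.approx(gamma, abs=1e-7)

    def test_gamma_agrees_with_in_plane_projection_route(self, template):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rot = Rotation.random(random_state=rng)
            pos = rng.normal(size=3)
            pos *= 30.0 / np.linalg.norm(pos)
            fr = place_molecule(template, rot.as_matrix(), pos)
            rec = orientation_angles(fr, 100)
            r_hat = -pos / np.linalg.norm(pos)
            n = rot.apply(template.normal)
            proj = r_hat - np.dot(r_hat, n) * n
            gamma2 = math.degrees(math.acos(np.clip(
                np.linalg.norm(proj), -1, 1)))
            assert rec.gamma == pytest.approx(gamma2, abs=1e-7)

    def test_rigid_motion_invariance(self, small_traj):
        fr = small_traj[0]
        rot = Rotation.from_euler("zyx", [31.0, -12.0, 55.0], degrees=True).as_matrix()
        center = droplet_com(fr)
        moved = fr.rotated(rot, about=center).translated([5.0, -3.0, 2.0])
        for mol in fr.molecule_ids("GAL"):
            a = orientation_angles(fr, int(mol))
            b = orientation_angles(moved, int(mol))
            assert b.alpha == pytest.approx(a.alpha, abs=1e-9)
            assert b.beta == pytest.approx(a.beta, abs=1e-9)
            assert b.gamma == pytest.approx(a.gamma, abs=1e-9)
            assert b.com_radius == pytest.approx(a.com_radius, abs=1e-9)


class TestAngleDistributions:
    def test_delta_alpha_yields_single_peak_bin(self):
        spec = SpeciesSpec(
            n_oleic=80, n_water=20,
            antioxidant_radial_law=Law.delta(31.0),
            antioxidant_angle_laws=AngleLaws(alpha=Law.delta(80.0),
                                             beta=Law.delta(100.0)),
            seed=13)
        traj = sample_trajectory(spec, 10)
        dist = angle_distribution(traj, "alpha", bin_width=3.0)
        assert len(dist.maxima) == 1
        assert dist.maxima[0] == 79.5  # centre of the 3-degree bin holding 80

    def test_unit_integral_all_angles(self, small_traj):
        for name in ("alpha", "beta", "gamma"):
            dist = angle_distribution(small_traj, name, 3.0)
            w = dist.bin_edges[1] - dist.bin_edges[0]
            assert (dist.density * w).sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_tallied_histogram(self, delta_traj):
        recs = orientation_records(delta_traj)
        gammas = [r.gamma for r in recs]
        dist = angle_distribution(delta_traj, "gamma", 5.0)
        counts, _ = np.histogram(gammas, bins=dist.bin_edges)
        np.testing.assert_allclose(dist.density, counts / (len(gammas) * 5.0),
                                   atol=1e-12)


class TestJointAngles:
    def test_two_component_mixture_recovers_both_maxima(self):
        laws = AngleLaws(components=(
            (0.5, Law.delta(55.5), Law.delta(64.5)),
            (0.5, Law.delta(82.5), Law.delta(154.5)),
        ))
        spec = SpeciesSpec(n_oleic=80, n_water=20,
                           antioxidant_radial_law=Law.delta(31.0),
                           antioxidant_angle_laws=laws, seed=19)
        traj = sample_trajectory(spec, 30)
        joint = joint_angle_distribution(traj, bin_width=3.0)
        tops = {(a, b) for a, b, _ in joint.maxima[:2]}
        assert tops == {(55.5, 64.5), (82.5, 154.5)}
        assert len(joint.maxima) == 2

    def test_single_component_single_maximum(self, delta_traj):
        joint = joint_angle_distribution(delta_traj, bin_width=3.0)
        assert len(joint.maxima) == 1
        assert joint.maxima[0][:2] == (55.5, 64.5)

    def test_matches_naive_double_loop_binning(self, delta_traj):
        recs = orientation_records(delta_traj)
        joint = joint_angle_distribution(delta_traj, bin_width=10.0)
        n_bins = 18
        counts = np.zeros((n_bins, n_bins))
        for r in recs:
            i = min(int(r.alpha // 10.0), n_bins - 1)
            j = min(int(r.beta // 10.0), n_bins - 1)
            counts[i, j] += 1
        np.testing.assert_allclose(joint.density,
                                   counts / (len(recs) * 100.0), atol=1e-12)

    def test_unit_mass(self, small_traj):
        joint = joint_angle_distribution(small_traj, 3.0)
        assert joint.density.sum() * 9.0 == pytest.approx(1.0, abs=1e-9)
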