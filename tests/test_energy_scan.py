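"""Screened-Coulomb/LJ energies, collective variables, bias potential and
the metadynamics scan + rescoring against brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from petnano.constants import COULOMB_CONSTANT, KB
from petnano.core import Atom, MolecularSystem
from petnano.energy import (EnergyModel, PairEnergy, RigidBody, RigidPose,
                            lj_pair, pose_energy, screened_coulomb)
from petnano.metadynamics import (HillStore, ScanConfig,
                                  collective_variables, metadynamics_scan,
                                  rescore_and_select)
from petnano.synth import generate_toy_complex


def charged_atom(i, q, pos, element="C"):
    return Atom(i, element, np.asarray(pos, dtype=float), charge=q)


class TestScreenedCoulomb:
    def test_zero_charge_gives_zero(self):
        model = EnergyModel()
        for r in (0.1, 0.5, 3.0):
            assert screened_coulomb(0.0, 1.0, r, model) == 0.0

    def test_infinite_screening_length_recovers_coulomb(self):
        model = EnergyModel(kappa=math.inf)
        for r in (0.2, 1.0, 5.0):
            expected = COULOMB_CONSTANT / (model.epsilon_r * r)
            assert screened_coulomb(1.0, 1.0, r, model) == pytest.approx(
                expected, rel=1e-6)

    def test_screening_at_one_debye_length(self):
        model = EnergyModel()
        bare = EnergyModel(kappa=math.inf)
        r = model.kappa
        ratio = (screened_coulomb(1.0, 1.0, r, model)
                 / screened_coulomb(1.0, 1.0, r, bare))
        assert ratio == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            screened_coulomb(1.0, 1.0, 0.0, EnergyModel())


class TestLennardJones:
    def test_zero_at_sigma_and_minimum_depth(self):
        model = EnergyModel(lj_scale=0.1)
        sigma, epsilon = model.lj_params["C"]
        assert lj_pair("C", "C", sigma, model) == pytest.approx(0.0, abs=1e-12)
        r_min = 2.0 ** (1.0 / 6.0) * sigma
        assert lj_pair("C", "C", r_min, model) == pytest.approx(
            -0.1 * epsilon)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="LJ"):
            lj_pair("C", "Xx", 0.3, EnergyModel())

    def test_lorentz_berthelot_mixing(self):
        model = EnergyModel(lj_scale=1.0)
        (s1, e1), (s2, e2) = model.lj_params["C"], model.lj_params["O"]
        r_min = 2.0 ** (1.0 / 6.0) * 0.5 * (s1 + s2)
        assert lj_pair("C", "O", r_min, model) == pytest.approx(
            -math.sqrt(e1 * e2))


class TestPoseEnergy:
    def _dimer(self):
        a = MolecularSystem([charged_atom(0, 0.5, (0, 0, 0)),
                             charged_atom(1, -0.3, (0.3, 0, 0), "O")])
        b = MolecularSystem([charged_atom(0, -0.2, (0, 0, 0)),
                             charged_atom(1, 0.4, (0, 0.3, 0), "O")])
        return a, b

    def test_far_separation_is_zero(self):
        a, b = self._dimer()
        pose = RigidPose(np.array([0, 0, 0, 1.0]), np.array([100.0, 0, 0]))
        coul, vdw = pose_energy(a, b, pose, EnergyModel())
        assert abs(coul) < 1e-6 and abs(vdw) < 1e-6

    def test_matches_pairwise_hand_sum(self):
        a, b = self._dimer()
        model = EnergyModel()
        pose = RigidPose(np.array([0, 0, 0, 1.0]), np.array([1.0, 0.2, 0.1]))
        coul, vdw = pose_energy(a, b, pose, model)
        body_b = RigidBody(b)
        moved = pose.apply(body_b.coords)
        body_a = RigidBody(a)
        expect_c = expect_v = 0.0
        for i in range(2):
            for j in range(2):
                r = float(np.linalg.norm(body_a.coords[i] - moved[j]))
                expect_c += screened_coulomb(body_a.charges[i],
                                             body_b.charges[j], r, model)
                expect_v += lj_pair(body_a.elements[i], body_b.elements[j],
                                    r, model)
        assert coul == pytest.approx(expect_c, rel=1e-10)
        assert vdw == pytest.approx(expect_v, rel=1e-10)

    def test_invariant_under_joint_rotation(self):
        a, b = self._dimer()
        model = EnergyModel()
        pose = RigidPose(np.array([0, 0, 0, 1.0]), np.array([0.9, 0.1, 0.0]))
        e0 = pose_energy(a, b, pose, model)
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 0.7])
        a2, b2 = a.copy(), b.copy()
        a2.set_positions(rot.apply(a.positions()))
        # rotating both bodies and the pose jointly leaves energy unchanged
        b2.set_positions(b.positions())
        quat_new = (rot * Rotation.from_quat(pose.rotation)).as_quat()
        pose2 = RigidPose(quat_new / np.linalg.norm(quat_new),
                          rot.apply(pose.translation))
        e1 = pose_energy(a2, b2, pose2, model)
        assert e0[0] == pytest.approx(e1[0], rel=1e-9)
        assert e0[1] == pytest.approx(e1[1], rel=1e-9)


class TestCollectiveVariables:
    def test_axis_poses(self):
        up = RigidPose(np.array([0, 0, 0, 1.0]), np.array([0, 0, 2.0]))
        theta, _phi = collective_variables(up)
        assert theta == pytest.approx(0.0)
        right = RigidPose(np.array([0, 0, 0, 1.0]), np.array([2.0, 0, 0]))
        theta, phi = collective_variables(right)
        assert theta == pytest.approx(math.pi / 2)
        assert phi == pytest.approx(0.0)

    def test_random_poses_match_trigonometric_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.normal(size=3) * 2.0
            if np.linalg.norm(t) < 1e-3:
                continue
            pose = RigidPose(np.array([0, 0, 0, 1.0]), t)
            theta, phi = collective_variables(pose)
            r = np.linalg.norm(t)
            assert theta == pytest.approx(math.acos(t[2] / r))
            assert phi == pytest.approx(math.atan2(t[1], t[0]))
            assert -math.pi < phi <= math.pi

    def test_coincident_centres_rejected(self):
        pose = RigidPose(np.array([0, 0, 0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError, match="coincident"):
            collective_variables(pose)


class TestBiasPotential:
    def test_empty_store_is_zero(self):
        assert HillStore().potential(1.0, 0.5) == 0.0

    def test_first_hill_has_base_height(self):
        hills = HillStore()
        height = hills.deposit(1.2, 0.3)
        assert height == pytest.approx(0.8)
        assert hills.potential(1.2, 0.3) == pytest.approx(0.8)

    def test_periodic_in_phi(self):
        hills = HillStore()
        hills.deposit(1.0, 3.0)
        for phi in (-2.5, 0.0, 3.1):
            assert hills.potential(1.0, phi) == pytest.approx(
                hills.potential(1.0, phi + 2 * math.pi), abs=1e-12)

    def test_well_tempered_heights_shrink_under_accumulated_bias(self):
        hills = HillStore()
        heights = [hills.deposit(1.0, 0.0) for _ in range(5)]
        assert all(b < a for a, b in zip(heights, heights[1:]))
        # expected rescaling of the second hill
        delta_t = (hills.bias_factor - 1) * hills.temperature
        assert heights[1] == pytest.approx(
            0.8 * math.exp(-0.8 / (KB * delta_t)))


class TestScan:
    def test_same_seed_identical_trajectory(self):
        protein, nano = generate_toy_complex(seed=1)
        config = ScanConfig(wall_distance=2.0, n_steps=500, seed=9)
        model = EnergyModel.scan_model()
        t1 = metadynamics_scan(protein, nano, model, config)
        t2 = metadynamics_scan(protein, nano, model, config)
        assert np.array_equal(
            np.array([p.translation for p in t1.poses]),
            np.array([p.translation for p in t2.poses]))
        assert t1.scaled_energy == t2.scaled_energy

    def test_lj_only_sphere_pair_sits_at_contact_distance(self):
        # one uncharged atom per body at low temperature: the visited
        # distance distribution peaks at the LJ minimum 2^(1/6) sigma
        a = MolecularSystem([charged_atom(0, 0.0, (0, 0, 0))])
        b = MolecularSystem([charged_atom(0, 0.0, (0, 0, 0))])
        model = EnergyModel(lj_scale=1.0)
        config = ScanConfig(wall_distance=1.0, n_steps=20000, seed=2,
                            temperature=10.0, translation_step=0.02)
        traj = metadynamics_scan(a, b, model, config)
        dists = np.array([np.linalg.norm(p.translation)
                          for p in traj.poses[2000:]])
        hist, edges = np.histogram(dists, bins=60, range=(0.3, 0.6))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        sigma = model.lj_params["C"][0]
        assert mode == pytest.approx(2 ** (1 / 6) * sigma, rel=0.05)

    def test_cv_coverage_of_the_sphere(self):
        protein, nano = generate_toy_complex(seed=0)
        config = ScanConfig(wall_distance=2.5, n_steps=20000, seed=0)
        traj = metadynamics_scan(protein, nano, EnergyModel.scan_model(),
                                 config)
        # 6 x 6 equal-area bins over (cos theta, phi)
        cos_t = np.cos([cv[0] for cv in traj.cvs])
        phi = np.array([cv[1] for cv in traj.cvs])
        h, _, _ = np.histogram2d(cos_t, phi, bins=6,
                                 range=[[-1, 1], [-math.pi, math.pi]])
        assert (h > 0).mean() >= 0.90

    def test_hill_heights_are_bounded_by_base_height(self):
        protein, nano = generate_toy_complex(seed=0)
        config = ScanConfig(wall_distance=2.0, n_steps=6000, seed=1)
        traj = metadynamics_scan(protein, nano, EnergyModel.scan_model(),
                                 config)
        assert traj.hill_log, "no hills deposited"
        assert all(h <= 0.8 + 1e-12 for _step, h in traj.hill_log)


class TestRescore:
    def test_single_pose_trajectory_returns_it(self):
        protein, nano = generate_toy_complex(seed=0)
        from petnano.metadynamics import ScanTrajectory
        traj = ScanTrajectory()
        pose = RigidPose(np.array([0, 0, 0, 1.0]), np.array([1.5, 0, 0]))
        traj.poses.append(pose)
        traj.scaled_energy.append(0.0)
        traj.bias.append(0.0)
        traj.cvs.append((1.0, 0.0))
        best, table = rescore_and_select(traj, protein, nano)
        assert np.array_equal(best.translation, pose.translation)
        assert table.shape == (1, 3)

    def test_empty_trajectory_rejected(self):
        from petnano.metadynamics import ScanTrajectory
        protein, nano = generate_toy_complex(seed=0)
        with pytest.raises(ValueError, match="empty"):
            rescore_and_select(ScanTrajectory(), protein, nano)

    def test_rescored_energies_differ_from_biased_ones(self):
        protein, nano = generate_toy_complex(seed=0)
        config = ScanConfig(wall_distance=2.0, n_steps=3000, seed=3)
        traj = metadynamics_scan(protein, nano, EnergyModel.scan_model(),
                                 config)
        assert traj.hill_log
        _best, table = rescore_and_select(traj, protein, nano)
        biased = np.array(traj.scaled_energy) + np.array(traj.bias)
        assert not np.allclose(table[:, 2], biased)

    def test_two_charge_system_matches_grid_search(self):
        # analytically transparent system: one +1e and one -1e atom
        a = MolecularSystem([charged_atom(0, 1.0, (0, 0, 0))])
        b = MolecularSystem([charged_atom(0, -1.0, (0, 0, 0))])
        rescoring = EnergyModel.rescoring_model()
        energy = PairEnergy(RigidBody(a), RigidBody(b), rescoring)
        quat = np.array([0, 0, 0, 1.0])
        grid_best = min(
            sum(energy(RigidPose(quat, d * r)))
            for r in np.linspace(0.25, 1.5, 100)
            for d in (np.array([0, 0, 1.0]), np.array([1.0, 0, 0])))
        config = ScanConfig(wall_distance=1.5, n_steps=20000, seed=11,
                            translation_step=0.02)
        traj = metadynamics_scan(a, b, EnergyModel.scan_model(), config)
        _best, table = rescore_and_select(traj, a, b)
        assert table[:, 2].min() <= grid_best + 1.0
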