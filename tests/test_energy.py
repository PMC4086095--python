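"""Interaction energy: closed forms, invariances, analytic derivatives."""

import numpy as np
import pytest

from pepsurf import energy
from pepsurf.energy import (EMIN_FACTOR, RMIN_FACTOR, InteractionEvaluator,
                            interaction_energy, pair_energy, rigid_gradient)
from pepsurf.geometry import RigidPose


def brute_force_energy(receptor, peptide, coords, cutoff):
    """Independent double-loop oracle using the scalar pair function."""
    p = receptor.params
    e = 0.0
    for i in range(len(coords)):
        for j in range(len(receptor.positions)):
            r = float(np.linalg.norm(coords[i] - receptor.positions[j]))
            if r > cutoff:
                continue
            ti, tj = peptide.type_ids[i], receptor.type_ids[j]
            e += pair_energy(r, p.pair(ti, tj),
                             peptide.charges[i], receptor.charges[j],
                             p.dielectric, p.coulomb_constant)
    return e


class TestPairEnergy:
    def test_closed_form_minimum(self):
        sigma, eps = 4.1, 2.3
        r = sigma * RMIN_FACTOR
        assert pair_energy(r, (sigma, eps, True)) == pytest.approx(
            -EMIN_FACTOR * eps, abs=1e-12)

    def test_zero_at_sigma(self):
        assert pair_energy(3.7, (3.7, 1.0, True)) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_neutral_pair_has_no_electrostatics(self):
        lj_only = pair_energy(5.0, (4.0, 1.0, True), 0.0, 0.0)
        with_q = pair_energy(5.0, (4.0, 1.0, True), 1.0, -1.0)
        assert with_q != lj_only
        assert pair_energy(5.0, (4.0, 1.0, True), 0.0, 1.0) == lj_only

    def test_repulsive_pair_nonnegative_everywhere(self):
        for r in np.linspace(0.05, 30.0, 400):
            assert pair_energy(float(r), (3.8, 1.0, False)) >= 0.0

    def test_repulsive_form_continuous_at_rmin(self):
        sigma = 3.8
        rmin = sigma * RMIN_FACTOR
        lo = pair_energy(rmin - 1e-8, (sigma, 1.0, False))
        hi = pair_energy(rmin + 1e-8, (sigma, 1.0, False))
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_softened_core_is_finite_and_linear(self):
        sigma = 3.8
        rc = 0.5 * sigma * RMIN_FACTOR
        e1 = pair_energy(0.2 * rc, (sigma, 1.0, True))
        e2 = pair_energy(0.4 * rc, (sigma, 1.0, True))
        e3 = pair_energy(0.6 * rc, (sigma, 1.0, True))
        assert np.isfinite([e1, e2, e3]).all()
        assert e2 - e1 == pytest.approx(e3 - e2, rel=1e-9)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(0.0, (3.8, 1.0, True))


class TestInteractionEnergy:
    def test_far_peptide_has_zero_energy(self, bead_model_factory):
        rec = bead_model_factory([[0, 0, 0], [3, 0, 0]])
        pep = bead_model_factory([[500, 0, 0]])
        assert interaction_energy(rec, pep, cutoff=20.0).total == 0.0

    def test_single_pair_equals_pair_energy(self, bead_model_factory,
                                            params):
        rec = bead_model_factory([[0, 0, 0]])
        pep = bead_model_factory([[5.2, 0, 0]])
        ti = params.type_index["APO_S"]
        expected = pair_energy(5.2, params.pair(ti, ti), 0, 0,
                               params.dielectric, params.coulomb_constant)
        assert interaction_energy(rec, pep, cutoff=20.0).total == \
            pytest.approx(expected, abs=1e-12)

    def test_breakdown_sums_to_total(self, bead_model_factory):
        rec = bead_model_factory([[0, 0, 0]], charges=[1.0])
        pep = bead_model_factory([[4.0, 1, 0]], charges=[-1.0])
        bd = interaction_energy(rec, pep, cutoff=20.0)
        assert bd.total == bd.lj + bd.elec
        assert bd.elec < 0

    @pytest.mark.parametrize("n_seed", range(5))
    def test_matches_brute_force_oracle(self, bead_model_factory, n_seed):
        rng = np.random.default_rng(n_seed)
        rec = bead_model_factory(rng.uniform(-10, 10, (20, 3)),
                                 charges=rng.choice([0, 0, 1, -1], 20))
        pep = bead_model_factory(rng.uniform(-10, 10, (10, 3)),
                                 charges=rng.choice([0, 0, 1, -1], 10))
        got = interaction_energy(rec, pep, cutoff=12.0).total
        want = brute_force_energy(rec, pep, pep.positions, 12.0)
        assert got == pytest.approx(want, abs=1e-9)

    def test_sparse_path_identical_to_dense(self, bead_model_factory):
        rng = np.random.default_rng(11)
        rec = bead_model_factory(rng.uniform(-15, 15, (40, 3)))
        pep = bead_model_factory(rng.uniform(-15, 15, (12, 3)))
        dense = InteractionEvaluator(rec, pep, 14.0)
        sparse = InteractionEvaluator(rec, pep, 14.0, force_sparse=True)
        bd1, g1 = dense.energy_grad(pep.positions)
        bd2, g2 = sparse.energy_grad(pep.positions)
        assert bd1.total == pytest.approx(bd2.total, abs=1e-9)
        assert np.allclose(g1, g2, atol=1e-9)

    def test_rigid_motion_invariance(self, bead_model_factory):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(5)
        rec_xyz = rng.uniform(-8, 8, (15, 3))
        pep_xyz = rng.uniform(-8, 8, (6, 3))
        e0 = interaction_energy(bead_model_factory(rec_xyz),
                                bead_model_factory(pep_xyz),
                                cutoff=50.0).total
        R = Rotation.from_rotvec([0.3, -1.1, 0.7])
        t = np.array([5.0, -2.0, 9.0])
        e1 = interaction_energy(
            bead_model_factory(R.apply(rec_xyz) + t),
            bead_model_factory(R.apply(pep_xyz) + t), cutoff=50.0).total
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_receptor_peptide_symmetry(self, bead_model_factory):
        rng = np.random.default_rng(6)
        a = bead_model_factory(rng.uniform(-6, 6, (9, 3)),
                               charges=rng.choice([0, 1, -1], 9))
        b = bead_model_factory(rng.uniform(-6, 6, (5, 3)),
                               charges=rng.choice([0, 1, -1], 5))
        assert interaction_energy(a, b, cutoff=40.0).total == pytest.approx(
            interaction_energy(b, a, cutoff=40.0).total, abs=1e-10)

    def test_cutoff_convergence(self, bead_model_factory):
        rng = np.random.default_rng(7)
        rec = bead_model_factory(rng.uniform(-10, 10, (25, 3)))
        pep = bead_model_factory(rng.uniform(-10, 10, (8, 3)))
        e50 = interaction_energy(rec, pep, cutoff=50.0).total
        e_all = interaction_energy(rec, pep, cutoff=1e6,
                                   all_pairs=True).total
        assert e50 == pytest.approx(e_all, abs=1e-6)


class TestRigidGradient:
    def test_symmetric_head_on_pair_has_zero_torque(self, bead_model_factory):
        rec = bead_model_factory([[0, 0, 0]])
        pep = bead_model_factory([[6, 0, 0]])
        g = rigid_gradient(rec, pep, cutoff=20.0)
        assert np.allclose(g.torque, 0.0, atol=1e-12)
        assert abs(g.force[0]) > 0

    def test_matches_finite_differences(self, bead_model_factory):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(8)
        qr = rng.choice([0, 1, -1], 12)
        qp = rng.choice([0, 1, -1], 5)
        rec = bead_model_factory(rng.uniform(-8, 8, (12, 3)), charges=qr)
        pep_xyz = rng.uniform(-8, 8, (5, 3))
        pep = bead_model_factory(pep_xyz, charges=qp)
        g = rigid_gradient(rec, pep, cutoff=60.0)
        h = 1e-5
        c = pep_xyz.mean(axis=0)

        def e_at(coords):
            return interaction_energy(
                rec, bead_model_factory(coords, charges=qp),
                cutoff=60.0).total

        for k in range(3):
            dv = np.zeros(3)
            dv[k] = h
            fd_force = -(e_at(pep_xyz + dv) - e_at(pep_xyz - dv)) / (2 * h)
            assert fd_force == pytest.approx(g.force[k], rel=1e-4, abs=1e-8)
            rv = np.zeros(3)
            rv[k] = h
            xp = Rotation.from_rotvec(rv).apply(pep_xyz - c) + c
            xm = Rotation.from_rotvec(-rv).apply(pep_xyz - c) + c
            fd_torque = -(e_at(xp) - e_at(xm)) / (2 * h)
            assert fd_torque == pytest.approx(g.torque[k], rel=1e-4,
                                              abs=1e-8)

    def test_pose_argument_matches_direct_coordinates(self,
                                                      bead_model_factory):
        rng = np.random.default_rng(9)
        rec = bead_model_factory(rng.uniform(-8, 8, (10, 3)))
        pep_xyz = rng.uniform(-8, 8, (6, 3))
        pep = bead_model_factory(pep_xyz)
        pose = RigidPose(tuple(rng.normal(size=4)), (1.0, -2.0, 0.5))
        moved = bead_model_factory(pose.apply(pep_xyz))
        e1 = interaction_energy(rec, pep, pose, cutoff=40.0).total
        e2 = interaction_energy(rec, moved, cutoff=40.0).total
        assert e1 == pytest.approx(e2, abs=1e-10)
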