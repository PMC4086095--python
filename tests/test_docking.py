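"""Docking stage: radii, start placement, orientations, minimization."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from pepsurf import docking, energy
from pepsurf.docking import (DockedPose, DockSettings, generate_orientations,
                             generate_start_points, merge_and_rank,
                             minimize_pose, peptide_radius)
from pepsurf.energy import EnergyBreakdown, RMIN_FACTOR
from pepsurf.geometry import RigidPose


class TestPeptideRadius:
    def test_single_bead_radius_zero(self, bead_model_factory):
        assert peptide_radius(bead_model_factory([[1, 2, 3]])) == 0.0

    def test_two_beads_half_separation(self, bead_model_factory):
        m = bead_model_factory([[0, 0, 0], [10, 0, 0]])
        assert peptide_radius(m) == pytest.approx(5.0)

    def test_matches_brute_force_scan(self, bead_model_factory):
        rng = np.random.default_rng(0)
        xyz = rng.normal(scale=4, size=(30, 3))
        m = bead_model_factory(xyz)
        c = xyz.mean(axis=0)
        brute = max(float(np.linalg.norm(x - c)) for x in xyz)
        assert peptide_radius(m) == pytest.approx(brute, abs=1e-12)


class TestStartPoints:
    def test_sphere_fixture_at_analytic_offset(self, sphere_receptor):
        starts = generate_start_points(sphere_receptor, radius=5.0,
                                       spacing=10.0)
        r = np.array([np.linalg.norm(s.position) for s in starts])
        # receptor beads on a 15 A sphere, peptide radius 5 -> offset 25
        assert np.all(np.abs(r - 25.0) <= 0.5)

    def test_neighbor_spacing_within_band(self, sphere_receptor):
        starts = generate_start_points(sphere_receptor, radius=5.0,
                                       spacing=10.0)
        pts = np.array([s.position for s in starts])
        d, _ = cKDTree(pts).query(pts, k=2)
        nn = d[:, 1]
        assert nn.min() >= 0.7 * 10.0
        assert nn.max() <= 1.5 * 10.0

    def test_doubling_spacing_quarters_count(self, sphere_receptor):
        n1 = len(generate_start_points(sphere_receptor, 5.0, 10.0))
        n2 = len(generate_start_points(sphere_receptor, 5.0, 20.0))
        assert 0.15 <= n2 / n1 <= 0.4

    def test_blind_coverage_no_large_angular_gap(self, sphere_receptor):
        starts = generate_start_points(sphere_receptor, 5.0, 10.0)
        pts = np.array([s.position for s in starts])
        u = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        # every direction on the sphere is within 2*spacing/R of a start
        probe = 25.0 * np.asarray(
            __import__("pepsurf.geometry",
                       fromlist=["fibonacci_sphere"]).fibonacci_sphere(500))
        pu = probe / np.linalg.norm(probe, axis=1, keepdims=True)
        cosang = np.clip(pu @ u.T, -1, 1)
        gap = np.arccos(cosang.max(axis=1))
        assert gap.max() <= 2 * 10.0 / 25.0

    def test_degenerate_receptor_rejected(self, bead_model_factory):
        with pytest.raises(ValueError):
            generate_start_points(bead_model_factory([[0, 0, 0]]), 5.0, 10.0)

    def test_deterministic(self, sphere_receptor):
        a = generate_start_points(sphere_receptor, 5.0, 10.0)
        b = generate_start_points(sphere_receptor, 5.0, 10.0)
        assert len(a) == len(b)
        assert all(np.array_equal(x.position, y.position)
                   for x, y in zip(a, b))


class TestOrientations:
    def test_default_count_is_260_unit_quaternions(self):
        q = generate_orientations(260)
        assert q.shape == (260, 4)
        assert np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-9)

    def test_single_orientation_is_identity(self):
        q = generate_orientations(1)
        assert Rotation.from_quat(q[0]).magnitude() == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_orientations_pairwise_distinct(self):
        q = generate_orientations(260)
        rots = Rotation.from_quat(q)
        # minimum pairwise rotation angle strictly positive
        min_ang = np.inf
        for i in range(0, 260, 13):
            ang = (rots[i].inv() * rots).magnitude()
            ang[i] = np.inf
            min_ang = min(min_ang, ang.min())
        assert min_ang > 1e-3


class TestMinimizePose:
    def test_two_bead_pair_reaches_closed_form_separation(
            self, bead_model_factory, params):
        rec = bead_model_factory([[0.0, 0.0, 0.0]])
        pep = bead_model_factory([[5.5, 0.0, 0.0]])
        settings = DockSettings(cutoff=30.0, gtol=1e-6, maxiter=500)
        dp = minimize_pose(rec, pep, RigidPose.identity(anchor=(5.5, 0, 0)),
                           settings)
        sep = np.linalg.norm(dp.pose.apply(pep.positions)[0])
        ti = params.type_index["APO_S"]
        sigma = params.sigma_table[ti, ti]
        assert sep == pytest.approx(sigma * RMIN_FACTOR, abs=1e-2)

    def test_start_at_minimum_stays_put(self, bead_model_factory, params):
        ti = params.type_index["APO_S"]
        sigma = params.sigma_table[ti, ti]
        x0 = sigma * RMIN_FACTOR
        rec = bead_model_factory([[0.0, 0.0, 0.0]])
        pep = bead_model_factory([[x0, 0.0, 0.0]])
        dp = minimize_pose(rec, pep, RigidPose.identity(anchor=(x0, 0, 0)),
                           DockSettings(cutoff=30.0, gtol=1e-6))
        moved = np.linalg.norm(dp.pose.apply(pep.positions)[0]
                               - pep.positions[0])
        assert moved <= 1e-2

    def test_descent_property_random_starts(self, bead_model_factory):
        rng = np.random.default_rng(42)
        rec = bead_model_factory(rng.uniform(-8, 8, (30, 3)))
        pep = bead_model_factory(rng.uniform(-2, 2, (5, 3)))
        ev = energy.InteractionEvaluator(rec, pep, 25.0)
        c0 = pep.positions.mean(axis=0)
        settings = DockSettings(cutoff=25.0)
        for _ in range(25):
            q = rng.normal(size=4)
            t = rng.uniform(-12, 12, 3)
            start = RigidPose(tuple(q), tuple(t), anchor=tuple(c0))
            e_start = ev.energy(start.apply(pep.positions)).total
            dp = minimize_pose(rec, pep, start, settings, evaluator=ev)
            assert dp.energy.total <= e_start + 1e-9

    def test_stored_energy_matches_recomputation(self, bead_model_factory):
        rng = np.random.default_rng(1)
        rec = bead_model_factory(rng.uniform(-8, 8, (20, 3)))
        pep = bead_model_factory(rng.uniform(-2, 2, (4, 3)))
        start = RigidPose.identity(anchor=tuple(pep.positions.mean(axis=0)))
        dp = minimize_pose(rec, pep, start, DockSettings(cutoff=25.0))
        again = energy.interaction_energy(rec, pep, dp.pose,
                                          cutoff=25.0).total
        assert dp.energy.total == pytest.approx(again, abs=1e-6)


@pytest.fixture(scope="module")
def planted():
    from pepsurf.evaluate import make_synthetic_complex
    return make_synthetic_complex(seed=3, peptide_seq="ATVS",
                                  outer_radius=8.0)


class TestDockConformer:

    def test_best_pose_lands_in_planted_groove(self, planted):
        settings = DockSettings(spacing=14.0, n_orientations=24,
                                cutoff=25.0, gtol=0.01, maxiter=300)
        poses = docking.dock_conformer(planted.receptor_model,
                                       planted.peptide_free, settings)
        assert len(poses) <= \
            len(generate_start_points(
                planted.receptor_model,
                peptide_radius(planted.peptide_free), 14.0)) * 24
        energies = [dp.energy.total for dp in poses]
        assert energies == sorted(energies)
        top = poses[0]
        cen = top.pose.apply(
            planted.peptide_free.reduced.positions).mean(axis=0)
        assert np.linalg.norm(cen - planted.planted_centroid) < 5.0

    def test_parallel_equals_serial(self, planted):
        settings = DockSettings(spacing=18.0, n_orientations=4,
                                cutoff=25.0, gtol=0.02, maxiter=200)
        serial = docking.dock_conformer(planted.receptor_model,
                                        planted.peptide_free, settings)
        settings2 = DockSettings(spacing=18.0, n_orientations=4,
                                 cutoff=25.0, gtol=0.02, maxiter=200,
                                 workers=2)
        par = docking.dock_conformer(planted.receptor_model,
                                     planted.peptide_free, settings2)
        assert len(serial) == len(par)
        for a, b in zip(serial, par):
            assert a.sort_key == b.sort_key
            assert a.pose.quat == b.pose.quat
            assert a.pose.translation == b.pose.translation


def _pose(e, cid=0, sid=0, oid=0):
    return DockedPose(pose=RigidPose.identity(),
                      energy=EnergyBreakdown(e, 0.0),
                      conformer_id=cid, start_id=sid, orientation_id=oid)


class TestMergeAndRank:
    def test_merges_sorted(self):
        merged = merge_and_rank([[_pose(-5), _pose(-1)], [_pose(-3)]])
        assert [p.energy.total for p in merged] == [-5, -3, -1]

    def test_single_list_unchanged(self):
        lst = [_pose(-2), _pose(-1)]
        assert merge_and_rank([lst]) == lst

    def test_ties_broken_by_provenance(self):
        a = _pose(-1.0, cid=1, sid=0)
        b = _pose(-1.0, cid=0, sid=5)
        assert merge_and_rank([[a], [b]]) == [b, a]

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_and_rank([[], []])
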