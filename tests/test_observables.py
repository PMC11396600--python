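"""Structural observables against closed forms and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from luciflux import observables as obs
from luciflux import synthdata as sd
from luciflux.trajio import Topology, Trajectory


def rand_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def horn_quaternion_rmsd(mobile, reference):
    """Independent superposition oracle: Horn's closed-form quaternion method."""
    X = mobile - mobile.mean(axis=0)
    Y = reference - reference.mean(axis=0)
    M = X.T @ Y
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(N)[-1]
    msd = (np.sum(X ** 2) + np.sum(Y ** 2) - 2 * lam) / X.shape[0]
    return np.sqrt(max(msd, 0.0))


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = obs.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_recovers_known_rigid_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        R0 = rand_rotation(rng)
        moved = pts @ R0.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = obs.kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R @ R0, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_quaternion_oracle_on_random_clouds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            _, _, rmsd = obs.kabsch_superpose(a, b)
            assert rmsd == pytest.approx(horn_quaternion_rmsd(a, b), abs=1e-9)

    def test_point_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            obs.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdSeries:
    def test_reference_frame_has_zero_rmsd(self):
        traj = sd.gaussian_ensemble(np.random.default_rng(0).normal(size=(5, 3)) * 10,
                                    np.full(5, 0.4), None,
                                    sd.GeneratorConfig(seed=1, n_frames=20))
        s = obs.rmsd_series(traj, reference_frame=0, selection="all")
        assert s.values[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_body_copies_give_zeros(self):
        rng = np.random.default_rng(3)
        base = rng.normal(scale=10, size=(6, 3))
        frames = [base]
        for _ in range(4):
            frames.append(base @ rand_rotation(rng).T + rng.normal(size=3))
        traj = Trajectory(Topology.point_sites(6), np.stack(frames))
        s = obs.rmsd_series(traj, selection="all")
        assert np.allclose(s.values, 0.0, atol=1e-9)

    def test_fitted_rmsd_never_exceeds_unfitted(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(scale=10, size=(20, 3))
        traj = sd.gaussian_ensemble(ref, np.full(20, 1.0), None,
                                    sd.GeneratorConfig(seed=5, n_frames=50))
        fitted = obs.rmsd_series(traj, selection="all").values
        raw = np.sqrt(np.mean(np.sum(
            (traj.coords - traj.coords[0][None]) ** 2, axis=2), axis=1))
        assert np.all(fitted <= raw + 1e-12)

    def test_gaussian_ensemble_matches_no_fit_oracle(self):
        """Mean best-fit RMSD tracks the brute-force no-superposition RMSD
        (fitting absorbs only ~6 rigid-body DOF out of 3N)."""
        n = 40
        rng = np.random.default_rng(6)
        ref = rng.normal(scale=15, size=(n, 3))
        sigma = 0.5
        traj = sd.gaussian_ensemble(ref, np.full(n, sigma), None,
                                    sd.GeneratorConfig(seed=7, n_frames=2000))
        fitted = obs.rmsd_series(traj, selection="all").values[1:]
        raw = np.sqrt(np.mean(np.sum(
            (traj.coords[1:] - traj.coords[0][None]) ** 2, axis=2), axis=1))
        assert np.all(fitted <= raw)
        # fitting absorbs only ~6 of 3N degrees of freedom: the fitted mean
        # tracks the brute-force value closely
        assert np.mean(fitted) == pytest.approx(np.mean(raw), rel=0.06)
        # deviation from frame 0 is sigma*sqrt(2) per axis -> RMSD ~ sigma*sqrt(6)
        assert np.mean(raw) == pytest.approx(sigma * np.sqrt(6), rel=0.15)

    def test_empty_selection_rejected(self):
        traj = Trajectory(Topology.point_sites(3), np.zeros((2, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            obs.rmsd_series(traj, selection=[])


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert obs.radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_two_angstrom_apart(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert obs.radius_of_gyration(pts) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(scale=5, size=(50, 3))
        com = pts.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1)))
        assert obs.radius_of_gyration(pts) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=5, size=(12, 3))
        moved = pts @ rand_rotation(rng).T + rng.normal(scale=100, size=3)
        assert obs.radius_of_gyration(moved) == pytest.approx(
            obs.radius_of_gyration(pts), abs=1e-9)


class TestRmsf:
    def test_static_trajectory_all_zeros(self):
        coords = np.repeat(np.random.default_rng(0).normal(size=(1, 5, 3)), 4, axis=0)
        traj = Trajectory(Topology.point_sites(5), coords)
        assert np.allclose(obs.rmsf(traj, selection="all", superpose=False), 0.0)

    def test_gaussian_ensemble_recovers_sigma_sqrt3(self):
        site_sd = np.array([0.2, 0.5, 0.8, 1.1])
        rng = np.random.default_rng(9)
        ref = rng.normal(scale=20, size=(4, 3))
        traj = sd.gaussian_ensemble(ref, site_sd, None,
                                    sd.GeneratorConfig(seed=10, n_frames=10_000))
        fl = obs.rmsf(traj, selection="all", superpose=False)
        assert np.allclose(fl, site_sd * np.sqrt(3), rtol=0.05)

    def test_frame_order_invariance(self):
        traj = sd.gaussian_ensemble(np.zeros((3, 3)), np.ones(3), None,
                                    sd.GeneratorConfig(seed=11, n_frames=100))
        shuffled = Trajectory(traj.topology,
                              traj.coords[np.random.default_rng(0).permutation(100)])
        a = obs.rmsf(traj, selection="all", superpose=False)
        b = obs.rmsf(shuffled, selection="all", superpose=False)
        assert np.allclose(a, b)

    def test_single_frame_rejected(self):
        traj = Trajectory(Topology.point_sites(3), np.zeros((1, 3, 3)))
        with pytest.raises(ValueError):
            obs.rmsf(traj)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        total, _ = obs.sasa(np.zeros((1, 3)), ["C"], probe_radius=1.4,
                            n_sphere_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(exact, rel=0.005)

    def test_distant_atoms_add_isolated_areas(self):
        total, per = obs.sasa(np.array([[0.0, 0, 0], [100.0, 0, 0]]), ["C", "N"])
        iso_c = 4 * np.pi * (1.7 + 1.4) ** 2
        iso_n = 4 * np.pi * (1.55 + 1.4) ** 2
        assert total == pytest.approx(iso_c + iso_n, rel=0.005)

    def test_monotone_decrease_on_approach(self):
        areas = []
        for d in (7.0, 6.0, 5.0, 4.0, 3.0):
            total, _ = obs.sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), ["C", "C"])
            areas.append(total)
        assert areas == sorted(areas, reverse=True)

    def test_caged_atom_is_buried(self):
        """A small atom inside a shell of overlapping large spheres has zero
        accessible area; verified against a Monte-Carlo point-rejection oracle."""
        rng = np.random.default_rng(12)
        # 26-point cage on a radius-2.0 shell of radius-2.0 spheres around H
        dirs = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                         for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)], dtype=float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), 2.0 * dirs])
        elements = ["H"] + ["X"] * 26
        override = {"X": 2.0}
        total, per = obs.sasa(coords, elements, radii_override=override,
                              n_sphere_points=500)
        assert per[0] == pytest.approx(0.0, abs=1e-12)
        # oracle: random points on the H accessible sphere all fall inside a cage sphere
        pts = rng.normal(size=(2000, 3))
        pts = (1.2 + 1.4) * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        d = np.linalg.norm(pts[:, None, :] - coords[None, 1:], axis=2)
        assert np.all(d.min(axis=1) < 2.0 + 1.4)

    def test_unknown_element_without_override_rejected(self):
        with pytest.raises(KeyError, match="radii_override"):
            obs.sasa(np.zeros((1, 3)), ["Zz"])


class TestDccm:
    def test_identical_displacement_gives_plus_one(self):
        rng = np.random.default_rng(13)
        disp = rng.normal(size=(200, 1, 3))
        ref = np.array([[0.0, 0, 0], [30.0, 0, 0]])
        coords = ref[None] + np.repeat(disp, 2, axis=1)
        traj = Trajectory(Topology.point_sites(2), coords)
        C = obs.dccm(traj, selection="all", superpose=False)
        assert C[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_antiphase_displacement_gives_minus_one(self):
        rng = np.random.default_rng(14)
        disp = rng.normal(size=(200, 1, 3))
        ref = np.array([[0.0, 0, 0], [30.0, 0, 0]])
        coords = ref[None] + np.concatenate([disp, -disp], axis=1)
        traj = Trajectory(Topology.point_sites(2), coords)
        C = obs.dccm(traj, selection="all", superpose=False)
        assert C[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_zero_variance_site_yields_nan_not_zero(self):
        coords = np.zeros((50, 2, 3))
        coords[:, 1] = np.random.default_rng(0).normal(size=(50, 3))
        traj = Trajectory(Topology.point_sites(2), coords)
        with pytest.warns(UserWarning, match="zero variance"):
            C = obs.dccm(traj, selection="all", superpose=False)
        assert np.isnan(C[0, 1]) and np.isnan(C[0, 0])
        assert C[1, 1] == 1.0

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_symmetric_unit_diagonal_bounded(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=3, size=(40, 6, 3)) + rng.normal(
            scale=20, size=(1, 6, 3))
        traj = Trajectory(Topology.point_sites(6), coords)
        C = obs.dccm(traj, selection="all", superpose=False)
        assert np.allclose(C, C.T, atol=1e-10)
        assert np.allclose(np.diag(C), 1.0)
        assert np.nanmax(np.abs(C)) <= 1 + 1e-10


class TestPocketDistance:
    def test_static_single_atom_groups(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 5.0
        traj = Trajectory(Topology.point_sites(2), coords)
        s = obs.pocket_distance(traj, [1], [2])
        assert np.allclose(s.values, 5.0)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(15)
        traj = Trajectory(Topology.point_sites(10), rng.normal(size=(6, 10, 3)))
        a = obs.pocket_distance(traj, [1, 2, 3], [8, 9, 10]).values
        b = obs.pocket_distance(traj, [8, 9, 10], [1, 2, 3]).values
        assert np.allclose(a, b)

    def test_matches_brute_force_centroids(self):
        rng = np.random.default_rng(16)
        traj = Trajectory(Topology.point_sites(8), rng.normal(scale=10, size=(5, 8, 3)))
        ga, gb = [1, 2, 3], [6, 7]
        s = obs.pocket_distance(traj, ga, gb).values
        ia = traj.topology.calpha_indices(ga)
        ib = traj.topology.calpha_indices(gb)
        for f in range(5):
            ca = traj.coords[f, ia].mean(axis=0)
            cb = traj.coords[f, ib].mean(axis=0)
            assert s[f] == pytest.approx(np.linalg.norm(ca - cb), abs=1e-12)

    def test_unresolvable_range_rejected(self):
        traj = Trajectory(Topology.point_sites(3), np.zeros((2, 3, 3)))
        with pytest.raises(KeyError):
            obs.pocket_distance(traj, [99], [1])


class TestHelixContent:
    def test_ideal_helix_interior_probability_one(self, ideal_helix):
        prob, frac = obs.helix_content(ideal_helix, range(1, 13))
        interior = [prob[r] for r in range(5, 9)]
        assert all(p == 1.0 for p in interior)
        assert frac[0] > 0.9

    def test_extended_strand_probability_zero(self, ideal_strand):
        prob, frac = obs.helix_content(ideal_strand, range(1, 13))
        assert all(p == 0.0 for p in prob.values())
        assert np.allclose(frac, 0.0)

    def test_alternating_frames_give_half(self, ideal_helix, ideal_strand):
        coords = np.concatenate([ideal_helix.coords, ideal_strand.coords,
                                 ideal_helix.coords, ideal_strand.coords])
        traj = Trajectory(ideal_helix.topology, coords)
        prob, _ = obs.helix_content(traj, range(5, 9))
        assert all(p == 0.5 for p in prob.values())

    def test_missing_backbone_excluded_with_warning(self, ideal_helix):
        topo = ideal_helix.topology
        keep = [i for i, a in enumerate(topo.atoms)
                if not (a.residue_number == 6 and a.name == "O")]
        from luciflux.trajio import Topology
        traj = Trajectory(Topology([topo.atoms[i] for i in keep]),
                          ideal_helix.coords[:, keep])
        with pytest.warns(UserWarning, match="excluded"):
            prob, _ = obs.helix_content(traj, range(1, 13))
        assert 6 not in prob
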