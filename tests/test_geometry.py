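"""Geometric operators: H-bonds, water bridges, planes, superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from uturn.geometry import (HBondCriteria, detect_hbond, detect_water_bridge,
                            fit_base_plane, hbond_series,
                            plane_atom_distance_series, superpose_and_rmsd)
from uturn.model_io import AtomRef


def _triple_frame(make_ens, donor, hydrogen, acceptor):
    atoms = [(14, "U", "N3", "N"), (14, "U", "H3", "H"), (17, "A", "OP2", "O")]
    return make_ens(atoms, np.array([donor, hydrogen, acceptor])).frame(0)


D = AtomRef(14, "N3")
H = AtomRef(14, "H3")
A = AtomRef(17, "OP2")


class TestHBond:
    @pytest.mark.parametrize("acceptor,expect_sat,expect_d,expect_ang", [
        ((0, 0, 2.9), True, 2.9, 180.0),     # linear, inside both thresholds
        ((0, 0, 3.5), False, 3.5, 180.0),    # distance boundary: strict <
    ])
    def test_distance_criterion(self, make_ens, acceptor, expect_sat,
                                expect_d, expect_ang):
        fr = _triple_frame(make_ens, (0, 0, 0), (0, 0, 1.0), acceptor)
        obs = detect_hbond(fr, D, H, A)
        assert obs.satisfied is expect_sat
        assert obs.distance == pytest.approx(expect_d)
        assert obs.angle == pytest.approx(expect_ang)

    def test_angle_boundary_is_strict(self, make_ens):
        # acceptor ~120 deg off the donor direction, inside distance range
        h = np.array([0, 0, 1.0])
        direction = np.array([np.sin(np.radians(60)), 0, np.cos(np.radians(60))])
        acc = h + 2.0 * direction
        fr = _triple_frame(make_ens, (0, 0, 0), h, acc)
        obs = detect_hbond(fr, D, H, A)
        assert obs.angle == pytest.approx(120.0, abs=1e-6)
        assert obs.distance < 3.5
        # the threshold is strict: a criterion set exactly at the observed
        # angle rejects, an epsilon below accepts
        at = HBondCriteria(3.5, obs.angle)
        below = HBondCriteria(3.5, obs.angle - 1e-9)
        assert not detect_hbond(fr, D, H, A, at).satisfied
        assert detect_hbond(fr, D, H, A, below).satisfied

    def test_degenerate_criteria_accept_anything(self, make_ens):
        rng = np.random.default_rng(11)
        crit = HBondCriteria(d_max=np.inf, angle_min=0.0)
        for _ in range(50):
            pts = rng.uniform(-8, 8, size=(3, 3))
            fr = _triple_frame(make_ens, *pts)
            assert detect_hbond(fr, D, H, A, crit).satisfied

    def test_far_hydrogen_warns(self, make_ens):
        fr = _triple_frame(make_ens, (0, 0, 0), (0, 0, 2.0), (0, 0, 2.9))
        with pytest.warns(UserWarning, match="covalently"):
            detect_hbond(fr, D, H, A)

    def test_unresolvable_atom_names_reference(self, make_ens):
        fr = _triple_frame(make_ens, (0, 0, 0), (0, 0, 1.0), (0, 0, 2.9))
        with pytest.raises(KeyError, match="99:N3"):
            detect_hbond(fr, AtomRef(99, "N3"), H, A)

    def test_series_matches_scalar(self, make_ens):
        rng = np.random.default_rng(5)
        atoms = [(14, "U", "N3", "N"), (14, "U", "H3", "H"),
                 (17, "A", "OP2", "O")]
        coords = rng.uniform(-4, 4, size=(20, 3, 3))
        ens = make_ens(atoms, coords)
        dist, ang, sat = hbond_series(ens, D, H, A)
        with pytest.warns(UserWarning):
            for i, fr in enumerate(ens):
                obs = detect_hbond(fr, D, H, A)
                assert dist[i] == pytest.approx(obs.distance)
                assert ang[i] == pytest.approx(obs.angle)
                assert sat[i] == obs.satisfied


def _bridge_atoms(extra_waters=()):
    atoms = [(18, "U", "N3", "N"), (18, "U", "H3", "H"), (13, "U", "O2", "O")]
    for num in extra_waters:
        atoms += [(num, "HOH", "O", "O"), (num, "HOH", "H1", "H"),
                  (num, "HOH", "H2", "H")]
    return atoms


def _water_block(o, toward):
    o = np.asarray(o, dtype=float)
    u = (np.asarray(toward) - o) / np.linalg.norm(np.asarray(toward) - o)
    return [o, o + 0.97 * u, o + 0.97 * np.array([u[1], -u[0], 0.0])]


class TestWaterBridge:
    donor = (AtomRef(18, "N3"), AtomRef(18, "H3"))
    acceptor = AtomRef(13, "O2")

    def test_bridge_found(self, make_ens):
        o2 = np.array([5.7, 0, 0])
        wat = _water_block([2.9, 0, 0], o2)
        coords = [np.zeros(3), [1.0, 0, 0], o2] + wat
        fr = make_ens(_bridge_atoms([105]), np.array(coords)).frame(0)
        found = detect_water_bridge(fr, self.donor, self.acceptor)
        assert found is not None and found.residue_number == 105

    def test_no_water_in_range_returns_none(self, make_ens):
        wat = _water_block([30.0, 0, 0], [35.0, 0, 0])
        coords = [np.zeros(3), [1.0, 0, 0], [5.7, 0, 0]] + wat
        fr = make_ens(_bridge_atoms([105]), np.array(coords)).frame(0)
        assert detect_water_bridge(fr, self.donor, self.acceptor) is None

    def test_tie_break_prefers_smaller_residue_number(self, make_ens):
        o2 = np.array([5.7, 0, 0])
        w1 = _water_block([2.9, 0.2, 0], o2)
        w2 = _water_block([2.9, -0.2, 0], o2)
        coords = [np.zeros(3), [1.0, 0, 0], o2] + w1 + w2
        fr = make_ens(_bridge_atoms([105, 88]), np.array(coords)).frame(0)
        found = detect_water_bridge(fr, self.donor, self.acceptor)
        assert found.residue_number == 88

    def test_water_must_donate_not_just_touch(self, make_ens):
        # both water hydrogens point away from the acceptor: no bridge
        o = np.array([2.9, 0, 0])
        away = [o, o + [0, 0.97, 0], o + [0, -0.97, 0]]
        coords = [np.zeros(3), [1.0, 0, 0], [5.7, 0, 0]] + away
        fr = make_ens(_bridge_atoms([105]), np.array(coords)).frame(0)
        assert detect_water_bridge(fr, self.donor, self.acceptor) is None


def _flat_ring_atoms(resname="U"):
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    pts = []
    for i in range(6):
        a = np.radians(60 * i)
        pts.append([1.4 * np.cos(a), 1.4 * np.sin(a), 0.0])
    return ([(1, resname, n, n[0]) for n in names], np.array(pts))


class TestBasePlane:
    def test_flat_ring_exact(self, make_ens):
        atoms, pts = _flat_ring_atoms()
        plane = fit_base_plane(make_ens(atoms, pts[None]).frame(0), 1)
        assert abs(plane.normal[2]) == pytest.approx(1.0)
        assert plane.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self, make_ens, random_rigid):
        rng = np.random.default_rng(2)
        atoms, pts = _flat_ring_atoms()
        pts = pts + rng.normal(0, 0.05, pts.shape)
        q, t, _ = random_rigid(seed=4)
        p1 = fit_base_plane(make_ens(atoms, pts[None]).frame(0), 1)
        p2 = fit_base_plane(make_ens(atoms, (pts @ q.T + t)[None]).frame(0), 1)
        assert p2.rms_residual == pytest.approx(p1.rms_residual, abs=1e-9)
        np.testing.assert_allclose(np.abs(q @ p1.normal), np.abs(p2.normal),
                                   atol=1e-9)

    def test_beats_random_candidate_planes(self, make_ens):
        rng = np.random.default_rng(9)
        atoms, pts = _flat_ring_atoms()
        pts = pts + rng.normal(0, 0.05, pts.shape)
        plane = fit_base_plane(make_ens(atoms, pts[None]).frame(0), 1)
        centered = pts - pts.mean(axis=0)
        normals = rng.normal(size=(10_000, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        residuals = np.sqrt(np.mean((centered @ normals.T) ** 2, axis=0))
        assert plane.rms_residual <= residuals.min() + 1e-12

    def test_matches_dense_grid_minimization(self, make_ens):
        # 10-atom puckered instance; brute-force grid over orientations
        rng = np.random.default_rng(17)
        names = ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9", "C1'"]
        pts = rng.uniform(-2, 2, size=(10, 3)) * [1, 1, 0.1]
        atoms = [(1, "A", n, n[0]) for n in names]
        plane = fit_base_plane(make_ens(atoms, pts[None]).frame(0), 1,
                               ring_atoms=names)
        centered = pts - pts.mean(axis=0)
        theta = np.linspace(0, np.pi, 400)
        phi = np.linspace(0, 2 * np.pi, 800)
        tt, pp = np.meshgrid(theta, phi)
        normals = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                            np.cos(tt)], axis=-1).reshape(-1, 3)
        grid_best = np.sqrt(np.mean((centered @ normals.T) ** 2, axis=0)).min()
        assert plane.rms_residual == pytest.approx(grid_best, abs=1e-3)

    def test_collinear_atoms_rejected(self, make_ens):
        atoms = [(1, "U", n, n[0]) for n in ["N1", "C2", "N3"]]
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_base_plane(make_ens(atoms, pts[None]).frame(0), 1,
                           ring_atoms=["N1", "C2", "N3"])


class TestPlaneDistanceSeries:
    def test_atom_on_normal_constant(self, make_ens):
        atoms, pts = _flat_ring_atoms()
        atoms = atoms + [(2, "A", "OP2", "O")]
        target = np.array([0.3, -0.2, 3.0])
        coords = np.vstack([pts, target[None]])
        ens = make_ens(atoms, np.stack([coords, coords, coords]))
        series = plane_atom_distance_series(ens, 1, AtomRef(2, "OP2"))
        np.testing.assert_allclose(series.distances, 3.0, atol=1e-12)
        assert series.median == pytest.approx(3.0)
        assert series.sd == pytest.approx(0.0, abs=1e-12)

    def test_even_count_median_is_midpoint(self, make_ens):
        atoms, pts = _flat_ring_atoms()
        atoms = atoms + [(2, "A", "OP2", "O")]
        f1 = np.vstack([pts, [[0, 0, 2.0]]])
        f2 = np.vstack([pts, [[0, 0, 4.0]]])
        ens = make_ens(atoms, np.stack([f1, f2]))
        series = plane_atom_distance_series(ens, 1, AtomRef(2, "OP2"))
        assert series.median == pytest.approx(3.0)


class TestSuperposition:
    def _noisy_ensemble(self, make_ens, n_frames, sigma, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(-10, 10, size=(40, 3))
        atoms = [(i // 4 + 1, "U", f"C{i % 4 + 1}", "C") for i in range(40)]
        coords = base[None] + rng.normal(0, sigma, size=(n_frames, 40, 3))
        return make_ens(atoms, coords)

    def test_identical_frames_zero_rmsd(self, make_ens):
        ens = self._noisy_ensemble(make_ens, 1, 0.0)
        ens = ens.with_coords(np.repeat(ens.coords, 5, axis=0))
        result = superpose_and_rmsd(ens)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in result.per_residue_rmsd.values())

    def test_rotated_copies_zero_rmsd(self, make_ens, random_rigid):
        ens = self._noisy_ensemble(make_ens, 1, 0.0)
        frames = [ens.coords[0]]
        for seed in range(1, 5):
            q, t, _ = random_rigid(seed=seed)
            frames.append(ens.coords[0] @ q.T + t)
        result = superpose_and_rmsd(ens.with_coords(np.stack(frames)))
        assert max(result.per_residue_rmsd.values()) < 1e-9

    def test_gaussian_noise_recovers_sigma_sqrt3(self, make_ens):
        sigma = 0.1
        ens = self._noisy_ensemble(make_ens, 1500, sigma, seed=42)
        result = superpose_and_rmsd(ens)
        overall = float(np.sqrt((result.atom_rmsd ** 2).mean()))
        assert overall == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_kabsch_agrees_with_scipy_rotation_oracle(self):
        rng = np.random.default_rng(1)
        from uturn.geometry import _kabsch

        p = rng.uniform(-5, 5, size=(12, 3))
        rot_true = Rotation.random(random_state=3)
        q = rot_true.apply(p) + [1.0, -2.0, 0.5]
        r, mc, tc = _kabsch(p, q)
        est, _ = Rotation.align_vectors(q - q.mean(axis=0), p - p.mean(axis=0))
        np.testing.assert_allclose(r, est.as_matrix(), atol=1e-9)
        np.testing.assert_allclose((p - mc) @ r.T + tc, q, atol=1e-9)

    def test_empty_subset_rejected(self, make_ens):
        ens = self._noisy_ensemble(make_ens, 3, 0.1)
        with pytest.raises(ValueError, match="nonempty"):
            superpose_and_rmsd(ens, subset=[])
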