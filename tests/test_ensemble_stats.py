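import numpy as np
import pytest

from clampmd.ensemble_stats import (DegenerateClusteringError, HBondSpec,
                                    cluster_representative, dccm, detect_hbond,
                                    hbond_occupancy)
from clampmd.geometry import DescriptorSeries
from clampmd.structure_io import SelectionSpec
from conftest import make_structure, make_trajectory


def _ca_chain(n=4, spread=6.0):
    atoms = [("CA", "GLY", r, "C",
              (spread * r, 1.5 * ((r * 3) % 5), 2.0 * ((r * 7) % 3)))
             for r in range(1, n + 1)]
    return make_structure(atoms)


def _horn_fit(mobile, ref, w):
    """Independent quaternion (Horn) superposition used by the DCCM oracle."""
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(0)
    rc = (w[:, None] * ref).sum(0)
    a = mobile - mc
    b = ref - rc
    M = (w[:, None, None] * np.einsum("ai,aj->aij", a, b)).sum(0)
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    vals, vecs = np.linalg.eigh(K)
    q = vecs[:, np.argmax(vals)]
    qw, qx, qy, qz = q
    R = np.array([
        [1 - 2 * (qy * qy + qz * qz), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
        [2 * (qx * qy + qz * qw), 1 - 2 * (qx * qx + qz * qz), 2 * (qy * qz - qx * qw)],
        [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx * qx + qy * qy)]])
    return lambda x: (x - mc) @ R.T + rc


class TestDCCM:
    def test_in_phase_unity(self):
        s = _ca_chain(6)
        frames = []
        for f in range(6):
            x = s.coord.copy()
            x[0, 0] += 0.3 * (-1) ** f
            x[1, 0] += 0.3 * (-1) ** f
            frames.append(x)
        # fit on the static (non-collinear) residues so the superposition
        # is the identity
        mat = dccm(make_trajectory(s, np.array(frames)),
                   fit_selection=SelectionSpec.residues((3, 6)))
        assert mat.matrix[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_anti_phase_minus_one(self):
        s = _ca_chain(6)
        frames = []
        for f in range(6):
            x = s.coord.copy()
            x[0, 0] += 0.3 * (-1) ** f
            x[1, 0] -= 0.3 * (-1) ** f
            frames.append(x)
        mat = dccm(make_trajectory(s, np.array(frames)),
                   fit_selection=SelectionSpec.residues((3, 6)))
        assert mat.matrix[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_double_loop_oracle(self):
        s = _ca_chain(4)
        rng = np.random.default_rng(2)
        frames = s.coord[None] + 0.4 * rng.standard_normal((6, 4, 3))
        traj = make_trajectory(s, frames)
        mat = dccm(traj)
        # oracle: replicate the documented procedure (fit to frame 0,
        # average, refit to average) with an independent Horn fit, then a
        # plain double loop over residues
        w = s.mass
        fitted = np.array([_horn_fit(f, frames[0], w)(f) for f in frames])
        avg = fitted.mean(axis=0)
        fitted = np.array([_horn_fit(f, avg, w)(f) for f in frames])
        dx = fitted - fitted.mean(axis=0)
        n = 4
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                num = np.mean([dx[f, i] @ dx[f, j] for f in range(6)])
                vi = np.mean([dx[f, i] @ dx[f, i] for f in range(6)])
                vj = np.mean([dx[f, j] @ dx[f, j] for f in range(6)])
                expected[i, j] = num / np.sqrt(vi * vj)
        np.testing.assert_allclose(mat.matrix, expected, atol=1e-10)

    def test_invariant_under_global_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        s = _ca_chain(5)
        rng = np.random.default_rng(9)
        frames = s.coord[None] + 0.3 * rng.standard_normal((8, 5, 3))
        traj = make_trajectory(s, frames)
        base = dccm(traj).matrix
        moved = np.array([
            f @ Rotation.from_euler("xyz", [10 * k, -5 * k, 3 * k],
                                    degrees=True).as_matrix().T + k
            for k, f in enumerate(frames)])
        np.testing.assert_allclose(dccm(make_trajectory(s, moved)).matrix,
                                   base, atol=1e-7)

    def test_matrix_contract(self):
        s = _ca_chain(5)
        rng = np.random.default_rng(21)
        frames = s.coord[None] + 0.3 * rng.standard_normal((7, 5, 3))
        mat = dccm(make_trajectory(s, frames))
        m = mat.matrix
        np.testing.assert_allclose(m, m.T, atol=0)
        np.testing.assert_allclose(np.diag(m), 1.0, atol=0)
        assert np.all(m >= -1) and np.all(m <= 1)

    def test_single_frame_rejected(self):
        s = _ca_chain(4)
        with pytest.raises(ValueError):
            dccm(make_trajectory(s, s.coord[None]))


def _hbond_structure(acceptor_xyz):
    atoms = [
        ("N", "GLY", 1, "N", (0.0, 0.0, 0.0)),
        ("H", "GLY", 1, "H", (1.0, 0.0, 0.0)),
        ("CA", "GLY", 1, "C", (-1.0, 1.0, 0.0)),
        ("O", "GLY", 2, "O", acceptor_xyz),
        ("CA", "GLY", 2, "C", (float(acceptor_xyz[0]) + 1.0, 1.0, 0.0)),
    ]
    return make_structure(atoms)


class TestHBond:
    def test_collinear_geometry_detected(self):
        s = _hbond_structure((2.8, 0.0, 0.0))
        spec = HBondSpec("G1-G2", 1, 2)
        assert detect_hbond(s, s.coord, spec)

    def test_distance_beyond_cutoff_rejected(self):
        s = _hbond_structure((5.0, 0.0, 0.0))
        assert not detect_hbond(s, s.coord, HBondSpec("G1-G2", 1, 2))

    @staticmethod
    def _acceptor_at_angle(dha_deg, heavy_dist=2.9):
        # D at origin, H at (1,0,0): placing A along direction
        # (cos(180-dha), sin(180-dha)) from H makes the D-H-A angle exactly
        # dha; solve |A - D| = heavy_dist for the H-A distance r
        phi = np.radians(180.0 - dha_deg)
        r = -np.cos(phi) + np.sqrt(np.cos(phi) ** 2 + heavy_dist ** 2 - 1.0)
        return (1.0 + r * np.cos(phi), r * np.sin(phi), 0.0)

    def test_angle_100_degrees_rejected_under_135_cutoff(self):
        s = _hbond_structure(self._acceptor_at_angle(100.0))
        d = np.linalg.norm(s.coord[3] - s.coord[0])
        assert d == pytest.approx(2.9, abs=1e-9)
        # verify the constructed D-H-A angle by explicit trigonometry
        v1 = s.coord[0] - s.coord[1]
        v2 = s.coord[3] - s.coord[1]
        ang = np.degrees(np.arccos(v1 @ v2 / np.linalg.norm(v1)
                                   / np.linalg.norm(v2)))
        assert ang == pytest.approx(100.0, abs=1e-9)
        assert not detect_hbond(s, s.coord, HBondSpec("G1-G2", 1, 2))
        # the same geometry passes once the cutoff drops below 100 degrees
        assert detect_hbond(s, s.coord,
                            HBondSpec("G1-G2", 1, 2, angle_cutoff=95.0))

    def test_heavy_only_mode_ignores_angle(self):
        s = _hbond_structure(self._acceptor_at_angle(100.0))
        assert detect_hbond(s, s.coord,
                            HBondSpec("G1-G2", 1, 2, mode="heavy-only"))

    def test_missing_residue_identified(self):
        s = _hbond_structure((2.8, 0.0, 0.0))
        with pytest.raises(KeyError, match="99"):
            detect_hbond(s, s.coord, HBondSpec("G1-G99", 1, 99))

    def test_occupancy_counts_exactly(self):
        on = _hbond_structure((2.8, 0.0, 0.0)).coord
        off = _hbond_structure((5.0, 0.0, 0.0)).coord
        s = _hbond_structure((2.8, 0.0, 0.0))
        frames = np.array([on if f in (0, 3, 7) else off for f in range(10)])
        occ = hbond_occupancy(make_trajectory(s, frames),
                              HBondSpec("G1-G2", 1, 2))
        assert occ.occupancy == 30.0
        assert list(np.nonzero(occ.mask)[0]) == [0, 3, 7]

    def test_permutation_leaves_occupancy_unchanged(self):
        on = _hbond_structure((2.8, 0.0, 0.0)).coord
        off = _hbond_structure((5.0, 0.0, 0.0)).coord
        s = _hbond_structure((2.8, 0.0, 0.0))
        frames = np.array([on, off, on, off, off])
        perm = frames[[4, 2, 0, 3, 1]]
        spec = HBondSpec("G1-G2", 1, 2)
        assert hbond_occupancy(make_trajectory(s, frames), spec).occupancy == \
               hbond_occupancy(make_trajectory(s, perm), spec).occupancy


class TestClusterRepresentative:
    def _series(self, values):
        return DescriptorSeries("RoG", "A", np.array(values, float))

    def test_separated_clusters(self):
        labels, reps = cluster_representative(
            self._series([1, 1, 1, 9, 9, 9]), k=2)
        assert list(labels) == [0, 0, 0, 1, 1, 1]
        assert list(reps) == [0, 3]

    def test_constant_series_single_cluster(self):
        labels, reps = cluster_representative(self._series([5.0] * 6), k=1)
        assert set(labels) == {0}
        assert reps[0] == 0

    def test_bimodal_matches_threshold_scan_oracle(self):
        rng = np.random.default_rng(31)
        vals = np.concatenate([rng.normal(2, 0.3, 10), rng.normal(8, 0.4, 10)])
        labels, _ = cluster_representative(self._series(vals), k=2)

        def wcss(mask):
            out = 0.0
            for m in (mask, ~mask):
                if m.any():
                    out += ((vals[m] - vals[m].mean()) ** 2).sum()
            return out

        got = wcss(labels == 0)
        # optimal 1-D 2-partition is induced by a threshold; scan all of them
        order = np.sort(vals)
        best = min(wcss(vals <= t) for t in (order[:-1] + order[1:]) / 2)
        assert got == pytest.approx(best, abs=1e-9)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(DegenerateClusteringError):
            cluster_representative(self._series([1.0, 1.0, 2.0]), k=3)

    def test_invariant_to_order_preserving_relabeling(self):
        vals = np.array([1.0, 1.2, 5.0, 5.5, 9.1, 9.0])
        labels, _ = cluster_representative(self._series(vals), k=3)
        labels2, _ = cluster_representative(self._series(vals * 2 + 1), k=3)
        assert list(labels) == list(labels2)
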