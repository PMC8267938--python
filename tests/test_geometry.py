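import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from clampmd.geometry import (DescriptorSeries, dihedral, group_distance,
                              radius_of_gyration, rmsd, rmsf, superpose)
from clampmd.structure_io import SelectionSpec
from conftest import PHE_ATOMS, make_structure, make_trajectory


def brute_force_min_rmsd(mobile, reference, weights):
    """Independent superposition oracle: multi-stage scan over a fine Euler
    grid (equivalent to a quaternion grid over rotations)."""
    w = weights / weights.sum()
    mob = mobile - (w[:, None] * mobile).sum(0)
    ref = reference - (w[:, None] * reference).sum(0)

    def weighted_rmsd(mats):
        rotated = np.einsum("rij,aj->rai", mats, mob)
        d2 = ((rotated - ref) ** 2).sum(axis=2)
        return np.sqrt((d2 * w).sum(axis=1))

    best = np.zeros(3)
    span, step = 180.0, 6.0
    for _ in range(6):
        offsets = np.arange(-span, span + step / 2, step)
        aa, bb, cc = np.meshgrid(best[0] + offsets, best[1] + offsets,
                                 best[2] + offsets, indexing="ij")
        eulers = np.stack([aa.ravel(), bb.ravel(), cc.ravel()], axis=1)
        mats = Rotation.from_euler("zyz", eulers, degrees=True).as_matrix()
        vals = weighted_rmsd(mats)
        best = eulers[int(np.argmin(vals))]
        span, step = 1.5 * step, step / 8
    return float(vals.min())


class TestSuperpose:
    def test_identity(self):
        x = np.array(make_structure(PHE_ATOMS).coord)
        res = superpose(x, x)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-10)
        assert res.fit_rmsd == pytest.approx(0.0, abs=1e-10)

    def test_pure_translation_recovered(self):
        x = np.array(make_structure(PHE_ATOMS).coord)
        shifted = x + np.array([5.0, -2.0, 1.0])
        res = superpose(shifted, x)
        assert res.fit_rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.apply(shifted), x, atol=1e-8)

    def test_determinant_plus_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.standard_normal((5, 3))
            b = rng.standard_normal((5, 3))
            res = superpose(a, b)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_quaternion_grid_oracle(self):
        rng = np.random.default_rng(7)
        mob = rng.standard_normal((5, 3)) * 2.0
        ref = rng.standard_normal((5, 3)) * 2.0
        w = rng.uniform(1.0, 12.0, 5)
        res = superpose(mob, ref, weights=w)
        assert res.fit_rmsd == pytest.approx(
            brute_force_min_rmsd(mob, ref, w), abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            superpose(line[:2], line[:2])


class TestRMSD:
    def test_zero_for_identical(self):
        x = np.array(make_structure(PHE_ATOMS).coord)
        assert rmsd(x, x, fit=False) == 0.0

    def test_two_atom_closed_form(self):
        x = np.array([[1.0, 0, 0], [0.0, 0, 0]])
        y = np.zeros((2, 3))
        assert rmsd(x, y, masses=np.ones(2), fit=False) == pytest.approx(
            np.sqrt(0.5), abs=1e-12)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 3))
        y = rng.standard_normal((4, 3))
        m = rng.uniform(1.0, 16.0, 4)
        acc = 0.0
        for i in range(4):
            acc += m[i] * ((x[i] - y[i]) ** 2).sum()
        expected = np.sqrt(acc / m.sum())
        assert rmsd(x, y, masses=m, fit=False) == pytest.approx(
            expected, abs=1e-10)

    def test_symmetric_without_fit(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 6, 3))
        m = rng.uniform(1, 12, 6)
        assert rmsd(x, y, masses=m, fit=False) == pytest.approx(
            rmsd(y, x, masses=m, fit=False), abs=1e-12)

    def test_fit_removes_rigid_motion(self):
        x = np.array(make_structure(PHE_ATOMS).coord)
        R = Rotation.from_euler("xyz", [30, -60, 110], degrees=True).as_matrix()
        moved = x @ R.T + np.array([3.0, -7.0, 2.0])
        m = np.ones(len(x))
        assert rmsd(moved, x, masses=m, fit=True) == pytest.approx(0, abs=1e-8)

    def test_empty_selection_rejected(self):
        x = np.zeros((3, 3))
        with pytest.raises(ValueError):
            rmsd(x, x, selection=[], fit=False)


class TestRoG:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_equal_masses_half_separation(self):
        x = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert radius_of_gyration(x, masses=np.ones(2)) == pytest.approx(2.5)

    def test_matches_two_pass_loop_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((10, 3)) * 4
        m = rng.uniform(1, 16, 10)
        com = np.zeros(3)
        for i in range(10):
            com += m[i] * x[i]
        com /= m.sum()
        acc = sum(m[i] * ((x[i] - com) ** 2).sum() for i in range(10))
        assert radius_of_gyration(x, masses=m) == pytest.approx(
            np.sqrt(acc / m.sum()), abs=1e-10)

    def test_rigid_motion_invariant(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((8, 3))
        m = rng.uniform(1, 12, 8)
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = x @ R.T + 5.0
        assert radius_of_gyration(moved, masses=m) == pytest.approx(
            radius_of_gyration(x, masses=m), abs=1e-10)


class TestGroupDistance:
    def test_same_group_zero(self):
        x = np.array(make_structure(PHE_ATOMS).coord)
        m = np.ones(len(x))
        assert group_distance(x, [0, 1], [0, 1], m) == 0.0

    def test_three_four_five(self):
        x = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert group_distance(x, [0], [1], np.ones(2)) == pytest.approx(5.0)

    def test_empty_selection_names_preset(self):
        x = np.zeros((2, 3))
        with pytest.raises(ValueError, match="D1"):
            group_distance(x, [], [1], np.ones(2), preset="D1")

    def test_rigid_motion_invariant(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal((10, 3))
        m = rng.uniform(1, 16, 10)
        R = Rotation.from_euler("xyz", [45, 5, -30], degrees=True).as_matrix()
        d0 = group_distance(x, [0, 1, 2], [5, 6], m)
        d1 = group_distance(x @ R.T - 3.0, [0, 1, 2], [5, 6], m)
        assert d1 == pytest.approx(d0, abs=1e-10)


class TestDihedral:
    CIS = np.array([[1.0, 1.0, 0], [1.0, 0, 0], [-1.0, 0, 0], [-1.0, 1.0, 0]])
    TRANS = np.array([[1.0, 1.0, 0], [1.0, 0, 0], [-1.0, 0, 0], [-1.0, -1.0, 0]])

    def test_planar_cis_zero(self):
        assert dihedral(self.CIS, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_180(self):
        assert dihedral(self.TRANS, 0, 1, 2, 3) == pytest.approx(180.0)

    def test_range_reversal_and_mirror_symmetries(self):
        # a torsion is invariant under reversing the atom order and is
        # negated (mod 360) by a mirror reflection of the coordinates
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = rng.standard_normal((4, 3)) * 2
            try:
                a = dihedral(x, 0, 1, 2, 3)
            except ValueError:
                continue
            assert 0.0 <= a < 360.0
            assert dihedral(x, 3, 2, 1, 0) == pytest.approx(a, abs=1e-8)
            mirrored = x * np.array([1.0, 1.0, -1.0])
            b = dihedral(mirrored, 0, 1, 2, 3)
            assert (a + b) % 360.0 == pytest.approx(0.0, abs=1e-8) or \
                   (a + b) % 360.0 == pytest.approx(360.0, abs=1e-8)

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1.0, 0]])
        with pytest.raises(ValueError):
            dihedral(line, 0, 1, 2, 3)


class TestRMSF:
    def _base(self):
        atoms = [("CA", "GLY", r, "C",
                  (3.0 * r, 2.0 * ((r * 7) % 5), 1.5 * ((r * 3) % 4)))
                 for r in range(1, 11)]
        return make_structure(atoms)

    def test_static_trajectory_zero(self):
        s = self._base()
        traj = make_trajectory(s, np.repeat(s.coord[None], 4, axis=0))
        out = rmsf(traj)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_two_frame_alternation_closed_form(self):
        s = self._base()
        a = 0.8
        up, down = s.coord.copy(), s.coord.copy()
        up[4, 0] += a
        down[4, 0] -= a
        traj = make_trajectory(s, np.array([up, down, up, down]))
        # fit on the residues that do not move, so the fit is the identity
        fit = SelectionSpec.residues((1, 4), (7, 10))
        out = rmsf(traj, fit_selection=fit)
        assert out.values[4] == pytest.approx(a, abs=1e-10)
        others = np.delete(out.values, 4)
        np.testing.assert_allclose(others, 0.0, atol=1e-10)

    def test_global_translation_removed_by_fit(self):
        s = self._base()
        frames = [s.coord + np.array([0.0, 0, 0]), s.coord + np.array([4.0, 1, 2]),
                  s.coord + np.array([-2.0, 3, 0])]
        out = rmsf(make_trajectory(s, np.array(frames)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)


def test_descriptor_series_rejects_nonfinite():
    with pytest.raises(ValueError):
        DescriptorSeries("D1", "A", np.array([1.0, np.nan]))
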