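"""Alignment, kernel deformation and shape-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ssimfem.shape import (AnatomicalFrame, ControlGrid, MomentField,
                           RigidTransform, build_shape_matrix, deform,
                           fit_moments, icp_align, initial_align, kabsch,
                           make_control_grid)


def _frame(head=(24.0, 0.0, 62.0), neck=(0.4, 0.0, 0.2),
           shaft=(0.0, 0.0, 1.0)):
    return AnatomicalFrame(np.array(head), np.array(neck), np.array(shaft))


def _rotated_frame(frame, R, t):
    return AnatomicalFrame(R @ frame.head_centre + t, R @ frame.neck_axis,
                           R @ frame.shaft_axis)


class TestInitialAlign:
    def test_identity(self):
        f = _frame()
        T = initial_align(f, f)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-10)

    def test_recovers_known_motion(self):
        f = _frame()
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([5.0, 0.0, 0.0])
        moved = _rotated_frame(f, R, t)
        T = initial_align(moved, f)
        np.testing.assert_allclose(T.rotation, R.T, atol=1e-9)
        np.testing.assert_allclose(T.apply(moved.head_centre),
                                   f.head_centre, atol=1e-9)

    def test_antiparallel_neck_axes(self):
        """Neck axes anti-parallel: the resolved rotation is pi about an
        axis fixed by the shaft-alignment rule, and superposes both
        annotation axes."""
        f = _frame(neck=(1.0, 0.0, 0.0), shaft=(0.0, 0.0, 1.0))
        g = _frame(neck=(-1.0, 0.0, 0.0), shaft=(0.0, 0.0, 1.0))
        T = initial_align(g, f)
        np.testing.assert_allclose(T.rotation @ g.neck_axis, f.neck_axis,
                                   atol=1e-9)
        np.testing.assert_allclose(T.rotation @ g.shaft_axis, f.shaft_axis,
                                   atol=1e-9)
        assert np.isclose(np.trace(T.rotation), -1.0, atol=1e-9)  # pi turn

    def test_missing_annotations_rejected(self):
        with pytest.raises(ValueError, match="annotations"):
            initial_align(None, _frame())

    def test_degenerate_parallel_axes_rejected(self):
        with pytest.raises(ValueError, match="roll"):
            initial_align(_frame(neck=(0, 0, 1.0), shaft=(0, 0, 2.0)),
                          _frame())


class TestICP:
    def test_source_equals_target(self, rng):
        pts = rng.standard_normal((30, 3))
        T, rmsd, converged = icp_align(pts, pts)
        assert rmsd < 1e-12 and converged
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self, rng):
        pts = rng.standard_normal((200, 3)) * 10
        R = Rotation.from_euler("xyz", [4, -3, 6], degrees=True).as_matrix()
        t = np.array([0.5, -0.2, 0.9])
        src = pts @ R.T + t
        T, rmsd, _ = icp_align(src, pts)
        assert rmsd < 1e-8

    def test_single_step_matches_kabsch_oracle(self, rng):
        """One least-squares update under identity correspondence equals
        the closed-form solution from scipy's Rotation.align_vectors."""
        P = rng.standard_normal((8, 3))
        R = Rotation.from_euler("y", 25, degrees=True).as_matrix()
        Q = P @ R.T + np.array([1.0, 2.0, 3.0])
        T = kabsch(P, Q)
        rot_ref, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(T.rotation, rot_ref.as_matrix(),
                                   atol=1e-9)
        np.testing.assert_allclose(T.apply(P), Q, atol=1e-9)

    def test_rmsd_non_increasing_over_iterations(self, rng):
        pts = rng.standard_normal((100, 3)) * 5
        R = Rotation.from_euler("z", 20, degrees=True).as_matrix()
        src = pts @ R.T + [1, 0, 0]
        rmsds = []
        for it in range(1, 8):
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, rmsd, _ = icp_align(src, pts, max_iter=it)
            rmsds.append(rmsd)
        assert all(b <= a + 1e-9 for a, b in zip(rmsds, rmsds[1:]))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="4 points"):
            icp_align(rng.standard_normal((3, 3)),
                      rng.standard_normal((10, 3)))


class TestDeform:
    def grid(self):
        return ControlGrid(np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                           kernel_width=1.5)

    def test_zero_moments_identity(self, rng):
        pts = rng.standard_normal((10, 3))
        out = deform(pts, self.grid(), np.zeros((2, 3)))
        np.testing.assert_array_equal(out, pts)

    def test_coincident_point_unit_kernel(self):
        grid = ControlGrid(np.array([[1.0, 1.0, 1.0]]), kernel_width=2.0)
        out = deform(np.array([[1.0, 1.0, 1.0]]), grid,
                     np.array([[1.0, 0.0, 0.0]]))
        np.testing.assert_allclose(out, [[2.0, 1.0, 1.0]])

    def test_two_point_hand_computation(self):
        grid = self.grid()
        q = np.array([[1.0, 0.0, 0.0]])
        beta = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        k = np.exp(-1.0 / 1.5 ** 2)   # both control points 1 mm away
        expected = q + np.array([[k * 1.0, k * 2.0, 0.0]])
        np.testing.assert_allclose(deform(q, grid, beta), expected,
                                   rtol=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 50))
    def test_exact_linearity_in_moments(self, a, b, seed):
        rng = np.random.default_rng(seed)
        grid = ControlGrid(rng.standard_normal((4, 3)) * 3, 2.0)
        pts = rng.standard_normal((6, 3))
        b1 = rng.standard_normal((4, 3))
        b2 = rng.standard_normal((4, 3))
        lhs = deform(pts, grid, a * b1 + b * b2) - pts
        rhs = a * (deform(pts, grid, b1) - pts) + \
            b * (deform(pts, grid, b2) - pts)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestFitMoments:
    def test_recovers_small_deformation(self, template):
        verts = np.asarray(template.surface.vertices)
        grid = ControlGrid(template.grid.points,
                           template.grid.kernel_width / 2)
        rng = np.random.default_rng(7)
        beta = rng.normal(0, 0.05, (grid.q, 3))
        subject = deform(verts, grid, beta)
        rec = fit_moments(verts, subject, grid, reg_lambda=1e-9,
                          max_iter=50)
        err = np.linalg.norm(rec.beta - beta) / np.linalg.norm(beta)
        assert err < 0.05

    def test_identity_subject_gives_near_zero_moments(self, template):
        verts = np.asarray(template.surface.vertices)
        rec = fit_moments(verts, verts, template.grid)
        disp = deform(verts, template.grid, rec.beta) - verts
        assert np.max(np.abs(disp)) < 1e-6

    def test_forward_model_linearity(self, template):
        verts = np.asarray(template.surface.vertices)
        grid = ControlGrid(template.grid.points,
                           template.grid.kernel_width / 2)
        rng = np.random.default_rng(11)
        beta = rng.normal(0, 0.04, (grid.q, 3))
        r1 = fit_moments(verts, deform(verts, grid, beta), grid,
                         reg_lambda=1e-9, max_iter=50)
        r2 = fit_moments(verts, deform(verts, grid, 2 * beta), grid,
                         reg_lambda=1e-9, max_iter=50)
        err = np.linalg.norm(r2.beta - 2 * r1.beta) / \
            np.linalg.norm(2 * r1.beta)
        assert err < 0.01

    def test_singular_system_advises_regularisation(self, rng):
        pts = rng.standard_normal((4, 3))
        grid = make_control_grid([-3, -3, -3], [3, 3, 3], 64)
        subj = pts + 0.01
        with pytest.raises(np.linalg.LinAlgError, match="reg_lambda"):
            fit_moments(pts, subj, grid, reg_lambda=0.0)


class TestRigidInvariance:
    def test_global_motion_leaves_moments_unchanged(self, template):
        """Rigidly moving a subject before alignment leaves its fitted
        moment field unchanged to alignment tolerance."""
        verts = np.asarray(template.surface.vertices)
        grid = ControlGrid(template.grid.points,
                           template.grid.kernel_width / 2)
        rng = np.random.default_rng(5)
        beta = rng.normal(0, 0.05, (grid.q, 3))
        subject = deform(verts, grid, beta)

        R = Rotation.from_euler("xyz", [7, -4, 11],
                                degrees=True).as_matrix()
        t = np.array([8.0, -5.0, 3.0])
        moved = subject @ R.T + t
        frame = template.frame
        moved_frame = AnatomicalFrame(R @ frame.head_centre + t,
                                      R @ frame.neck_axis,
                                      R @ frame.shaft_axis)
        T0 = initial_align(moved_frame, frame)
        coarse = T0.apply(moved)
        T1, rmsd, _ = icp_align(coarse, subject)
        realigned = T1.apply(coarse)
        assert rmsd < 1e-6
        rec_moved = fit_moments(verts, realigned, grid, reg_lambda=1e-9,
                                max_iter=50)
        rec_plain = fit_moments(verts, subject, grid, reg_lambda=1e-9,
                                max_iter=50)
        err = np.linalg.norm(rec_moved.beta - rec_plain.beta) / \
            np.linalg.norm(rec_plain.beta)
        assert err < 0.01


class TestShapeMatrix:
    def grid(self):
        return ControlGrid(np.array([[0.0, 0, 0], [1.0, 0, 0]]), 1.0)

    def test_column_order_documented(self):
        g = self.grid()
        f1 = MomentField(np.array([[1.0, 2, 3], [4.0, 5, 6]]), g)
        f2 = MomentField(np.array([[7.0, 8, 9], [10.0, 11, 12]]), g)
        sm = build_shape_matrix([f1, f2], ["a", "b"])
        np.testing.assert_array_equal(
            sm.X_beta, [[1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12]])
        assert sm.subject_ids == ["a", "b"]

    def test_row_roundtrip(self):
        g = self.grid()
        f = MomentField(np.array([[1.0, -2, 3], [0.5, 0, -1]]), g)
        sm = build_shape_matrix([f])
        back = MomentField.from_flat(sm.X_beta[0], g)
        np.testing.assert_array_equal(back.beta, f.beta)

    def test_cohort_scale_dimensions(self):
        grid = make_control_grid([0, 0, 0], [1, 1, 1], 500)
        fields = [MomentField(np.zeros((500, 3)), grid) for _ in range(93)]
        assert build_shape_matrix(fields).X_beta.shape == (93, 1500)

    def test_mixed_grids_rejected(self):
        g1 = self.grid()
        g2 = ControlGrid(np.array([[0.0, 0, 0], [2.0, 0, 0]]), 1.0)
        with pytest.raises(ValueError, match="different control grid"):
            build_shape_matrix([MomentField(np.zeros((2, 3)), g1),
                                MomentField(np.zeros((2, 3)), g2)])


class TestControlGrid:
    def test_unit_box_perfect_cube(self):
        grid = make_control_grid([0, 0, 0], [1, 1, 1], 64)
        axes = np.linspace(0, 1, 4)
        expected = np.array([[x, y, z] for z in axes for y in axes
                             for x in axes])
        np.testing.assert_allclose(grid.points, expected)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ControlGrid(np.zeros((2, 3)), 1.0)

    def test_rigid_transform_roundtrip(self, rng):
        R = Rotation.from_euler("x", 40, degrees=True).as_matrix()
        T = RigidTransform(R, np.array([1.0, 2, 3]))
        pts = rng.standard_normal((5, 3))
        np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts,
                                   atol=1e-12)
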