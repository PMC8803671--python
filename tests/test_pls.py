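"""NIPALS PLS1: closed-form anchors, reconstruction identity, projection
consistency and the two-level fusion."""

import numpy as np
import pytest

from ssimfem.pls import (ModeCount, fit_pls, fit_ssim, mode_vector,
                         modes_to_explain, predict_y, project, reconstruct)


def random_problem(rng, n=20, p=12):
    X = rng.standard_normal((n, p))
    y = rng.integers(0, 2, n)
    while y.min() == y.max():
        y = rng.integers(0, 2, n)
    return X, y


class TestFitPLS:
    @pytest.mark.parametrize("seed", range(8))
    def test_first_weight_closed_form(self, seed):
        """w1 equals X_c^T y_c / ||X_c^T y_c|| exactly (up to the sign
        convention)."""
        rng = np.random.default_rng(seed)
        X, y = random_problem(rng)
        model = fit_pls(X, y, m=1)
        c = (X - X.mean(0)).T @ (y - y.mean())
        w_ref = c / np.linalg.norm(c)
        if w_ref[np.argmax(np.abs(w_ref))] < 0:
            w_ref = -w_ref
        np.testing.assert_allclose(model.weights[:, 0], w_ref, atol=1e-12)

    def test_signal_column_dominates_weight(self, rng):
        """With one column equal to y and orthogonal noise, the first
        weight concentrates on that column."""
        n = 64
        y = np.tile([0, 1], n // 2)
        noise = rng.standard_normal((n, 5))
        noise -= np.outer(y - y.mean(),
                          (y - y.mean()) @ noise) / np.sum(
                              (y - y.mean()) ** 2)
        X = np.column_stack([y.astype(float), noise])
        model = fit_pls(X, y, m=1)
        assert abs(model.weights[0, 0]) > 0.999

    def test_full_rank_reconstruction(self, rng):
        """Eq.-style identity: x_bar + T P^T reproduces the training
        matrix when all extractable modes are kept."""
        for n, p in ((15, 8), (8, 15)):
            X, y = random_problem(rng, n, p)
            model = fit_pls(X, y)
            Xhat = model.mean + model.components @ model.modes.T
            err = np.linalg.norm(Xhat - X) / np.linalg.norm(X - X.mean(0))
            assert err < 1e-8

    def test_score_orthogonality(self, rng):
        X, y = random_problem(rng, 25, 10)
        model = fit_pls(X, y)
        G = model.components.T @ model.components
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_varexp_profiles_monotone_bounded(self, rng):
        X, y = random_problem(rng, 30, 12)
        model = fit_pls(X, y)
        for prof in (model.varexp_x, model.varexp_y):
            assert np.all(np.diff(prof) >= -1e-12)
            assert prof[-1] <= 1 + 1e-9
        assert model.varexp_x[-1] > 1 - 1e-8   # full-rank extraction

    def test_covariance_maximality_dense_search(self, rng):
        """cov(Xw, y) over unit w peaks at w1 (3-column toy, dense
        unit-sphere scan)."""
        X, y = random_problem(rng, 40, 3)
        model = fit_pls(X, y, m=1)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        # Fibonacci sphere scan
        k = np.arange(20000)
        phi = np.arccos(1 - 2 * (k + 0.5) / len(k))
        theta = np.pi * (1 + 5 ** 0.5) * k
        W = np.column_stack([np.sin(phi) * np.cos(theta),
                             np.sin(phi) * np.sin(theta), np.cos(phi)])
        covs = np.abs(W @ (Xc.T @ yc))
        cov1 = abs((Xc @ model.weights[:, 0]) @ yc)
        assert cov1 >= covs.max() - 1e-6 * cov1

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="single class"):
            fit_pls(X, np.ones(10))

    def test_early_stop_when_response_explained(self):
        """A response lying exactly in the span of column 1 is fully
        deflated after one mode; extraction stops with a flag."""
        rng = np.random.default_rng(3)
        y = np.tile([0.0, 1.0], 8)
        X = np.column_stack([y, np.zeros(16), np.zeros(16)])
        model = fit_pls(X, y, m=3)
        assert model.stopped_early
        assert model.n_modes == 1

    def test_sign_convention(self, rng):
        X, y = random_problem(rng, 20, 6)
        model = fit_pls(X, y, m=3)
        for j in range(model.n_modes):
            w = model.weights[:, j]
            assert w[np.argmax(np.abs(w))] > 0

    def test_matches_sklearn_predictions(self, rng):
        """Independent oracle: sklearn PLSRegression gives the same
        response predictions for the same mode count."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(rng, 30, 10)
        m = 3
        ours = predict_y(fit_pls(X, y, m=m), X)
        ref = sklearn_pls.PLSRegression(n_components=m, scale=False)
        ref.fit(X, y.astype(float))
        np.testing.assert_allclose(ours, ref.predict(X).ravel(),
                                   atol=1e-8)


class TestProjectReconstruct:
    def test_zero_components_give_mean(self, rng):
        X, y = random_problem(rng)
        model = fit_pls(X, y, m=3)
        np.testing.assert_allclose(reconstruct(model, np.zeros(3)),
                                   model.mean)

    def test_training_rows_roundtrip(self, rng):
        X, y = random_problem(rng, 12, 7)
        model = fit_pls(X, y)
        np.testing.assert_allclose(reconstruct(model, model.components),
                                   X, atol=1e-8)

    def test_projection_consistency(self, rng):
        X, y = random_problem(rng, 18, 9)
        model = fit_pls(X, y, m=4)
        np.testing.assert_allclose(project(model, X), model.components,
                                   atol=1e-8)
        np.testing.assert_allclose(project(model, model.mean),
                                   np.zeros(4), atol=1e-10)

    def test_rank_one_mode_projection(self, rng):
        """On rank-1 data the first mode is unit-norm, so x_bar + 2 p1
        projects to components (2, 0, ...)."""
        u = rng.standard_normal(6)
        u /= np.linalg.norm(u)
        s = rng.standard_normal(12)
        y = (s > 0).astype(int)
        X = np.outer(s, u)
        model = fit_pls(X, y, m=1)
        t = project(model, model.mean + 2 * model.modes[:, 0])
        np.testing.assert_allclose(t, [2.0], atol=1e-8)

    def test_mode_vector_symmetry(self, rng):
        """+sigma and -sigma mode renderings average to the mean."""
        X, y = random_problem(rng)
        model = fit_pls(X, y, m=2)
        plus = mode_vector(model, 0, +1.0)
        minus = mode_vector(model, 0, -1.0)
        np.testing.assert_allclose((plus + minus) / 2, model.mean,
                                   atol=1e-12)
        np.testing.assert_allclose(mode_vector(model, 0, 0.0), model.mean)


class TestSSIM:
    def test_intensity_block_carries_signal(self, rng):
        """When all class signal lives in the intensity components, the
        first fused weight concentrates on the intensity block."""
        n = 80
        y = np.tile([0, 1], n // 2)
        shape_scores = rng.standard_normal((n, 4))
        intensity_scores = rng.standard_normal((n, 4)) + \
            2.0 * (y - 0.5)[:, None]
        ssm = fit_pls(shape_scores + 0.0, y, m=3)
        sim = fit_pls(intensity_scores, y, m=3)
        fused = fit_ssim(ssm, sim, y, m_shape=3, m_int=3, m=1)
        w = fused.weights[:, 0]
        frac_int = np.sum(w[3:] ** 2) / np.sum(w ** 2)
        assert frac_int > 0.9

    def test_empty_block_rejected(self, rng):
        X, y = random_problem(rng)
        m1 = fit_pls(X, y, m=2)
        with pytest.raises(ValueError, match="at least one"):
            fit_ssim(m1, m1, y, m_shape=0, m_int=2)

    def test_duplicated_blocks_symmetric(self, rng):
        X, y = random_problem(rng, 24, 8)
        m1 = fit_pls(X, y, m=2)
        fused = fit_ssim(m1, m1, y, m_shape=2, m_int=2, m=1)
        w = fused.weights[:, 0]
        np.testing.assert_allclose(w[:2], w[2:], atol=1e-8)

    def test_subject_mismatch_rejected(self, rng):
        X, y = random_problem(rng, 20, 6)
        X2, y2 = random_problem(rng, 22, 6)
        m1 = fit_pls(X, y, m=2)
        m2 = fit_pls(X2, y2, m=2)
        with pytest.raises(ValueError, match="different subject"):
            fit_ssim(m1, m2, y, m_shape=2, m_int=2)


class TestModesToExplain:
    @pytest.mark.parametrize("target,expected", [(0.9, 3), (0.5, 1),
                                                 (0.75, 2)])
    def test_profile_thresholds(self, target, expected, rng):
        X, y = random_problem(rng, 10, 5)
        model = fit_pls(X, y)
        model.varexp_x = np.array([0.5, 0.8, 0.92, 0.97, 1.0])[:model.n_modes]
        got = modes_to_explain(model, target)
        assert got == ModeCount(expected, True)

    def test_unreachable_flagged(self, rng):
        X, y = random_problem(rng, 10, 5)
        model = fit_pls(X, y, m=2)
        model.varexp_x = np.array([0.3, 0.6])
        got = modes_to_explain(model, 0.95)
        assert got.n_modes == 2 and not got.reached

    def test_rank_one_always_one(self, rng):
        u = rng.standard_normal(5)
        s = rng.standard_normal(14)
        y = (s > 0).astype(int)
        model = fit_pls(np.outer(s, u), y)
        for target in (0.1, 0.5, 0.99):
            assert modes_to_explain(model, target).n_modes == 1
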