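import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import splsreg as s
from splsreg.direction import CrossCovariance, SparsityParams


def _unit(v):
    return v / np.linalg.norm(v)


class TestSoftThreshold:
    def test_eta_zero_preserves_direction(self, rng):
        v = rng.standard_normal(7)
        out = s.soft_threshold(v, 0.0)
        np.testing.assert_allclose(out.values, _unit(v), atol=1e-12)

    def test_hand_computed_example(self):
        out = s.soft_threshold(np.array([0.5, -0.3, 0.1]), 0.5)
        # pre-normalization (0.25, -0.05, 0)
        expected = np.array([0.25, -0.05, 0.0])
        np.testing.assert_allclose(out.values, _unit(expected), atol=1e-5)
        np.testing.assert_allclose(
            out.values, [0.98058, -0.19612, 0.0], atol=1e-5
        )
        assert out.support.tolist() == [0, 1]

    def test_eta_near_one_keeps_only_argmax(self, rng):
        v = rng.standard_normal(9)
        out = s.soft_threshold(v, 1 - 1e-9)
        assert out.support.tolist() == [int(np.argmax(np.abs(v)))]

    def test_ties_at_maximum_all_survive(self):
        out = s.soft_threshold(np.array([1.0, -1.0, 0.2]), 0.9)
        assert out.support.tolist() == [0, 1]

    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 0.99))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_support_nonincreasing_in_eta(self, seed, eta):
        v = np.random.default_rng(seed).standard_normal(12)
        lower = set(s.soft_threshold(v, eta).support.tolist())
        higher = set(s.soft_threshold(v, min(eta + 0.3, 0.999)).support.tolist())
        assert higher <= lower

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            s.soft_threshold(np.ones(3), 1.0)
        with pytest.raises(ValueError):
            s.soft_threshold(np.zeros(3), 0.5)


class TestCrossCovariance:
    def test_operator_matches_dense_product(self, rng):
        X = rng.standard_normal((6, 4))
        Y = rng.standard_normal((6, 2))
        Z = X.T @ Y
        M = CrossCovariance(Z)
        v = rng.standard_normal(4)
        np.testing.assert_allclose(M.matvec(v), (Z @ Z.T) @ v, atol=1e-12)

    def test_rank_one_action_for_univariate(self, rng):
        z = rng.standard_normal((5, 1))
        M = CrossCovariance(z)
        v = rng.standard_normal(5)
        np.testing.assert_allclose(
            M.matvec(v), float(z[:, 0] @ v) * z[:, 0], atol=1e-12
        )

    def test_orthogonal_response_raises(self, rng):
        X = rng.standard_normal((10, 3))
        q, _ = np.linalg.qr(
            np.column_stack([X - X.mean(0), np.ones(10)])
        )
        y = rng.standard_normal(10)
        y -= q @ (q.T @ y)
        d = s.center_scale(X, y[:, None], scale_x=False, scale_y=False)
        with pytest.raises(ValueError, match="degenerate"):
            s.cross_covariance(d)


class TestWStep:
    def test_kappa_half_returns_normalized_Mc(self, rng):
        Z = rng.standard_normal((6, 3))
        M = CrossCovariance(Z)
        c = rng.standard_normal(6)
        w = s.w_step(M, c, 0.5)
        np.testing.assert_allclose(w, _unit(M.matvec(c)), atol=1e-12)

    def test_eigenvector_is_fixed_direction_at_kappa_half(self, rng):
        A = rng.standard_normal((5, 5))
        M = CrossCovariance(A)  # M = AA'
        _, vecs = np.linalg.eigh(A @ A.T)
        v = vecs[:, -1]
        w = s.w_step(M, v, 0.5)
        assert min(np.abs(w - v).max(), np.abs(w + v).max()) < 1e-8

    def test_lagrange_solution_satisfies_constraint_and_is_local_max(self, rng):
        A = rng.standard_normal((5, 5))
        M = CrossCovariance(A)
        Md = A @ A.T
        c = 10.0 * rng.standard_normal(5)
        kappa = 0.3
        kp = (1 - kappa) / (1 - 2 * kappa)
        w = s.w_step(M, c, kappa)
        # stated norm constraint: c'M (M+lam I)^-2 M c = kp^2, i.e. the
        # returned w = kp (M+lam)^{-1} M c has norm kp^2
        assert abs(np.linalg.norm(w) - kp**2) < 1e-6
        # the w-subproblem objective w'Mw - 2 kp w'Mc is minimized on the
        # sphere of radius ||w||: random rotations on that sphere are worse
        obj = lambda u: float(u @ Md @ u - 2 * kp * u @ Md @ c)
        base = obj(w)
        r = np.linalg.norm(w)
        for _ in range(40):
            u = w + 1e-3 * rng.standard_normal(5)
            u *= r / np.linalg.norm(u)
            assert obj(u) >= base - 1e-9

    def test_zero_Mc_raises(self):
        Z = np.zeros((4, 2))
        Z[0, 0] = 1.0  # exact null space on coordinates 1..3
        M = CrossCovariance(Z)
        with pytest.raises(ValueError):
            s.w_step(M, np.array([0.0, 1.0, 0.0, 0.0]), 0.5)


class TestCStep:
    def test_eta_zero_is_parallel_to_Mw(self, rng):
        Z = rng.standard_normal((7, 2))
        M = CrossCovariance(Z)
        w = _unit(rng.standard_normal(7))
        c = s.c_step(M, w, 0.0)
        Mw = M.matvec(w)
        np.testing.assert_allclose(_unit(c), _unit(Mw), atol=1e-12)

    def test_eta_near_one_is_one_hot(self, rng):
        Z = rng.standard_normal((7, 2))
        M = CrossCovariance(Z)
        w = _unit(rng.standard_normal(7))
        c = s.c_step(M, w, 1 - 1e-9)
        assert np.count_nonzero(c) == 1
        assert int(np.flatnonzero(c)[0]) == int(np.argmax(np.abs(M.matvec(w))))

    def test_univariate_c_step_parallel_to_thresholded_z(self, rng):
        z = rng.standard_normal((8, 1))
        M = CrossCovariance(z)
        for _ in range(5):
            w = _unit(rng.standard_normal(8))
            if abs(z[:, 0] @ w) < 1e-3:
                continue
            c = s.c_step(M, w, 0.4)
            st_z = s.soft_threshold(z[:, 0], 0.4).values
            assert min(
                np.abs(_unit(c) - st_z).max(), np.abs(_unit(c) + st_z).max()
            ) < 1e-10


class TestSparseDirection:
    @given(
        st.integers(0, 2**32 - 1),
        st.floats(0.0, 0.95),
        st.sampled_from([0.1, 0.3, 0.4, 0.5]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_univariate_solution_is_thresholded_cross_covariance(
        self, seed, eta, kappa
    ):
        """Closed form for q = 1: kappa-independent soft threshold of X'Y."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 8))
        y = X[:, :2].sum(axis=1) + 0.3 * rng.standard_normal(20)
        d = s.center_scale(X, y[:, None])
        Z = s.cross_covariance(d)
        dv = s.sparse_direction(Z, SparsityParams(eta=eta, kappa=kappa))
        st_z = s.soft_threshold(Z.Z[:, 0], eta)
        np.testing.assert_allclose(dv.values, st_z.values, atol=1e-12)

    def test_univariate_eta_zero_is_dense_pls_direction(self, uni_data):
        Z = s.cross_covariance(uni_data)
        dv = s.sparse_direction(Z, SparsityParams(eta=0.0))
        np.testing.assert_allclose(dv.values, _unit(Z.Z[:, 0]), atol=1e-12)

    def test_rank_one_multivariate_support_contains_univariate_support(self, rng):
        X = rng.standard_normal((30, 10))
        b = np.zeros(10)
        b[:3] = [2.0, -1.5, 1.0]
        base = X @ b
        Y = np.column_stack([c * base for c in (1.0, 2.0, 0.5)])
        Y += 0.05 * rng.standard_normal(Y.shape)
        d = s.center_scale(X, Y)
        d1 = s.center_scale(X, Y[:, :1])
        eta = 0.6
        multi = s.sparse_direction(
            s.cross_covariance(d), SparsityParams(eta=eta)
        )
        uni = s.sparse_direction(
            s.cross_covariance(d1), SparsityParams(eta=eta)
        )
        assert set(uni.support.tolist()) <= set(multi.support.tolist())

    def test_scale_invariance_in_response(self, multi_data):
        Z = multi_data.X.T @ multi_data.Y
        p = SparsityParams(eta=0.5, kappa=0.4)
        a = s.sparse_direction(CrossCovariance(Z), p)
        b = s.sparse_direction(CrossCovariance(7.3 * Z), p)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_fixed_point_stability_at_convergence(self, multi_data):
        Z = s.cross_covariance(multi_data)
        p = SparsityParams(eta=0.5, kappa=0.4)
        dv = s.sparse_direction(Z, p)
        # re-apply one w-step/c-step sweep at the solver's own surrogate
        # scale and operator normalization
        Zn = CrossCovariance(Z.Z / np.median(np.abs(Z.Z[Z.Z != 0])))
        w = s.w_step(Zn, dv.raw, p.kappa)
        c2 = s.c_step(Zn, w, p.eta)
        c2 /= np.linalg.norm(c2)
        assert np.abs(np.abs(c2) - np.abs(dv.values)).max() < 1e-4

    def test_unit_norm_and_support_consistency(self, multi_data):
        dv = s.sparse_direction(
            s.cross_covariance(multi_data), SparsityParams(eta=0.7)
        )
        assert abs(np.linalg.norm(dv.values) - 1.0) < 1e-10
        assert dv.support.tolist() == np.flatnonzero(dv.values).tolist()


class TestParams:
    @pytest.mark.parametrize(
        "kw", [{"eta": 1.0}, {"eta": -0.1}, {"kappa": 0.0},
               {"kappa": 0.6}, {"tol": 0.0}]
    )
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            SparsityParams(**kw)
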