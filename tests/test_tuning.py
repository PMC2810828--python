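import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import splsreg as s
from splsreg.tuning import _choose, fdr_screen


def _bh_bruteforce(pvals, alpha):
    """Direct evaluation of the step-up definition."""
    p = len(pvals)
    order = np.argsort(pvals, kind="stable")
    m_hat = 0
    for i in range(1, p + 1):
        if pvals[order[i - 1]] <= i * alpha / p:
            m_hat = i
    return np.sort(order[:m_hat])


class TestPartialCorrelation:
    def test_zero_correlation_gives_unit_pvalue(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        y = y - y.mean()
        r, z, p = s.partial_correlation_pvalues(X, y)
        assert abs(r[0]) < 1e-12
        assert abs(z[0]) < 1e-12
        assert p[0] == pytest.approx(1.0)

    def test_empty_conditioning_is_plain_pearson(self, rng):
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        r, _, _ = s.partial_correlation_pvalues(X, y)
        expected = [np.corrcoef(X[:, j], y)[0, 1] for j in range(6)]
        np.testing.assert_allclose(r, expected, atol=1e-12)

    def test_conditioning_matches_residual_oracle(self, rng):
        n = 50
        X = rng.standard_normal((n, 5))
        t = rng.standard_normal((n, 1))
        y = (2 * t[:, 0] + X[:, 0] + 0.5 * rng.standard_normal(n))
        r, _, _ = s.partial_correlation_pvalues(X, y, T_prev=t)
        # oracle: regress out t explicitly, then correlate residuals
        def resid(v):
            tc = np.column_stack([np.ones(n), t[:, 0]])
            return v - tc @ np.linalg.lstsq(tc, v, rcond=None)[0]
        for j in range(5):
            expected = np.corrcoef(resid(X[:, j]), resid(y))[0, 1]
            assert r[j] == pytest.approx(expected, abs=1e-10)

    def test_pvalue_monotone_in_correlation_magnitude(self):
        # push correlations of increasing strength through the transform
        n = 40
        rng = np.random.default_rng(7)
        base = rng.standard_normal(n)
        X = np.column_stack(
            [0.2 * base + rng.standard_normal(n),
             1.0 * base + 0.5 * rng.standard_normal(n),
             2.0 * base + 0.1 * rng.standard_normal(n)]
        )
        r, _, p = s.partial_correlation_pvalues(X, base)
        order = np.argsort(-np.abs(r))
        assert np.all(np.diff(p[order]) >= 0)

    def test_perfect_correlation_warns_p_zero(self):
        X = np.arange(10.0)[:, None]
        with pytest.warns(UserWarning, match="p-value"):
            _, _, p = s.partial_correlation_pvalues(X, np.arange(10.0))
        assert p[0] == 0.0

    def test_insufficient_n_raises(self, rng):
        with pytest.raises(ValueError, match="n > g"):
            s.partial_correlation_pvalues(
                rng.standard_normal((5, 2)), rng.standard_normal(5),
                T_prev=rng.standard_normal((5, 2)),
            )


class TestBHSelect:
    def test_all_unit_pvalues_select_nothing(self):
        assert s.bh_select(np.ones(6), 0.05).size == 0

    def test_worked_example(self):
        sel = s.bh_select(np.array([0.001, 0.01, 0.04, 0.2, 0.9]), 0.05)
        assert sel.tolist() == [0, 1]

    def test_boundary_all_at_alpha_over_p(self):
        p = 8
        sel = s.bh_select(np.full(p, 0.05 / p), 0.05)
        assert sel.tolist() == list(range(p))

    @given(st.integers(0, 2**32 - 1), st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_bruteforce_definition(self, seed, alpha):
        pv = np.random.default_rng(seed).uniform(size=9)
        np.testing.assert_array_equal(
            s.bh_select(pv, alpha), _bh_bruteforce(pv, alpha)
        )

    def test_all_sign_patterns_of_small_grid(self):
        # every subset of {small, large} p-values on a 5-vector
        for pattern in itertools.product([0.004, 0.6], repeat=5):
            pv = np.array(pattern)
            np.testing.assert_array_equal(
                s.bh_select(pv, 0.05), _bh_bruteforce(pv, 0.05)
            )

    def test_statsmodels_cross_check(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            pv = rng.uniform(size=15) ** 2
            sel = s.bh_select(pv, 0.1)
            reject, *_ = multipletests(pv, alpha=0.1, method="fdr_bh")
            assert sel.tolist() == np.flatnonzero(reject).tolist()

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            s.bh_select(np.array([0.5, 1.2]), 0.05)
        with pytest.raises(ValueError):
            s.bh_select(np.array([0.5]), 0.0)


class TestFDRFit:
    def test_alpha_one_recovers_near_dense_fit(self, uni_data):
        fit = s.fit_spls_fdr(uni_data, 1, alpha=1.0)
        # with alpha = 1 every variable with p-value < 1 is selected
        assert fit.active.indices.size == uni_data.p

    def test_multivariate_rejected(self, multi_data):
        with pytest.raises(ValueError, match="univariate"):
            s.fit_spls_fdr(multi_data, 1, alpha=0.1)

    def test_null_data_selects_few(self, rng):
        # under a global null the BH screen controls selections near zero
        counts = []
        for _ in range(50):
            X = rng.standard_normal((100, 50))
            y = rng.standard_normal(100)
            sel = fdr_screen(X - X.mean(0), y - y.mean(), None, 0.1)
            counts.append(sel.selected.size)
        assert np.mean(counts) <= 0.1 * 50 * 1.5

    def test_grouped_signal_recovers_relevant_set(self, rng):
        cfg = s.scenario("s53_block", seed=77, p=40, q_spurious=10,
                         noise_to_signal=0.1)
        ds = s.generate(cfg)
        d = s.center_scale(ds.X_train, ds.Y_train)
        fit = s.fit_spls_fdr(d, 2, alpha=0.1)
        assert set(ds.relevant.tolist()) <= set(fit.active.indices.tolist())


class TestCV:
    def test_single_cell_grid_returns_that_cell(self, rng):
        X = rng.standard_normal((30, 6))
        y = X[:, 0] + 0.2 * rng.standard_normal(30)
        res = s.kfold_cv_spls(X, y, eta_grid=[0.5], K_grid=[2], folds=5, seed=3)
        assert (res.chosen_eta, res.chosen_K) == (0.5, 2)

    def test_identical_seed_bitwise_reproducible(self, rng):
        X = rng.standard_normal((40, 8))
        y = X[:, :2].sum(1) + 0.3 * rng.standard_normal(40)
        a = s.kfold_cv_spls(X, y, eta_grid=[0.2, 0.6], K_grid=[1, 2], folds=5, seed=9)
        b = s.kfold_cv_spls(X, y, eta_grid=[0.2, 0.6], K_grid=[1, 2], folds=5, seed=9)
        assert a.grid.equals(b.grid)
        assert (a.chosen_eta, a.chosen_K) == (b.chosen_eta, b.chosen_K)

    def test_one_component_truth_chooses_K1_under_parsimony(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            h = rng.standard_normal(n) * 20
            X = rng.standard_normal((n, 12))
            X[:, :6] += h[:, None]
            y = 3.0 * h + rng.standard_normal(n)
            res = s.kfold_cv_spls(
                X, y, eta_grid=[0.1, 0.5, 0.9], K_grid=[1, 2, 3],
                folds=5, rule="parsimony_1.1", seed=seed,
            )
            hits += res.chosen_K == 1
        assert hits == 10

    def test_reported_minimum_matches_manual_fold_loop(self, rng):
        X = rng.standard_normal((30, 5))
        y = X[:, 0] - X[:, 1] + 0.3 * rng.standard_normal(30)
        eta, K, folds, seed = 0.3, 1, 5, 4
        res = s.kfold_cv_spls(X, y, eta_grid=[eta], K_grid=[K], folds=folds,
                              seed=seed)
        # manual loop with the same fold construction
        perm = np.random.default_rng(seed).permutation(30)
        errs = []
        for f in range(folds):
            test = perm[f::folds]
            train = np.setdiff1d(np.arange(30), test)
            d = s.center_scale(X[train], y[train, None])
            fit = s.fit_spls(d, K, eta=eta)
            pred = s.predict_spls(fit, X[test], d)
            errs.append(np.mean((y[test, None] - pred) ** 2))
        assert res.grid["cv_error"].iloc[0] == pytest.approx(np.mean(errs))

    def test_parsimony_rule_prefers_small_K_then_large_eta(self):
        import pandas as pd

        grid = pd.DataFrame(
            {"eta": [0.1, 0.9, 0.1, 0.9], "K": [1, 1, 2, 2],
             "cv_error": [1.09, 1.05, 1.0, 1.2]}
        )
        eta, K = _choose(grid, "parsimony_1.1")
        assert (eta, K) == (0.9, 1)
        eta, K = _choose(grid, "min")
        assert (eta, K) == (0.1, 2)

    def test_too_small_folds_raise(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="folds"):
            s.kfold_cv_spls(X, y, eta_grid=[0.5], K_grid=[1], folds=1)
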