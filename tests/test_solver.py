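import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import Lasso

from cisfine import solver
from cisfine.solver import PenaltySpec


def random_instance(rng, n=40, p=8, k=2, rho=0.5, noise=1.0):
    """Correlated-design regression instance with k causal columns."""
    z = rng.standard_normal((n, p))
    for j in range(1, p):
        z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
    beta = np.zeros(p)
    beta[rng.choice(p, k, replace=False)] = rng.standard_normal(k) * 2
    y = z @ beta + noise * rng.standard_normal(n)
    return z, y


class TestThresholdUpdate:
    def test_lasso_limit_is_soft_threshold(self):
        assert solver.threshold_update(1.0, PenaltySpec(0.0, 0.3)) == pytest.approx(0.7)
        assert solver.threshold_update(-1.0, PenaltySpec(0.0, 0.3)) == pytest.approx(-0.7)

    def test_hard_threshold_kills_small_soft_threshold_survivors(self):
        # t = 0.7 but sqrt(2*0.5) = 1.0 > 0.7 -> zero
        assert solver.threshold_update(1.0, PenaltySpec(0.5, 0.3)) == 0.0

    def test_large_correlation_survives_both_penalties(self):
        # t = 1.5 >= sqrt(2*0.5) = 1.0
        assert solver.threshold_update(2.0, PenaltySpec(0.5, 0.5)) == pytest.approx(1.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        rho=st.floats(-3, 3, allow_nan=False),
        lam0=st.floats(0, 2),
        lam1=st.floats(0, 2),
    )
    def test_is_scalar_minimizer(self, rho, lam0, lam1):
        """The update must minimize 0.5 b^2 - rho b + lam1|b| + lam0 1[b!=0]."""
        pen = PenaltySpec(lam0, lam1)
        b_star = solver.threshold_update(rho, pen)

        def J(b):
            return 0.5 * b * b - rho * b + lam1 * abs(b) + lam0 * (b != 0)

        grid = np.linspace(-4, 4, 1601)
        assert J(b_star) <= J(grid).min() + 1e-9


class TestObjective:
    def test_zero_beta_is_half_y_norm(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        val = solver.objective(X, y, np.zeros(3), PenaltySpec(1.0, 1.0))
        assert val == pytest.approx(0.5 * y @ y)

    def test_unpenalized_ols_attains_half_rss(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ b
        val = solver.objective(X, y, b, PenaltySpec(0.0, 0.0))
        assert val == pytest.approx(0.5 * resid @ resid)
        # any perturbation increases the loss
        assert solver.objective(X, y, b + 0.1, PenaltySpec(0.0, 0.0)) > val

    def test_hand_computed_single_column(self):
        x = np.ones(4) / 2.0  # unit norm
        y = 2.0 * x
        val = solver.objective(x[:, None], y, np.array([1.5]), PenaltySpec(0.1, 0.2))
        assert val == pytest.approx(0.5 * 0.25 + 0.1 + 0.2 * 1.5)  # 0.525

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            solver.objective(rng.standard_normal((5, 2)), np.zeros(5), np.zeros(3), PenaltySpec(0, 0))


class TestFitL0L1:
    def test_prohibitive_l0_gives_empty_model(self, rng):
        X, y = random_instance(rng)
        Xs, yc, *_ = solver.standardize(X, y)
        lam0 = 0.5 * np.abs(Xs.T @ yc).max() ** 2 * 1.01
        fit = solver.fit_l0l1(X, y, PenaltySpec(lam0, 0.0))
        assert fit.support.size == 0

    def test_ols_limit(self, rng):
        X, y = random_instance(rng, n=60, p=5)
        fit = solver.fit_l0l1(X, y, PenaltySpec(0.0, 0.0), tol=0.0, max_iter=50_000)
        X1 = np.column_stack([np.ones(60), X])
        b = np.linalg.lstsq(X1, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, b[1:], atol=1e-8)
        np.testing.assert_allclose(fit.intercept, b[0], atol=1e-8)

    def test_orthonormal_design_closed_form(self, rng):
        # centered orthonormal columns survive standardization unchanged
        A = rng.standard_normal((30, 6))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        y = rng.standard_normal(30)
        pen = PenaltySpec(0.05, 0.1)
        fit = solver.fit_l0l1(Q, y, pen)
        expected = np.array([solver.threshold_update(r, pen) for r in Q.T @ (y - y.mean())])
        np.testing.assert_allclose(fit.beta_std, expected, atol=1e-10)

    def test_objective_recomputable_from_fit(self, rng):
        X, y = random_instance(rng, n=50, p=10)
        pen = PenaltySpec(0.2, 0.3)
        fit = solver.fit_l0l1(X, y, pen)
        Xs, yc, *_ = solver.standardize(X, y)
        assert solver.objective(Xs, yc, fit.beta_std, pen) == pytest.approx(
            fit.objective, rel=1e-10
        )
        np.testing.assert_array_equal(fit.support, np.flatnonzero(fit.beta_std))

    def test_monotone_descent_per_step(self, rng):
        for _ in range(10):
            X, y = random_instance(rng, n=40, p=12, k=3, rho=0.8)
            fit = solver.fit_l0l1(X, y, PenaltySpec(0.3, 0.2), keep_history=True)
            hist = np.array(fit.objective_history)
            assert (np.diff(hist) <= 1e-9 * (1 + hist[:-1])).all()

    def test_swap_search_escapes_ld_trap(self):
        # two near-duplicate columns: CD from a bad warm start parks on the
        # decoy; the swap move must recover the better column
        rng = np.random.default_rng(3)
        n = 200
        causal = rng.standard_normal(n)
        decoy = causal + 0.1 * rng.standard_normal(n)
        X = np.column_stack([decoy, causal])
        y = causal.copy()
        bad_start = np.array([1.0, 0.0])
        pen = PenaltySpec(0.4, 0.0)
        fit = solver.fit_l0l1(X, y, pen, beta_init=bad_start)
        assert fit.support.tolist() == [1]

    def test_permutation_equivariance_convex_case(self, rng):
        X, y = random_instance(rng, n=50, p=8)
        perm = rng.permutation(8)
        pen = PenaltySpec(0.0, 0.5)
        a = solver.fit_l0l1(X, y, pen, tol=1e-12, max_iter=10_000)
        b = solver.fit_l0l1(X[:, perm], y, pen, tol=1e-12, max_iter=10_000)
        np.testing.assert_allclose(b.beta, a.beta[perm], atol=1e-6)

    def test_nonconvergence_flagged_not_raised(self, rng):
        X, y = random_instance(rng, n=40, p=10)
        fit = solver.fit_l0l1(X, y, PenaltySpec(0.0, 0.001), tol=1e-16, max_iter=2)
        assert fit.converged is False

    def test_lasso_limit_matches_reference_solver(self, rng):
        for _ in range(10):
            X, y = random_instance(rng, n=50, p=10, rho=0.6)
            Xs, yc, *_ = solver.standardize(X, y)
            lam1 = 0.2 * np.abs(Xs.T @ yc).max()
            fit = solver.fit_l0l1(X, y, PenaltySpec(0.0, lam1), tol=1e-12, max_iter=50_000)
            ref = Lasso(alpha=lam1 / 50, fit_intercept=False, tol=1e-12, max_iter=500_000)
            ref.fit(Xs, yc)
            np.testing.assert_allclose(fit.beta_std, ref.coef_, atol=1e-4)


class TestFitPath:
    def test_singleton_grid_equals_direct_fit(self, rng):
        X, y = random_instance(rng)
        path = solver.fit_path(X, y, [0.2], [0.1])
        direct = solver.fit_l0l1(X, y, PenaltySpec(0.2, 0.1))
        assert len(path) == 1
        np.testing.assert_allclose(path[0].beta, direct.beta, atol=1e-8)

    def test_first_default_path_point_empty(self, rng):
        X, y = random_instance(rng)
        l0g, l1g = solver.default_grids(X, y, n_lambda1=5, n_lambda0=4)
        path = solver.fit_path(X, y, l0g, l1g)
        assert path[0].support.size == 0

    def test_pure_lasso_path_matches_reference(self, rng):
        X, y = random_instance(rng, n=60, p=8)
        Xs, yc, *_ = solver.standardize(X, y)
        lam1_max = np.abs(Xs.T @ yc).max()
        l1_grid = lam1_max * np.array([0.5, 0.2, 0.05])
        path = solver.fit_path(X, y, [0.0], l1_grid, tol=1e-12, max_iter=50_000)
        for fit, lam1 in zip(path, l1_grid):
            ref = Lasso(alpha=lam1 / 60, fit_intercept=False, tol=1e-12, max_iter=500_000)
            ref.fit(Xs, yc)
            np.testing.assert_allclose(fit.beta_std, ref.coef_, atol=1e-4)

    def test_unique_supports_deduplicates(self, rng):
        X, y = random_instance(rng)
        path = solver.fit_path(X, y, [1e6, 2e6], [1e6, 2e6])  # all empty
        assert len(solver.unique_supports(path)) == 1


class TestSelectByCV:
    def test_tie_breaks_toward_sparser_model(self, rng):
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        Xs, yc, *_ = solver.standardize(X, y)
        big = 10.0 * 0.5 * np.abs(Xs.T @ yc).max() ** 2
        # both lambda0 values prohibit any entry -> identical (null) CV error
        fit = solver.select_by_cv(X, y, [big, 2 * big], [0.1], n_folds=4, seed=0)
        assert fit.support.size == 0
        assert fit.penalty.lambda0 == pytest.approx(2 * big)

    def test_null_model_mostly_selected_under_pure_noise(self):
        """CV-min keeps the null model for most pure-noise genes and never
        selects more than a couple of spurious variants."""
        sizes = []
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((80, 10))
            y = rng.standard_normal(80)
            fit = solver.select_by_cv(X, y, seed=s, n_lambda1=15, n_lambda0=8)
            sizes.append(fit.support.size)
        sizes = np.array(sizes)
        assert (sizes == 0).mean() >= 0.65
        assert sizes.mean() <= 0.75

    def test_single_strong_causal_recovered(self):
        exact = 0
        n_rep = 25
        for s in range(n_rep):
            rng = np.random.default_rng(2000 + s)
            X = rng.standard_normal((500, 10))
            g = 2.0 * X[:, 4]
            noise_sd = np.sqrt(np.var(g) * 0.2 / 0.8)  # h2 = 0.8
            y = g + noise_sd * rng.standard_normal(500)
            fit = solver.select_by_cv(X, y, seed=s, n_lambda1=15, n_lambda0=8)
            assert 4 in fit.support  # the causal SNP is never missed
            exact += fit.support.tolist() == [4]
        assert exact >= 0.7 * n_rep

    def test_cv_error_reported(self, rng):
        X, y = random_instance(rng, n=50, p=6)
        fit = solver.select_by_cv(X, y, seed=1, n_lambda1=10, n_lambda0=5)
        assert fit.cv_error is not None and fit.cv_error > 0


class TestStabilityEnsemble:
    def test_reduces_to_cv_selection(self, rng):
        X, y = random_instance(rng, n=60, p=8)
        stab = solver.stability_ensemble(X, y, n_boot=1, subsample_frac=1.0, seed=3,
                                         n_lambda1=10, n_lambda0=5)
        direct = solver.select_by_cv(X, y, seed=3, n_lambda1=10, n_lambda0=5)
        np.testing.assert_array_equal(stab.support, direct.support)

    def test_frequencies_are_selection_fractions(self, rng):
        X, y = random_instance(rng, n=100, p=6, k=1, noise=0.3)
        n_boot = 5
        stab = solver.stability_ensemble(
            X, y, n_boot=n_boot, subsample_frac=0.7, freq_threshold=0.0, seed=4,
            n_lambda1=8, n_lambda0=4,
        )
        assert ((stab.frequencies >= 0) & (stab.frequencies <= 1)).all()
        counts = stab.frequencies * n_boot
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-12)
        # threshold 0 keeps everything ever selected
        ever = set()
        for fit in stab.fits:
            ever |= set(fit.support.tolist())
        assert set(stab.support.tolist()) == ever
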