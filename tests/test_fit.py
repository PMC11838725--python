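import numpy as np
import pytest
from scipy.optimize import minimize

import winratio as wr
from winratio.fit import _design
from winratio.pairwise import PairSet


def pair_set_from_arrays(delta, z_diff, ids=None):
    """Assemble a PairSet directly from win indicators and differences."""
    delta = np.asarray(delta, dtype=np.uint8)
    z_diff = np.atleast_2d(np.asarray(z_diff, dtype=float))
    n_pairs, p = z_diff.shape
    n = n_pairs + 1
    return PairSet(
        subject_ids=np.arange(n, dtype=object),
        i_idx=np.zeros(n_pairs, dtype=int),
        j_idx=np.arange(1, n_pairs + 1),
        delta=delta,
        z_diff=z_diff,
        shared_time=np.ones(n_pairs),
        tier=np.ones(n_pairs, dtype=np.int8),
        covariate_names=[f"z{k+1}" for k in range(p)],
    )


def flip_pairs(pairs, mask):
    """Relabel which pair member is 'i' for the masked pairs."""
    delta = pairs.delta.copy()
    z = pairs.z_diff.copy()
    delta[mask] = 1 - delta[mask]
    z[mask] = -z[mask]
    flipped = pairs.take(slice(None))
    flipped.delta = delta
    flipped.z_diff = z
    return flipped


@pytest.fixture(scope="module")
def sim_pairs():
    data = wr.generate_dataset(wr.scenario1(n=80, p=6, seed=3))
    return wr.build_pair_set(data)


class TestObjective:
    def test_zero_beta_gives_log_two(self, sim_pairs):
        assert wr.objective(sim_pairs, np.zeros(6), 0.7, 0.5) == (
            pytest.approx(np.log(2)))

    def test_single_pair_value(self):
        ps = pair_set_from_arrays([1], [[1.0]])
        assert wr.objective(ps, np.array([1.0]), 0.0, 1.0) == (
            pytest.approx(-(1 - np.log(1 + np.e))))

    def test_l1_penalty_added(self):
        ps = pair_set_from_arrays([1, 0], [[1.0, 0.0], [0.0, 1.0]])
        beta = np.array([1.0, -2.0])
        base = wr.objective(ps, beta, 0.0, 1.0)
        assert wr.objective(ps, beta, 0.3, 1.0) == pytest.approx(base + 0.3 * 3)

    def test_ridge_penalty_added(self):
        ps = pair_set_from_arrays([1], [[1.0, 1.0]])
        beta = np.array([2.0, -1.0])
        base = wr.objective(ps, beta, 0.0, 0.0)
        assert wr.objective(ps, beta, 0.4, 0.0) == (
            pytest.approx(base + 0.4 * 0.5 * 5))


class TestEstimatingFunction:
    def test_single_pair_at_zero(self):
        ps = pair_set_from_arrays([1], [[1.0]])
        np.testing.assert_allclose(
            wr.estimating_function(ps, np.zeros(1)), [0.5])

    def test_closed_form_at_zero(self, sim_pairs):
        expected = sim_pairs.z_diff.T @ (sim_pairs.delta - 0.5) / len(sim_pairs)
        np.testing.assert_allclose(
            wr.estimating_function(sim_pairs, np.zeros(6)), expected)

    def test_is_negative_gradient_of_objective(self, sim_pairs):
        rng = np.random.default_rng(0)
        beta = rng.normal(size=6) * 0.5
        U = wr.estimating_function(sim_pairs, beta)
        grad = np.empty(6)
        h = 1e-6
        for j in range(6):
            e = np.zeros(6)
            e[j] = h
            grad[j] = (wr.objective(sim_pairs, beta + e, 0.0, 1.0)
                       - wr.objective(sim_pairs, beta - e, 0.0, 1.0)) / (2 * h)
        np.testing.assert_allclose(U, -grad, atol=1e-6)


class TestUnregularized:
    def test_balanced_symmetric_design_gives_zero(self):
        ps = pair_set_from_arrays([1, 0], [[1.0], [1.0]])
        np.testing.assert_allclose(wr.fit_unregularized(ps), [0.0], atol=1e-12)

    def test_matches_generic_convex_optimizer(self, sim_pairs):
        beta_nr = wr.fit_unregularized(sim_pairs)
        res = minimize(
            lambda b: wr.objective(sim_pairs, b, 0.0, 1.0),
            np.zeros(6),
            jac=lambda b: -wr.estimating_function(sim_pairs, b),
            method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(beta_nr, res.x, atol=1e-5)
        assert np.max(np.abs(wr.estimating_function(sim_pairs, beta_nr))) < 1e-8

    def test_single_pair_is_separated(self):
        ps = pair_set_from_arrays([1], [[1.0]])
        with pytest.raises(wr.PerfectSeparationError):
            wr.fit_unregularized(ps)


class TestLambdaMax:
    def test_zero_when_estimating_function_zero_at_origin(self):
        ps = pair_set_from_arrays([1, 0], [[1.0], [1.0]])
        assert wr.lambda_max(ps, 1.0) == 0.0

    def test_brackets_first_nonzero_coefficient(self, sim_pairs):
        lmax = wr.lambda_max(sim_pairs, 1.0)
        cfg = wr.FitConfig(alpha=1.0,
                           lambda_grid=np.array([1.01 * lmax, 0.9 * lmax]))
        path = wr.fit_path(sim_pairs, cfg)
        assert np.all(path.betas[0] == 0)
        assert np.any(path.betas[1] != 0)

    def test_inversely_proportional_to_alpha(self, sim_pairs):
        assert wr.lambda_max(sim_pairs, 1.0) == (
            pytest.approx(wr.lambda_max(sim_pairs, 0.5) / 2))


class TestPath:
    def test_all_zero_above_lambda_max(self, sim_pairs):
        lmax = wr.lambda_max(sim_pairs, 1.0)
        cfg = wr.FitConfig(alpha=1.0,
                           lambda_grid=np.array([2 * lmax, 1.5 * lmax, lmax]))
        path = wr.fit_path(sim_pairs, cfg)
        assert np.all(path.betas == 0)
        assert list(path.n_nonzero) == [0, 0, 0]

    @pytest.mark.parametrize("alpha", [1.0, 0.5])
    def test_matches_independent_saga_solver(self, sim_pairs, alpha):
        from sklearn.linear_model import LogisticRegression
        lmax = wr.lambda_max(sim_pairs, alpha, standardize=False)
        grid = np.geomspace(lmax, lmax / 50, 8)
        cfg = wr.FitConfig(alpha=alpha, lambda_grid=grid, standardize=False)
        path = wr.fit_path(sim_pairs, cfg)
        X = sim_pairs.z_diff
        y = sim_pairs.delta.astype(int)
        N = len(sim_pairs)
        for k in [3, 7]:
            lam = grid[k]
            clf = LogisticRegression(
                penalty="elasticnet", l1_ratio=alpha, C=1.0 / (N * lam),
                fit_intercept=False, solver="saga", tol=1e-10, max_iter=200000)
            clf.fit(X, y)
            np.testing.assert_allclose(path.betas[k], clf.coef_[0], atol=1e-4)

    def test_zero_lambda_endpoint_matches_newton(self, sim_pairs):
        lmax = wr.lambda_max(sim_pairs, 1.0)
        grid = np.append(np.geomspace(lmax, lmax * 1e-3, 25), 0.0)
        path = wr.fit_path(sim_pairs, wr.FitConfig(alpha=1.0, lambda_grid=grid))
        np.testing.assert_allclose(
            path.betas[-1], wr.fit_unregularized(sim_pairs), atol=1e-5)

    def test_pair_order_flip_invariance(self, sim_pairs):
        """Which pair member is called 'i' is arbitrary: flipping any subset
        must leave the objective and every fit unchanged (no-intercept
        symmetry)."""
        rng = np.random.default_rng(1)
        mask = rng.random(len(sim_pairs)) < 0.5
        flipped = flip_pairs(sim_pairs, mask)
        beta = rng.normal(size=6)
        assert wr.objective(flipped, beta, 0.2, 0.7) == (
            pytest.approx(wr.objective(sim_pairs, beta, 0.2, 0.7), abs=1e-12))
        np.testing.assert_allclose(
            wr.estimating_function(flipped, beta),
            wr.estimating_function(sim_pairs, beta), atol=1e-12)
        cfg = wr.FitConfig(alpha=1.0, n_lambda=30)
        path_a = wr.fit_path(sim_pairs, cfg)
        path_b = wr.fit_path(flipped, cfg)
        np.testing.assert_allclose(path_a.lambdas, path_b.lambdas, rtol=1e-12)
        np.testing.assert_allclose(path_a.betas, path_b.betas, atol=1e-9)

    def test_ridge_never_produces_exact_zeros(self, sim_pairs):
        lmax = wr.lambda_max(sim_pairs, 0.0)
        grid = np.geomspace(lmax, lmax / 100, 10)
        path = wr.fit_path(sim_pairs, wr.FitConfig(alpha=0.0, lambda_grid=grid))
        assert np.all(path.betas != 0)

    def test_penalized_objective_nonincreasing_along_path(self, sim_pairs):
        path = wr.fit_path(sim_pairs, wr.FitConfig(alpha=1.0, n_lambda=40))
        vals = [wr.objective(sim_pairs, b, lam, 1.0)
                for lam, b in zip(path.lambdas, path.betas)]
        assert np.all(np.diff(vals) <= 1e-10)

    def test_standardization_reports_original_scale(self, sim_pairs):
        lmax = wr.lambda_max(sim_pairs, 1.0)
        grid = np.geomspace(lmax, lmax * 1e-3, 30)
        a = wr.fit_path(sim_pairs, wr.FitConfig(lambda_grid=grid))
        Xs, scale = _design(sim_pairs, True)
        assert np.allclose(np.mean(Xs * Xs, axis=0), 1.0)
        assert a.betas.shape == (30, 6) and np.all(a.scale_factors == scale)

    def test_nonconvergent_lambda_reported(self, sim_pairs):
        cfg = wr.FitConfig(alpha=1.0, max_iter=1, tol=1e-14,
                           lambda_grid=np.array([1e-4]))
        with pytest.raises(wr.ConvergenceError, match="lambda"):
            wr.fit_path(sim_pairs, cfg)


class TestFitAt:
    def test_matches_path_entry_on_grid(self, sim_pairs):
        cfg = wr.FitConfig(alpha=1.0)
        path = wr.fit_path(sim_pairs, cfg)
        lam = path.lambdas[60]
        single = wr.fit_at(sim_pairs, lam, cfg)
        np.testing.assert_allclose(single.betas[-1], path.betas[60],
                                   rtol=0, atol=1e-12)
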