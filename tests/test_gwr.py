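import numpy as np
import pytest

from wgwr.baselines import linear_aicc
from wgwr.gwr import (
    adaptive_gaussian_weights,
    fit_gwr,
    fit_local,
    gwr_aicc,
    jitter_locations,
    lonlat_to_planar,
    montecarlo_nonstationarity_test,
    optimize_bandwidth,
    predict,
)


@pytest.fixture()
def spatial_problem():
    rng = np.random.default_rng(10)
    n = 100
    locs = rng.uniform(0, 300, (n, 2))
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    beta1 = 1.0 + 2.0 * locs[:, 0] / 300.0
    y = 0.5 + beta1 * X[:, 1] - 0.7 * X[:, 2] + rng.normal(0, 0.4, n)
    return X, y, locs, beta1


class TestWeights:
    def test_kernel_closed_form(self):
        locs = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]])
        w = adaptive_gaussian_weights((0.0, 0.0), locs, q=2, exclude_self=True)
        # bandwidth = distance to 2nd nearest non-self neighbour = 10
        assert w[0] == pytest.approx(1.0)                      # d = 0
        assert w[2] == pytest.approx(np.exp(-0.5))             # d = b
        assert w[1] == pytest.approx(np.exp(-0.5 * 0.25))      # d = b/2

    def test_weights_decrease_with_distance(self, rng):
        locs = rng.uniform(0, 100, (50, 2))
        u0 = np.array([50.0, 50.0])
        w = adaptive_gaussian_weights(u0, locs, q=10)
        d = np.linalg.norm(locs - u0, axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_coincident_bandwidth_errors(self):
        locs = np.zeros((5, 2))
        with pytest.raises(ValueError, match="jitter"):
            adaptive_gaussian_weights((0.0, 0.0), locs, q=3)


class TestFitLocal:
    def test_uniform_weights_equal_ols(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = rng.normal(size=40)
        beta = fit_local(X, y, np.ones(40))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, ols, atol=1e-10)

    def test_intercept_only_weighted_mean(self, rng):
        y = rng.normal(size=30)
        w = rng.uniform(0.1, 1.0, 30)
        beta = fit_local(np.ones((30, 1)), y, w)
        assert beta[0] == pytest.approx(np.sum(w * y) / w.sum())

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        w = rng.uniform(0.01, 1.0, 20)
        beta = fit_local(X, y, w)
        W = np.diag(w)
        oracle = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_rank_deficient_errors(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, x])
        with pytest.raises(np.linalg.LinAlgError):
            fit_local(X, rng.normal(size=20), np.ones(20))


class TestFitGWR:
    def test_flat_kernel_equals_global_ols(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        m = fit_gwr(X, y, locs, q=X.shape[0], flat=True)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(m.local_coefficients - ols)) < 1e-8
        np.testing.assert_allclose(m.fitted, X @ ols, atol=1e-8)
        assert m.trace_S == pytest.approx(X.shape[1])

    def test_minimal_sample_size_runs(self, rng):
        n, m = 6, 2  # n = m + 4 just above the m+2 floor
        locs = rng.uniform(0, 10, (n, 2))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, m))])
        y = rng.normal(size=n)
        model = fit_gwr(X, y, locs, q=n)
        assert np.isfinite(model.trace_S)

    def test_hat_matrix_self_consistency(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        m = fit_gwr(X, y, locs, q=25)
        rows = np.array([m.hat_row(i) for i in range(0, 100, 7)])
        np.testing.assert_allclose(rows @ y, m.fitted[::7], atol=1e-10)
        assert X.shape[1] < m.trace_S < y.size

    def test_local_coefficient_recovery(self, spatial_problem):
        X, y, locs, beta1 = spatial_problem
        m = fit_gwr(X, y, locs, q=30)
        assert np.corrcoef(m.local_coefficients[:, 1], beta1)[0, 1] > 0.9

    def test_rigid_motion_invariance(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        locs2 = locs @ R.T + np.array([1000.0, -500.0])
        m1 = fit_gwr(X, y, locs, q=30)
        m2 = fit_gwr(X, y, locs2, q=30)
        np.testing.assert_allclose(m1.local_coefficients, m2.local_coefficients,
                                   atol=1e-8)
        assert m1.aicc == pytest.approx(m2.aicc, abs=1e-8)

    def test_recovery_error_shrinks_with_n(self):
        maes = []
        for n in (100, 200, 400):
            r = np.random.default_rng(99)
            locs = r.uniform(0, 300, (n, 2))
            X = np.column_stack([np.ones(n), r.normal(size=n)])
            beta1 = 1.0 + 2.0 * locs[:, 0] / 300.0
            y = 0.5 + beta1 * X[:, 1] + r.normal(0, 0.4, n)
            m = fit_gwr(X, y, locs, q=max(20, n // 8))
            maes.append(np.mean(np.abs(m.local_coefficients[:, 1] - beta1)))
        assert maes[2] < maes[1] < maes[0]


class TestAICc:
    def test_ols_limit_matches_linear_model_aicc(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        m = fit_gwr(X, y, locs, q=X.shape[0], flat=True)
        rss = np.sum((y - m.fitted) ** 2)
        assert m.aicc == pytest.approx(linear_aicc(y.size, rss, X.shape[1] - 1),
                                       abs=1e-8)

    def test_halving_sigma_lowers_aicc_by_2n_ln2(self):
        n, tr = 100, 8.0
        delta = gwr_aicc(n, 1.0, tr) - gwr_aicc(n, 0.25, tr)  # sigma halved
        assert delta == pytest.approx(2 * n * np.log(2))

    def test_monotone_in_trace(self):
        a = [gwr_aicc(100, 1.0, tr) for tr in (5.0, 10.0, 20.0, 40.0)]
        assert np.all(np.diff(a) > 0)

    def test_saturated_smoother_is_infinite(self):
        assert gwr_aicc(20, 1.0, 18.5) == np.inf


class TestBandwidth:
    def test_golden_section_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(4)
        n = 80
        locs = rng.uniform(0, 100, (n, 2))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta1 = 1.0 + 3.0 * locs[:, 1] / 100.0
        y = beta1 * X[:, 1] + rng.normal(0, 0.3, n)
        q_opt, _ = optimize_bandwidth(X, y, locs)
        sweep = {q: fit_gwr(X, y, locs, q).aicc for q in range(5, n + 1)}
        q_best = min(sweep, key=lambda q: (sweep[q], q))
        assert q_opt == q_best

    def test_homogeneous_data_shows_no_support_for_locality(self):
        # with a globally linear truth the AICc profile is flat: the most
        # global bandwidth sits within a small gap of the optimum, and the
        # chosen model's effective complexity stays near the OLS count
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 60
            locs = r.uniform(0, 100, (n, 2))
            X = np.column_stack([np.ones(n), r.normal(size=n)])
            y = 1.0 + 2.0 * X[:, 1] + r.normal(0, 0.5, n)
            q_opt, cache = optimize_bandwidth(X, y, locs)
            gap = fit_gwr(X, y, locs, n).aicc - cache[q_opt]
            assert abs(gap) < 4.0
            assert fit_gwr(X, y, locs, q_opt).trace_S < X.shape[1] + 3

    def test_width_one_range(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        q_opt, _ = optimize_bandwidth(X, y, locs, q_range=(40, 40))
        assert q_opt == 40


class TestPredict:
    def test_prediction_at_training_location_matches_fitted(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        m = fit_gwr(X, y, locs, q=30)
        pred = predict(m, X[:5], locs[:5])
        np.testing.assert_allclose(pred, m.fitted[:5], atol=1e-10)

    def test_flat_limit_prediction_is_global_ols(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        m = fit_gwr(X, y, locs, q=X.shape[0], flat=True)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = predict(m, X[:3], locs[:3])
        np.testing.assert_allclose(pred, X[:3] @ ols, atol=1e-8)

    def test_beats_global_ols_on_nonstationary_data(self):
        rng = np.random.default_rng(21)
        n = 300
        locs = rng.uniform(0, 300, (n, 2))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta1 = 1.0 + 3.0 * locs[:, 0] / 300.0
        y = beta1 * X[:, 1] + rng.normal(0, 0.3, n)
        tr, te = np.arange(200), np.arange(200, 300)
        m = fit_gwr(X[tr], y[tr], locs[tr], q=30)
        rmse_gwr = np.sqrt(np.mean((y[te] - predict(m, X[te], locs[te])) ** 2))
        ols, *_ = np.linalg.lstsq(X[tr], y[tr], rcond=None)
        rmse_ols = np.sqrt(np.mean((y[te] - X[te] @ ols) ** 2))
        assert rmse_gwr < rmse_ols

    def test_column_mismatch_rejected(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        m = fit_gwr(X, y, locs, q=30)
        with pytest.raises(ValueError, match="column"):
            predict(m, X[:3, :2], locs[:3])


class TestHelpers:
    def test_lonlat_projection_preserves_small_distances(self):
        # two points 0.01 deg apart in latitude: ~1.112 km
        locs = lonlat_to_planar([116.0, 116.0], [-32.0, -31.99])
        d = np.linalg.norm(locs[1] - locs[0])
        assert d == pytest.approx(6371.0 * np.radians(0.01), rel=1e-6)

    def test_jitter_breaks_exact_ties(self):
        locs = np.zeros((6, 2))
        out = jitter_locations(locs, scale=1e-6, seed=1)
        d = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        assert np.all(d[np.triu_indices(6, 1)] > 0)
        assert np.max(np.abs(out - locs)) <= 1e-6
        # seeded: reproducible
        np.testing.assert_array_equal(out, jitter_locations(locs, 1e-6, seed=1))


class TestNonstationarity:
    def test_rank_formula_minimum_p(self, rng):
        # observed exceeding every permutation gives p = 1/(n_perm+1)
        n = 60
        locs = rng.uniform(0, 100, (n, 2))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta1 = 10.0 * locs[:, 0] / 100.0
        y = beta1 * X[:, 1] + rng.normal(0, 0.1, n)
        t = montecarlo_nonstationarity_test(X, y, locs, q=15, n_perm=19, seed=0)
        assert t.p_variance[1] == pytest.approx(1.0 / 20.0)

    def test_power_on_strongly_varying_coefficient(self):
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 80
            locs = r.uniform(0, 100, (n, 2))
            X = np.column_stack([np.ones(n), r.normal(size=n)])
            beta1 = 1.0 + 4.0 * locs[:, 0] / 100.0
            y = beta1 * X[:, 1] + r.normal(0, 0.3, n)
            t = montecarlo_nonstationarity_test(X, y, locs, q=20, n_perm=99,
                                                seed=seed)
            rejections += t.p_variance[1] <= 0.05
        assert rejections >= 16

    def test_minimum_permutations_enforced(self, spatial_problem):
        X, y, locs, _ = spatial_problem
        with pytest.raises(ValueError, match="19"):
            montecarlo_nonstationarity_test(X, y, locs, q=30, n_perm=5)
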