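import numpy as np
import pandas as pd
import pytest

from dynatile.errors import UndefinedCorrelationError
from dynatile.weights import (
    GaussianProcess,
    WeightVector,
    expected_improvement,
    objective,
    optimize_weights,
    weighted_similarity,
)


def synthetic_table(n_rows, seed, noise_metric=None):
    """Score table with a shared latent signal plus per-metric noise; one
    metric can be made pure noise."""
    rng = np.random.default_rng(seed)
    signal = rng.uniform(0, 1, n_rows)
    cols = {}
    for name, scale in (("s_cosine", 1.0), ("s_frobenius", 1.0), ("s_sw", 100.0)):
        if name == noise_metric:
            values = rng.uniform(0, 1, n_rows)
        else:
            values = np.clip(signal + rng.normal(0, 0.15, n_rows), 0, 1)
        cols[name] = values * scale
    return pd.DataFrame(cols)


def grid_search(df, step):
    """Exhaustive simplex-grid oracle for the objective."""
    best = -np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for wc in ticks:
        for wf in ticks:
            wsw = 1.0 - wc - wf
            if wsw < -1e-9:
                continue
            w = WeightVector.from_array([wc, wf, max(wsw, 0.0)])
            try:
                o, *_ = objective(w, df)
            except UndefinedCorrelationError:
                continue
            best = max(best, o)
    return best


class TestWeightedSimilarity:
    def test_basis_vector_recovers_metric(self):
        w = WeightVector(1.0, 0.0, 0.0)
        assert weighted_similarity((0.7, 0.2, 0.9), w) == pytest.approx(0.7)

    def test_equal_weights_average(self):
        w = WeightVector(1 / 3, 1 / 3, 1 / 3)
        assert weighted_similarity((0.9, 0.6, 0.3), w) == pytest.approx(0.6)

    def test_permutation_symmetry(self):
        scores = (0.9, 0.6, 0.3)
        w = (0.5, 0.3, 0.2)
        perm = [2, 0, 1]
        s1 = weighted_similarity(scores, WeightVector(*w))
        s2 = weighted_similarity(
            tuple(scores[i] for i in perm), WeightVector(*(w[i] for i in perm))
        )
        assert s1 == pytest.approx(s2)

    def test_weights_must_normalize(self):
        with pytest.raises(ValueError):
            WeightVector(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            WeightVector(-0.2, 0.6, 0.6)


class TestObjective:
    def test_identical_columns_give_unit_objective(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 50)
        df = pd.DataFrame({"s_cosine": x, "s_frobenius": x, "s_sw": 100 * x})
        o, c_cos, c_frob, c_sw = objective(WeightVector(0.2, 0.3, 0.5), df)
        assert o == pytest.approx(1.0)
        assert (c_cos, c_frob, c_sw) == pytest.approx((1.0, 1.0, 1.0))

    def test_basis_weight_self_correlation(self):
        df = synthetic_table(100, seed=2)
        _, c_cos, _, _ = objective(WeightVector(1.0, 0.0, 0.0), df)
        assert c_cos == pytest.approx(1.0)

    def test_matches_independent_pearson(self):
        from scipy.stats import pearsonr

        df = synthetic_table(100, seed=3)
        w = WeightVector(0.4, 0.4, 0.2)
        o, c_cos, c_frob, c_sw = objective(w, df)
        s = (
            0.4 * df["s_cosine"] + 0.4 * df["s_frobenius"] + 0.2 * df["s_sw"] / 100.0
        ).to_numpy()
        expected = [pearsonr(s, df[c]).statistic for c in ("s_cosine", "s_frobenius", "s_sw")]
        assert (c_cos, c_frob, c_sw) == pytest.approx(tuple(expected))
        assert o == pytest.approx(np.mean(expected))

    def test_constant_column_raises(self):
        df = synthetic_table(50, seed=4)
        df["s_sw"] = 42.0
        with pytest.raises(UndefinedCorrelationError, match="s_sw"):
            objective(WeightVector(0.3, 0.3, 0.4), df)


class TestGaussianProcess:
    def test_interpolates_observations(self):
        gp = GaussianProcess(sigma2=1.0, length_scale=0.3)
        x = np.array([[0.2, 0.3, 0.5], [0.6, 0.2, 0.2]])
        y = np.array([0.4, 0.9])
        gp.fit(x, y)
        mean, var = gp.predict(x)
        assert np.allclose(mean, y, atol=1e-6)
        assert np.all(var < 1e-6)

    def test_reverts_to_prior_far_away(self):
        gp = GaussianProcess(sigma2=2.0, length_scale=0.1)
        gp.fit(np.array([[0.0, 0.0, 1.0]]), np.array([0.7]))
        mean, var = gp.predict(np.array([[50.0, 0.0, 0.0]]))
        assert mean[0] == pytest.approx(0.0, abs=1e-8)
        assert var[0] == pytest.approx(2.0, abs=1e-8)

    def test_two_point_closed_form(self):
        # direct evaluation of the 2-observation posterior mean formula
        sigma2, ell = 1.5, 0.4
        x = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        y = np.array([0.3, 0.3])
        gp = GaussianProcess(sigma2=sigma2, length_scale=ell).fit(x, y)
        mid = np.array([[0.5, 0.0, 0.0]])
        k = lambda a, b: sigma2 * np.exp(-np.sum((a - b) ** 2) / (2 * ell**2))
        kmat = np.array([[k(x[0], x[0]), k(x[0], x[1])], [k(x[1], x[0]), k(x[1], x[1])]])
        kstar = np.array([k(mid[0], x[0]), k(mid[0], x[1])])
        expected = kstar @ np.linalg.solve(kmat + 1e-10 * np.eye(2), y)
        mean, _ = gp.predict(mid)
        assert mean[0] == pytest.approx(expected, abs=1e-8)
        # symmetric observations -> symmetric posterior: gradient flat at midpoint
        left, _ = gp.predict(np.array([[0.4, 0.0, 0.0]]))
        right, _ = gp.predict(np.array([[0.6, 0.0, 0.0]]))
        assert left[0] == pytest.approx(right[0], abs=1e-10)

    def test_matches_sklearn_reference(self):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=(8, 3))
        y = rng.normal(0, 0.5, 8)
        sigma2, ell = 0.8, 0.35
        gp = GaussianProcess(sigma2=sigma2, length_scale=ell).fit(x, y)
        ref = GaussianProcessRegressor(
            kernel=ConstantKernel(sigma2, "fixed") * RBF(ell, "fixed"),
            alpha=1e-10, optimizer=None,
        ).fit(x, y)
        x_new = rng.uniform(0, 1, size=(5, 3))
        mean, var = gp.predict(x_new)
        ref_mean, ref_sd = ref.predict(x_new, return_std=True)
        assert np.allclose(mean, ref_mean, atol=1e-6)
        assert np.allclose(np.sqrt(var), ref_sd, atol=1e-5)


class TestExpectedImprovement:
    def test_zero_at_incumbent_with_no_uncertainty(self):
        assert expected_improvement(0.5, 0.0, 0.5) == pytest.approx(0.0)

    def test_positive_with_uncertainty(self):
        assert expected_improvement(0.0, 0.5, 0.8) > 0.0

    def test_monotone_in_mean(self):
        means = np.linspace(-1, 1, 21)
        ei = expected_improvement(means, np.full_like(means, 0.2), 0.3)
        assert np.all(np.diff(ei) > 0)


class TestOptimizeWeights:
    def test_budget_and_monotone_best(self):
        df = synthetic_table(120, seed=6)
        weights, trace = optimize_weights(df, n_random=5, n_guided=10, seed=0)
        assert len(trace.records) == 15
        assert (trace.records["phase"].values[:5] == "random").all()
        assert (trace.records["phase"].values[5:] == "guided").all()
        best = trace.best_so_far
        assert np.all(np.diff(best) >= 0)
        assert weights.as_array().sum() == pytest.approx(1.0)
        assert best[-1] >= trace.records["objective"][:5].max()

    def test_reproducible_given_seed(self):
        df = synthetic_table(100, seed=7)
        w1, t1 = optimize_weights(df, n_random=5, n_guided=5, seed=42)
        w2, t2 = optimize_weights(df, n_random=5, n_guided=5, seed=42)
        assert np.allclose(w1.as_array(), w2.as_array())
        pd.testing.assert_frame_equal(t1.records, t2.records)

    def test_reaches_grid_optimum_small(self):
        df = synthetic_table(150, seed=8)
        weights, trace = optimize_weights(df, n_random=10, n_guided=30, seed=1)
        best_bo = trace.best_so_far[-1]
        best_grid = grid_search(df, step=0.04)
        assert best_bo >= best_grid - 2e-3

    def test_noise_metric_weight_never_dominates(self):
        # With one pure-noise metric the mean-correlation objective has its
        # optimum at (almost) uniform weights: for two identical signal
        # columns plus noise the closed form gives exactly w = 1/3 each, so
        # the noise weight can match but should not exceed the signal
        # weights beyond sampling jitter.
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            df = synthetic_table(120, seed=100 + seed, noise_metric="s_sw")
            weights, _ = optimize_weights(df, n_random=8, n_guided=12, seed=seed)
            if weights.w_sw <= min(weights.w_cosine, weights.w_frobenius) + 0.1:
                wins += 1
        assert wins > n_seeds / 2
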