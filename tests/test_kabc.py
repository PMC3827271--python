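"""Kernel ridge regression ABC machinery against independent oracles."""

import numpy as np
import pytest

from ursabc.kabc import (
    KernelConfig,
    KrrRegressor,
    PosteriorEstimate,
    SimTable,
    krr_posterior_mean,
    load_simtable,
    rbf_kernel,
    replicate_abc,
    run_abc,
    save_simtable,
    select_hyperparams_cv,
)


def toy_problem(rng, n=120, d=4, p=2, noise=0.05):
    """theta smooth but nonlinear in s, so bandwidth genuinely matters."""
    s = rng.normal(size=(n, d))
    a = np.arange(1, d * p + 1).reshape(d, p) / (d * p)
    theta = np.sin(s @ a * 2.0) + noise * rng.normal(size=(n, p))
    return SimTable(theta=theta, s=s)


class TestRbfKernel:
    def test_zero_distance_is_one(self, rng):
        u = rng.normal(size=6)
        assert rbf_kernel(u, u, 2.0) == 1.0

    def test_symmetry(self, rng):
        u, v = rng.normal(size=6), rng.normal(size=6)
        assert rbf_kernel(u, v, 0.7) == rbf_kernel(v, u, 0.7)

    def test_closed_form_value(self):
        assert rbf_kernel([0, 0], [1, 1], 1.0) == pytest.approx(np.exp(-1.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([0, 0], [1], 1.0)


class TestKrrPosteriorMean:
    def test_matches_sklearn_kernel_ridge(self, rng):
        KernelRidge = pytest.importorskip("sklearn.kernel_ridge").KernelRidge
        for _ in range(3):
            s = rng.normal(size=(50, 5))
            theta = rng.normal(size=(50, 3))
            table = SimTable(theta=theta, s=s)
            sigma2, lam = 2.0, 1e-3
            obs = rng.normal(size=5)
            ours = krr_posterior_mean(table, obs, KernelConfig(sigma2, lam, standardize=False))
            ref = KernelRidge(alpha=table.n * lam, kernel="rbf", gamma=1 / (2 * sigma2))
            ref.fit(s, theta - theta.mean(axis=0))
            expected = theta.mean(axis=0) + ref.predict(obs.reshape(1, -1))[0]
            np.testing.assert_allclose(ours, expected, rtol=1e-8)

    def test_interpolates_as_lambda_vanishes(self, rng):
        table = toy_problem(rng, n=40)
        cfg = KernelConfig(sigma2=3.0, lam=1e-12, standardize=False)
        np.testing.assert_allclose(
            krr_posterior_mean(table, table.s[7], cfg), table.theta[7], atol=1e-6)

    def test_returns_prior_mean_as_lambda_diverges(self, rng):
        table = toy_problem(rng, n=40)
        cfg = KernelConfig(sigma2=3.0, lam=1e12, standardize=False)
        np.testing.assert_allclose(
            krr_posterior_mean(table, rng.normal(size=4), cfg),
            table.theta.mean(axis=0), atol=1e-8)

    def test_row_permutation_invariance(self, rng):
        table = toy_problem(rng)
        perm = rng.permutation(table.n)
        permuted = SimTable(theta=table.theta[perm], s=table.s[perm])
        cfg = KernelConfig(sigma2=1.5, lam=1e-3)
        obs = rng.normal(size=4)
        np.testing.assert_allclose(krr_posterior_mean(table, obs, cfg),
                                   krr_posterior_mean(permuted, obs, cfg), rtol=1e-9)

    def test_affine_rescaling_invariance_with_standardization(self, rng):
        table = toy_problem(rng)
        cfg = KernelConfig(sigma2=1.5, lam=1e-3, standardize=True)
        obs = rng.normal(size=4)
        scale = np.array([10.0, 0.1, 3.0, 1.0])
        shift = np.array([5.0, -2.0, 0.0, 100.0])
        rescaled = SimTable(theta=table.theta, s=table.s * scale + shift)
        np.testing.assert_allclose(
            krr_posterior_mean(table, obs, cfg),
            krr_posterior_mean(rescaled, obs * scale + shift, cfg), rtol=1e-8)

    def test_gram_matrix_is_psd(self, rng):
        from scipy.spatial.distance import cdist

        s = rng.normal(size=(30, 6))
        gram = np.exp(-cdist(s, s, "sqeuclidean") / (2 * 0.8))
        eigs = np.linalg.eigvalsh(gram)
        assert eigs.min() > -1e-10

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            KernelConfig(sigma2=0.0, lam=1e-3)
        with pytest.raises(ValueError):
            KernelConfig(sigma2=1.0, lam=-1.0)


class TestHyperparamSelection:
    def test_single_pair_grid_is_returned(self, rng):
        table = toy_problem(rng, n=40)
        cfg = select_hyperparams_cv(table, sigma2_grid=[2.5], lambda_grid=[1e-2], seed=0)
        assert cfg.sigma2 == 2.5 and cfg.lam == 1e-2

    def test_seeded_selection_is_reproducible(self, rng):
        table = toy_problem(rng)
        a = select_hyperparams_cv(table, seed=42)
        b = select_hyperparams_cv(table, seed=42)
        assert a == b

    def test_cv_beats_extreme_bandwidths(self, rng):
        table = toy_problem(rng, n=200, noise=0.02)
        holdout = toy_problem(rng, n=100, noise=0.02)

        def mse(cfg):
            reg = KrrRegressor(table, cfg)
            preds = np.array([reg.predict(s) for s in holdout.s])
            return float(np.mean((preds - holdout.theta) ** 2))

        best = select_hyperparams_cv(table, seed=1)
        lo = KernelConfig(sigma2=best.sigma2 * 1e-4, lam=best.lam)
        hi = KernelConfig(sigma2=best.sigma2 * 1e4, lam=best.lam)
        assert mse(best) < mse(lo)
        assert mse(best) < mse(hi)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            select_hyperparams_cv(toy_problem(rng), sigma2_grid=[], seed=0)


def cheap_gaussian_model(theta, rng):
    return theta + rng.normal(scale=0.2, size=theta.shape)


def cheap_prior(rng):
    return rng.normal(loc=[1.0, -2.0], scale=1.0)


class TestRunAbc:
    def test_point_mass_prior_returns_the_point(self, rng):
        point = np.array([3.0, 5.0])
        est = run_abc(np.array([0.0, 0.0]), lambda r: point, cheap_gaussian_model,
                      n=60, seed=1, folds=5)
        np.testing.assert_allclose(est, point, atol=1e-6)

    def test_simulator_failure_is_contextualized(self):
        def broken(theta, rng):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="simulator failed"):
            run_abc(np.zeros(2), cheap_prior, broken, n=10, seed=0)

    def test_seeded_run_reproducible(self):
        a = run_abc(np.array([1.0, -2.0]), cheap_prior, cheap_gaussian_model,
                    n=80, seed=7, folds=5)
        b = run_abc(np.array([1.0, -2.0]), cheap_prior, cheap_gaussian_model,
                    n=80, seed=7, folds=5)
        np.testing.assert_array_equal(a, b)


class TestReplicateAbc:
    def test_single_replication_warns_and_reports_zero_sd(self):
        with pytest.warns(UserWarning, match="replication SD"):
            est = replicate_abc(np.array([1.0, -2.0]), cheap_prior,
                                cheap_gaussian_model, n=50, r=1, seed=0, folds=5)
        assert (est.sd == 0).all()

    def test_identical_seeds_give_zero_spread(self):
        runs = [run_abc(np.array([1.0, -2.0]), cheap_prior, cheap_gaussian_model,
                        n=50, seed=3, folds=5) for _ in range(2)]
        assert np.std(runs, axis=0).max() == 0.0

    def test_replication_sd_shrinks_with_n(self):
        obs = np.array([1.0, -2.0])
        small = replicate_abc(obs, cheap_prior, cheap_gaussian_model,
                              n=60, r=6, seed=11, folds=5)
        large = replicate_abc(obs, cheap_prior, cheap_gaussian_model,
                              n=600, r=6, seed=11, folds=5)
        assert large.sd.mean() < small.sd.mean()

    def test_invalid_replication_count(self):
        with pytest.raises(ValueError):
            replicate_abc(np.zeros(2), cheap_prior, cheap_gaussian_model,
                          n=50, r=0, seed=0)


class TestPersistence:
    def test_tsv_round_trip(self, rng, tmp_path):
        table = toy_problem(rng, n=20)
        path = tmp_path / "table.tsv"
        save_simtable(table, path)
        back = load_simtable(path, n_params=2)
        np.testing.assert_allclose(back.theta, table.theta)
        np.testing.assert_allclose(back.s, table.s)


class TestPosteriorEstimate:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            PosteriorEstimate(mean=np.zeros(2), sd=np.array([-1.0, 0.0]), r=2, n=10)
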