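"""Bayesian sparse regressions: conjugate oracles, calibration, ELBO ascent."""

import numpy as np
import pytest

from txpred.bayes import (
    McmcSchedule,
    SpikeSlabPrior,
    default_mixture_grid,
    fit_bayesc,
    fit_go_bayesc,
    fit_veb_mixture,
    fit_vb_spike_slab,
)
from txpred.core import GroupPartition
from txpred.linear import LinearFit, fit_ridge
from conftest import random_centered


def standardized(rng, n, m):
    X = rng.standard_normal((n, m))
    X -= X.mean(0)
    X /= X.std(0, ddof=1)
    y = rng.standard_normal(n)
    y -= y.mean()
    return X, y


class TestSchedule:
    def test_long_chain_retention_arithmetic(self):
        assert McmcSchedule(130_000, 30_000, 50).retained == 2000
        assert McmcSchedule(85_000, 10_000, 50).retained == 1500

    def test_rejects_too_few_retained(self):
        with pytest.raises(ValueError, match="at least 100"):
            McmcSchedule(n_iter=200, burn_in=100, thin=10)

    def test_rejects_burnin_past_end(self):
        with pytest.raises(ValueError):
            McmcSchedule(n_iter=100, burn_in=100, thin=1)


class TestBayesC:
    def test_conjugate_case_matches_ridge(self, rng):
        """With pi=1 and fixed variances the posterior mean is ridge."""
        n, m = 100, 50
        X, _ = random_centered(rng, n, m)
        beta = np.concatenate([rng.normal(0, 0.5, 5), np.zeros(m - 5)])
        y = X @ beta + rng.standard_normal(n)
        y -= y.mean()
        sb2, se2 = 0.5, 1.0
        sched = McmcSchedule(n_iter=22_000, burn_in=2_000, thin=1, seed=3)
        ps = fit_bayesc(
            X, y, sched,
            SpikeSlabPrior(pi=1.0, fix_pi=True, sigma_beta2=sb2, sigma_e2=se2,
                           fix_variances=True),
        )
        ridge = fit_ridge(X, y, se2 / (sb2 * n)).effects
        # analytic posterior sd and a conservative effective sample size
        cov = se2 * np.linalg.inv(X.T @ X + (se2 / sb2) * np.eye(m))
        mcse = np.sqrt(np.diag(cov)) / np.sqrt(ps.retained_draws / 20)
        assert np.all(np.abs(ps.effect_mean - ridge) < 3 * mcse)

    def test_single_gene_matches_analytic_mixture_posterior(self, rng):
        n = 60
        x = rng.standard_normal((n, 1))
        x -= x.mean(0)
        y = 0.4 * x[:, 0] + rng.standard_normal(n)
        y -= y.mean()
        pi, sb2, se2 = 0.3, 0.6, 1.0
        sched = McmcSchedule(n_iter=62_000, burn_in=2_000, thin=1, seed=9)
        ps = fit_bayesc(
            x, y, sched,
            SpikeSlabPrior(pi=pi, fix_pi=True, sigma_beta2=sb2, sigma_e2=se2,
                           fix_variances=True),
        )
        d = float(x[:, 0] @ x[:, 0])
        xty = float(x[:, 0] @ y)
        c = d / se2 + 1.0 / sb2
        mu = xty / (se2 * c)
        logodds = np.log(pi / (1 - pi)) - 0.5 * np.log(sb2 * c) + 0.5 * mu**2 * c
        p_inc = 1.0 / (1.0 + np.exp(-logodds))
        post_mean = p_inc * mu
        post_var = p_inc * (1.0 / c + mu**2) - post_mean**2
        mcse = np.sqrt(post_var / (ps.retained_draws / 20))
        assert abs(ps.effect_mean[0] - post_mean) < 3 * mcse
        assert abs(ps.pip[0] - p_inc) < 3 * np.sqrt(
            p_inc * (1 - p_inc) / (ps.retained_draws / 20)
        )

    def test_null_data_pip_tracks_fixed_prior(self):
        rng = np.random.default_rng(42)
        n, m = 150, 300
        X, _ = standardized(rng, n, m)
        y = np.random.default_rng(0).standard_normal(n)
        y -= y.mean()
        sched = McmcSchedule(n_iter=4000, burn_in=1000, thin=3, seed=0)
        fixed = fit_bayesc(X, y, sched, SpikeSlabPrior(pi=0.5, fix_pi=True))
        assert abs(fixed.pip.mean() - 0.5) < 0.1
        # with the pi hyperprior the posterior may drift low, but no gene
        # should look confidently causal on pure noise
        free = fit_bayesc(X, y, sched)
        assert free.pip.max() < 0.95

    def test_residual_variance_recovered_on_noise(self):
        rng = np.random.default_rng(17)
        n, m = 200, 50
        X, _ = standardized(rng, n, m)
        y = rng.standard_normal(n)
        y -= y.mean()
        ps = fit_bayesc(X, y, McmcSchedule(4000, 1000, 3, seed=2))
        assert 0.8 <= ps.var_components["sigma_e2"] / np.var(y, ddof=1) <= 1.2

    def test_seeded_determinism(self, rng):
        X, y = standardized(rng, 40, 30)
        sched = McmcSchedule(1000, 200, 2, seed=5)
        a = fit_bayesc(X, y, sched)
        b = fit_bayesc(X, y, sched)
        np.testing.assert_array_equal(a.effect_mean, b.effect_mean)
        np.testing.assert_array_equal(a.pip, b.pip)
        assert a.var_components == b.var_components


class TestGoBayesC:
    def test_degenerate_partition_matches_plain_bayesc(self, rng):
        n, m = 100, 60
        X, _ = random_centered(rng, n, m)
        y = X[:, :4] @ rng.normal(0, 0.4, 4) + rng.standard_normal(n)
        y -= y.mean()
        prior = SpikeSlabPrior(pi=0.5, fix_pi=True, sigma_beta2=0.3,
                               sigma_e2=1.0, fix_variances=True)
        sched = McmcSchedule(6000, 1000, 2, seed=7)
        part = GroupPartition(np.arange(20), np.arange(20, m), m)
        a = fit_bayesc(X, y, sched, prior)
        b = fit_go_bayesc(X, y, part, sched, prior)
        # identical shared hyperparameters: the chains consume the same
        # random draws, so the fits coincide exactly
        np.testing.assert_allclose(a.effect_mean, b.effect_mean, atol=1e-12)

    def test_signal_concentrates_pip_in_causal_group(self):
        hits = 0
        reps = 8
        for s in range(reps):
            rng = np.random.default_rng(200 + s)
            n, m = 100, 120
            X, _ = standardized(rng, n, m)
            beta = np.zeros(m)
            beta[:10] = rng.normal(0, 0.5, 10)
            y = X @ beta + 0.5 * rng.standard_normal(n)
            y -= y.mean()
            part = GroupPartition(np.arange(10), np.arange(10, m), m)
            ps = fit_go_bayesc(X, y, part, McmcSchedule(3000, 500, 2, seed=s))
            if ps.pip[:10].mean() > ps.pip[10:].mean():
                hits += 1
        assert hits >= reps - 1

    def test_reports_both_groups(self, rng):
        X, y = standardized(rng, 50, 30)
        part = GroupPartition(np.arange(10), np.arange(10, 30), 30)
        ps = fit_go_bayesc(X, y, part, McmcSchedule(800, 300, 1, seed=1))
        for key in ("sigma_beta2_in_go", "sigma_beta2_not_go", "pi_in_go",
                    "pi_not_go", "sigma_e2"):
            assert key in ps.var_components


class TestVbSpikeSlab:
    def test_single_predictor_matches_enumerated_posterior(self, rng):
        n = 50
        x = rng.standard_normal((n, 1))
        x -= x.mean(0)
        y = 0.5 * x[:, 0] + rng.standard_normal(n)
        y -= y.mean()
        sigma2, sa2, pi = 1.0, 0.7, 0.3
        ps = fit_vb_spike_slab(
            x, y, logodds_grid=[np.log10(pi / (1 - pi))],
            sigma2=sigma2, sa2=sa2, update_hyper=False,
        )
        d = float(x[:, 0] @ x[:, 0])
        xty = float(x[:, 0] @ y)
        log_bf = -0.5 * np.log1p(sa2 * d) + 0.5 * sa2 * xty**2 / (
            sigma2 * (1 + sa2 * d)
        )
        expected = 1.0 / (1.0 + np.exp(-(np.log(pi / (1 - pi)) + log_bf)))
        assert ps.pip[0] == pytest.approx(expected, abs=1e-6)

    def test_null_data_keeps_pip_near_prior(self):
        rng = np.random.default_rng(31)
        X, y = standardized(rng, 100, 150)
        ps = fit_vb_spike_slab(X, y, logodds_grid=[-3.0])
        prior_p = 1.0 / (1.0 + 10.0**3)
        assert ps.pip.mean() <= 2 * prior_p * 10  # no mass invented on noise

    def test_huge_effect_detected(self):
        rng = np.random.default_rng(8)
        n, m = 150, 100
        X, _ = standardized(rng, n, m)
        beta = np.zeros(m)
        beta[17] = 5.0
        g = X @ beta
        e = rng.standard_normal(n)
        e *= np.sqrt(np.var(g) / 9 / np.var(e))  # h2 ~ 0.9
        y = g + e
        y -= y.mean()
        ps = fit_vb_spike_slab(X, y)
        assert ps.pip[17] > 0.95

    def test_elbo_monotone_on_random_instances(self):
        # fit_vb_spike_slab raises internally on any ELBO decrease > 1e-8
        for s in range(10):
            rng = np.random.default_rng(500 + s)
            X, y = standardized(rng, 30, 60)
            fit_vb_spike_slab(X, y)


class TestVebMixture:
    def test_reduces_to_spike_slab_on_two_point_grid(self, rng):
        n, m = 80, 40
        X, _ = standardized(rng, n, m)
        beta = np.zeros(m)
        beta[:3] = rng.normal(0, 0.6, 3)
        y = X @ beta + rng.standard_normal(n)
        y -= y.mean()
        sigma2, slab = 1.0, 0.5
        pi_in = 0.2
        vb = fit_vb_spike_slab(
            X, y, logodds_grid=[np.log10(pi_in / (1 - pi_in))],
            sigma2=sigma2, sa2=slab / sigma2, update_hyper=False,
        )
        veb = fit_veb_mixture(
            X, y, grid=np.array([0.0, slab]),
            weights=np.array([1 - pi_in, pi_in]),
            update_weights=False, sigma2=sigma2,
        )
        np.testing.assert_allclose(veb.effect_mean, vb.effect_mean, atol=1e-4)

    def test_null_data_loads_effectively_null_components(self):
        # On pure noise the weight ties among the spike and grid components
        # whose variance is far below the likelihood noise (they are
        # statistically indistinguishable), so the sharp statement is that
        # >= 90% of the prior mass is effectively null and the fitted
        # effects explain essentially nothing.
        for s in range(5):
            rng = np.random.default_rng(900 + s)
            X, y = standardized(rng, 150, 300)
            ps = fit_veb_mixture(X, y, K=10)
            w = ps.diagnostics["weights"]
            g = ps.diagnostics["grid"]
            v_lik = ps.var_components["sigma_e2"] / 150
            assert w[g <= v_lik].sum() >= 0.9
            assert np.var(X @ ps.effect_mean) / np.var(y) < 0.02

    def test_lasso_init_reaches_same_elbo(self):
        rng = np.random.default_rng(77)
        n, m = 100, 200
        X, _ = standardized(rng, n, m)
        beta = np.zeros(m)
        beta[:5] = rng.normal(0, 0.8, 5)
        y = X @ beta + 0.5 * rng.standard_normal(n)
        y -= y.mean()
        from txpred.linear import fit_lasso

        lam = 0.1 * np.max(np.abs(X.T @ y)) / n
        init = fit_lasso(X, y, lam)
        cold = fit_veb_mixture(X, y, K=15, max_iter=1000)
        warm = fit_veb_mixture(X, y, K=15, init=init, max_iter=1000)
        assert abs(cold.var_components["elbo"] - warm.var_components["elbo"]) < 1e-3 * (
            1 + abs(cold.var_components["elbo"])
        )
        assert warm.var_components["n_iterations"] <= 1000

    def test_default_grid_shape(self, rng):
        X, y = standardized(rng, 30, 20)
        grid = default_mixture_grid(X, y, K=12)
        assert grid[0] == 0.0 and grid.size == 13
        assert np.all(np.diff(grid[1:]) > 0)
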