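"""TRM construction and the (GO-)TBLUP mixed models."""

import numpy as np
import pytest

from txpred.bayes import McmcSchedule
from txpred.core import ExpressionMatrix, standardize_columns
from txpred.kernel import (
    Kernel,
    blup_conditional_mean,
    build_trm,
    fit_go_tblup,
    fit_tblup,
    predict_kernel_masked,
)
from txpred.simulate import SimulationConfig, simulate_dataset

SHORT = McmcSchedule(n_iter=4000, burn_in=1000, thin=3, seed=0)


def random_standardized(rng, n, m):
    vals = rng.standard_normal((n, m))
    X = ExpressionMatrix(
        [f"L{i}" for i in range(n)], [f"g{j}" for j in range(m)], vals
    )
    return standardize_columns(X)


class TestTrm:
    def test_two_line_kernel_by_hand(self):
        X = ExpressionMatrix(["a", "b"], ["g1", "g2"], [[1.0, 1.0], [3.0, 2.0]])
        T = build_trm(standardize_columns(X))
        np.testing.assert_allclose(T.values, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)
        assert np.trace(T.values) == pytest.approx(1.0)

    def test_trace_is_n_minus_one(self, rng):
        X = random_standardized(rng, 17, 90)
        T = build_trm(X)
        assert np.trace(T.values) == pytest.approx(16.0, abs=1e-6)

    def test_subset_kernels_add_back_to_total(self, rng):
        X = random_standardized(rng, 12, 50)
        sub = list(X.gene_ids[:20])
        comp = list(X.gene_ids[20:])
        T, T1, T2 = build_trm(X), build_trm(X, sub), build_trm(X, comp)
        np.testing.assert_allclose(
            20 * T1.values + 30 * T2.values, 50 * T.values, atol=1e-10
        )

    def test_requires_standardized_matrix(self, rng):
        X = ExpressionMatrix(["a", "b", "c"], ["g"], rng.standard_normal((3, 1)))
        with pytest.raises(ValueError, match="standardized"):
            build_trm(X)

    def test_empty_subset_rejected(self, rng):
        X = random_standardized(rng, 5, 10)
        with pytest.raises(ValueError):
            build_trm(X, [])


class TestTblup:
    def test_gblup_equals_rrblup_at_fixed_ratio(self):
        """T(T+rho I)^-1 y must equal ridge on the standardized genes."""
        for s in range(5):
            rng = np.random.default_rng(s)
            n, m = 20, 100
            X = random_standardized(rng, n, m)
            y = rng.standard_normal(n)
            y -= y.mean()
            rho = float(rng.uniform(0.2, 5.0))
            T = build_trm(X)
            idx = np.arange(n)
            that = blup_conditional_mean(T.values, y, idx, idx, rho)
            W = X.values
            beta = np.linalg.solve(W.T @ W + m * rho * np.eye(m), W.T @ y)
            np.testing.assert_allclose(that, W @ beta, atol=1e-6)

    def test_schedule_retention(self):
        assert McmcSchedule(85_000, 10_000, 50).retained == 1500

    def test_variance_share_recovery_dense_h2_08(self):
        cfg = SimulationConfig(n_lines=180, n_genes=1000, n_blocks=50,
                               architecture="dense", heritability=0.8,
                               n_terms=0, seed=21)
        ds, _ = simulate_dataset(cfg)
        y = ds.phenotype.values - ds.phenotype.values.mean()
        fit = fit_tblup(y, build_trm(ds.expression), SHORT)
        share = fit.var_components["variance_share"][0]
        assert 0.7 <= share <= 0.9

    def test_non_psd_kernel_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        K = Kernel(("a", "b"), bad, n_genes_used=2)
        with pytest.raises(ValueError, match="PSD"):
            fit_tblup(np.array([0.5, -0.5]), K, SHORT)

    def test_seeded_determinism(self, rng):
        X = random_standardized(rng, 25, 60)
        y = rng.standard_normal(25)
        y -= y.mean()
        T = build_trm(X)
        sched = McmcSchedule(1000, 200, 2, seed=4)
        a, b = fit_tblup(y, T, sched), fit_tblup(y, T, sched)
        np.testing.assert_array_equal(a.fitted_t, b.fitted_t)


class TestGoTblup:
    def test_shared_signal_two_identical_kernels_match_single(self, rng):
        n, m = 60, 200
        X = random_standardized(rng, n, m)
        beta = rng.normal(0, 1 / np.sqrt(m), m)
        y = X.values @ beta + 0.5 * rng.standard_normal(n)
        y -= y.mean()
        T = build_trm(X)
        one = fit_tblup(y, T, McmcSchedule(6000, 1000, 2, seed=3))
        two = fit_go_tblup(y, T, T, McmcSchedule(6000, 1000, 2, seed=3))
        # aliasing check: total fitted effect agrees within MC error
        resid = one.fitted_t - two.fitted_t
        assert np.max(np.abs(resid)) < 0.15 * np.std(y)

    def test_go_concentrated_signal_raises_go_variance(self):
        hits = 0
        reps = 8
        for s in range(reps):
            cfg = SimulationConfig(
                n_lines=100, n_genes=300, n_blocks=30,
                architecture="go_concentrated", n_causal=10, heritability=0.8,
                n_terms=5, term_size_range=(12, 20),
                causal_term_id="TERM:0001", seed=300 + s,
            )
            ds, _ = simulate_dataset(cfg)
            genes = sorted(ds.gene_sets.genes("TERM:0001"))
            rest = [g for g in ds.expression.gene_ids if g not in set(genes)]
            T_go = build_trm(ds.expression, genes)
            T_ng = build_trm(ds.expression, rest)
            y = ds.phenotype.values - ds.phenotype.values.mean()
            fit = fit_go_tblup(y, T_go, T_ng,
                               McmcSchedule(2000, 500, 2, seed=s))
            if (fit.var_components["sigma_t2_go"][0]
                    > fit.var_components["sigma_t2_not_go"][0]):
                hits += 1
        assert hits >= reps - 1

    def test_mismatched_line_ids_rejected(self, rng):
        X = random_standardized(rng, 10, 20)
        T1 = build_trm(X)
        T2 = Kernel(tuple(reversed(T1.line_ids)), T1.values, 20)
        with pytest.raises(ValueError, match="line"):
            fit_go_tblup(np.zeros(10), T1, T2, SHORT)

    def test_component_effects_sum_to_total(self, rng):
        X = random_standardized(rng, 30, 80)
        y = rng.standard_normal(30)
        y -= y.mean()
        T1 = build_trm(X, list(X.gene_ids[:30]))
        T2 = build_trm(X, list(X.gene_ids[30:]))
        fit = fit_go_tblup(y, T1, T2, McmcSchedule(800, 300, 1, seed=2))
        np.testing.assert_allclose(
            fit.components["go"] + fit.components["not_go"], fit.fitted_t,
            atol=1e-8,
        )


class TestMaskedPrediction:
    def test_oracle_mode_equals_conditional_mean(self, rng):
        n = 30
        X = random_standardized(rng, n, 80)
        y = rng.standard_normal(n)
        y -= y.mean()
        T = build_trm(X)
        test_ids = [f"L{i}" for i in (2, 9, 17)]
        mask = np.array([i in set(test_ids) for i in X.line_ids])
        pred = predict_kernel_masked(y[~mask], T, SHORT, test_ids, oracle_rho=1.5)
        ref = blup_conditional_mean(
            T.values, y[~mask], np.flatnonzero(~mask), np.flatnonzero(mask), 1.5
        )
        np.testing.assert_allclose(pred, ref, atol=1e-6)

    def test_unrelated_test_line_predicted_at_prior_mean(self):
        # a test line with zero kernel covariance to every training line
        n = 10
        vals = np.eye(n)
        vals[-1, -1] = 1.0
        vals[-1, :-1] = 0.0
        vals[:-1, -1] = 0.0
        K = Kernel(tuple(f"L{i}" for i in range(n)), vals, n_genes_used=5)
        y = np.random.default_rng(0).standard_normal(n - 1)
        y -= y.mean()
        pred = predict_kernel_masked(y, K, SHORT, [f"L{n-1}"], oracle_rho=0.5)
        assert pred[0] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_line_interpolated_as_rho_vanishes(self, rng):
        n = 12
        X = random_standardized(rng, n, 40)
        W = np.vstack([X.values, X.values[3]])  # duplicate line 3 as test row
        ids = tuple(list(X.line_ids) + ["dup"])
        T = Kernel(ids, W @ W.T / 40, n_genes_used=40)
        y = rng.standard_normal(n)
        y -= y.mean()
        pred = predict_kernel_masked(y, T, SHORT, ["dup"], oracle_rho=1e-8)
        assert pred[0] == pytest.approx(y[3], abs=1e-3)

    def test_unknown_test_id_rejected(self, rng):
        X = random_standardized(rng, 8, 10)
        T = build_trm(X)
        with pytest.raises(ValueError, match="absent"):
            predict_kernel_masked(np.zeros(8), T, SHORT, ["nope"])

    def test_sampler_prediction_close_to_oracle_at_matched_ratio(self, rng):
        # with variances fixed near truth the MCMC route should agree with
        # the closed form up to Monte Carlo error
        cfg = SimulationConfig(n_lines=60, n_genes=400, n_blocks=40,
                               architecture="dense", heritability=0.6,
                               n_terms=0, seed=5)
        ds, _ = simulate_dataset(cfg)
        T = build_trm(ds.expression)
        y = ds.phenotype.values - ds.phenotype.values.mean()
        test_ids = list(ds.expression.line_ids[:6])
        mask = np.array([i in set(test_ids) for i in ds.expression.line_ids])
        sched = McmcSchedule(8000, 2000, 3, seed=9)
        pred = predict_kernel_masked(y[~mask], T, sched, test_ids)
        ref = blup_conditional_mean(
            T.values, y[~mask], np.flatnonzero(~mask), np.flatnonzero(mask),
            (1 - 0.6) / 0.6,
        )
        assert np.corrcoef(pred, ref)[0, 1] > 0.95
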