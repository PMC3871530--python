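"""Conjugate posterior, modified Gibbs sampler and network assembly."""

import numpy as np
import pytest

from lrbi import (
    Dataset,
    GRNModel,
    LRBI,
    LRBIConfig,
    NoiseSpec,
    PriorSpec,
    RowRegression,
    build_row_regression,
    conjugate_posterior,
    default_prior,
    generate_expression,
    gibbs_step,
    infer_network,
    infer_row,
)
from lrbi.core import CoefLabel
from lrbi.inference import _init_state


def _row_from_arrays(y, D, gene_index=0):
    k = D.shape[0]
    labels = tuple(CoefLabel("B", gene_index, j) for j in range(1, k)) + (
        CoefLabel("F", gene_index, gene_index),)
    return RowRegression(gene_index=gene_index, response=np.asarray(y, float),
                         design=np.asarray(D, float), coef_labels=labels)


class TestConjugatePosterior:
    def test_single_observation_by_hand(self):
        """One observation on the first regressor: Lambda_n = I + e1 e1',
        mu_n = (1, 0, ..., 0)."""
        k = 4
        D = np.zeros((k, 1))
        D[0, 0] = 1.0
        row = _row_from_arrays([2.0], D)
        prior = PriorSpec(mu0=np.zeros(k), Lambda0=np.eye(k))
        mu_n, Lambda_n, alpha_n, beta_n = conjugate_posterior(row, prior)
        expected_L = np.eye(k)
        expected_L[0, 0] = 2.0
        np.testing.assert_allclose(Lambda_n, expected_L)
        np.testing.assert_allclose(mu_n, [1.0, 0, 0, 0])
        assert alpha_n == pytest.approx(1.5)
        # beta_n = beta0 + (y.y - mu_n' Lambda_n mu_n)/2 = 1 + (4 - 2)/2
        assert beta_n == pytest.approx(2.0)

    def test_overwhelming_prior_pins_mean_at_mu0(self):
        rng = np.random.default_rng(0)
        row = _row_from_arrays(rng.normal(size=20), rng.normal(size=(3, 20)))
        mu0 = np.array([0.3, -0.7, 1.1])
        prior = PriorSpec(mu0=mu0, Lambda0=1e8 * np.eye(3))
        mu_n, *_ = conjugate_posterior(row, prior)
        np.testing.assert_allclose(mu_n, mu0, atol=1e-5)

    def test_large_sample_mean_matches_least_squares(self):
        """At N=10^4 with weak prior, mu_n agrees with the OLS oracle."""
        rng = np.random.default_rng(1)
        theta = np.array([0.8, -0.5, 0.0, 1.0])
        D = rng.normal(size=(4, 10_000))
        y = theta @ D + rng.normal(0, 0.1, 10_000)
        row = _row_from_arrays(y, D)
        mu_n, *_ = conjugate_posterior(row, default_prior(row))
        ols, *_ = np.linalg.lstsq(D.T, y, rcond=None)
        np.testing.assert_allclose(mu_n, ols, atol=1e-3)


class TestGibbsStep:
    def test_fixed_rng_gives_identical_trajectory(self):
        rng_data = np.random.default_rng(2)
        row = _row_from_arrays(rng_data.normal(size=30),
                               rng_data.normal(size=(3, 30)))
        prior = default_prior(row)
        chains = []
        for _ in range(2):
            state = _init_state(row, prior)
            rng = np.random.default_rng(99)
            for _ in range(50):
                gibbs_step(state, row, prior, rng)
            chains.append(np.array(state.sample_history))
        np.testing.assert_array_equal(chains[0], chains[1])

    def test_draw_mean_matches_posterior_mean(self):
        """Coefficient draws are centered at mu_n: the empirical mean over
        10^4 post-burn-in draws agrees within 3 Monte-Carlo SEs."""
        rng_data = np.random.default_rng(3)
        theta = np.array([0.5, -0.4, 1.0])
        D = rng_data.normal(size=(3, 100))
        y = theta @ D + rng_data.normal(0, 0.1, 100)
        row = _row_from_arrays(y, D)
        prior = default_prior(row)
        state = _init_state(row, prior)
        rng = np.random.default_rng(4)
        n, burn = 11_000, 1000
        for _ in range(n):
            gibbs_step(state, row, prior, rng)
        draws = np.array(state.sample_history[burn:])
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - state.mu_n) < 3 * mc_se + 1e-12)

    def test_near_noise_free_draws_concentrate_on_truth(self):
        rng_data = np.random.default_rng(5)
        theta = np.array([0.9, -0.6, 1.0])
        D = rng_data.normal(size=(3, 1000))
        y = theta @ D + rng_data.normal(0, 1e-3, 1000)
        row = _row_from_arrays(y, D)
        prior = default_prior(row)
        state = _init_state(row, prior)
        rng = np.random.default_rng(6)
        for _ in range(400):
            gibbs_step(state, row, prior, rng)
        second_half = np.array(state.sample_history[200:])
        assert np.all(second_half.std(axis=0) < 0.02)
        np.testing.assert_allclose(second_half.mean(axis=0), theta, atol=0.01)


class TestInferRow:
    def test_huge_epsilon_stops_at_first_checkpoint_after_min_iters(self):
        rng_data = np.random.default_rng(7)
        row = _row_from_arrays(rng_data.normal(size=20),
                               rng_data.normal(size=(3, 20)))
        cfg = LRBIConfig(epsilon=1e6, min_iters=200, max_iters=5000,
                         check_every=50)
        _, diag = infer_row(row, default_prior(row), cfg,
                            np.random.default_rng(0))
        assert diag["converged"]
        assert diag["iterations"] == 200

    def test_identifiable_row_matches_ols(self):
        rng_data = np.random.default_rng(8)
        theta = np.array([0.7, 0.0, -0.8, 1.0])
        D = rng_data.normal(size=(4, 2000))
        y = theta @ D + rng_data.normal(0, 1e-3, 2000)
        row = _row_from_arrays(y, D)
        est, _ = infer_row(row, default_prior(row), LRBIConfig(),
                           np.random.default_rng(1))
        ols, *_ = np.linalg.lstsq(D.T, y, rcond=None)
        np.testing.assert_allclose(est, ols, atol=1e-2)

    def test_smaller_epsilon_does_not_worsen_gap_to_posterior_mean(self):
        """Mean gap to mu_n over seeds is no larger at eps/2 than at eps."""
        rng_data = np.random.default_rng(9)
        theta = np.array([0.6, -0.5, 1.0])
        D = rng_data.normal(size=(3, 80))
        y = theta @ D + rng_data.normal(0, 0.1, 80)
        row = _row_from_arrays(y, D)
        prior = default_prior(row)
        gaps = {}
        for eps in (2e-4, 1e-4):
            g = []
            for s in range(20):
                cfg = LRBIConfig(epsilon=eps, min_iters=200, max_iters=20_000,
                                 check_every=50)
                est, diag = infer_row(row, prior, cfg, np.random.default_rng(s))
                g.append(np.linalg.norm(est - diag["mu_n"]))
            gaps[eps] = np.mean(g)
        assert gaps[1e-4] <= gaps[2e-4] * 1.05


class TestInferNetwork:
    def test_deterministic_and_zero_diagonal(self, tiny_dataset):
        _, data = tiny_dataset
        cfg = LRBIConfig(seed=21)
        a = infer_network(data, config=cfg)
        b = LRBI(data, cfg).fit()
        np.testing.assert_array_equal(a.B_hat, b.B_hat)
        assert np.all(np.diag(a.B_hat) == 0)

    def test_recovers_tiny_cascade(self, tiny_dataset):
        model, data = tiny_dataset
        res = LRBI(data, LRBIConfig(seed=3)).fit()
        assert res.edge_positions() >= model.edge_set()
        for i, j in model.edge_set():
            assert abs(res.B_hat[i, j] - model.B[i, j]) < 0.1
        np.testing.assert_allclose(res.F_hat, 1.0, atol=0.1)

    def test_threshold_nesting_without_refit(self, tiny_dataset):
        _, data = tiny_dataset
        res = LRBI(data, LRBIConfig(seed=4, threshold=0.05)).fit()
        e_05 = res.edge_positions()
        e_10 = res.with_threshold(0.1).edge_positions()
        e_20 = res.with_threshold(0.2).edge_positions()
        assert e_20 <= e_10 <= e_05
        assert all(abs(w) >= 0.1 for *_, w in res.with_threshold(0.1).edges)

    def test_null_network_rarely_calls_edges(self):
        """With no true edges and ample data, spurious calls are rare."""
        false_rates = []
        for s in range(10):
            model = GRNModel(B=np.zeros((6, 6)), F=np.eye(6))
            rng = np.random.default_rng(s)
            X = rng.choice([0, 1, 2], size=(6, 300), p=[0.25, 0.5, 0.25])
            data = generate_expression(model, X, NoiseSpec(0.01), seed=s)
            res = LRBI(data, LRBIConfig(seed=s)).fit()
            false_rates.append(len(res.edges) / (6 * 5))
        assert np.mean(false_rates) < 0.05

    def test_per_gene_substreams_match_standalone_rows(self, tiny_dataset):
        """Row inference is order-independent: the full fit reproduces each
        row run in isolation with its own substream."""
        _, data = tiny_dataset
        cfg = LRBIConfig(seed=17)
        full = LRBI(data, cfg).fit()
        from lrbi.inference import _gene_rng

        row = build_row_regression(data, 2)
        est, _ = infer_row(row, default_prior(row), cfg, _gene_rng(17, 2))
        for c, lab in zip(est, row.coef_labels):
            if lab.kind == "B":
                assert full.B_hat[lab.target, lab.regulator] == c
            else:
                assert full.F_hat[lab.target] == c

    def test_standardize_flag_changes_scale_not_determinism(self, tiny_dataset):
        _, data = tiny_dataset
        a = LRBI(data, LRBIConfig(seed=5, standardize=True)).fit()
        b = LRBI(data, LRBIConfig(seed=5, standardize=True)).fit()
        np.testing.assert_array_equal(a.B_hat, b.B_hat)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LRBIConfig(epsilon=0)
        with pytest.raises(ValueError):
            LRBIConfig(min_iters=100, max_iters=100)
        with pytest.raises(ValueError):
            LRBIConfig(threshold=-0.1)
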