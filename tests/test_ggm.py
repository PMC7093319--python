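"""Estimation: Spearman input, constrained MLE, and the three estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prsnet
from prsnet.ggm import gaussian_loglik

from helpers import (constrained_mle_by_optimizer, pcor_by_schur,
                     random_correlation_matrix, spearman_no_ties)


class TestSpearmanMatrix:
    def test_monotone_transform_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"x": x, "y": np.exp(x) + 5})
        S = prsnet.spearman_matrix(df)
        assert S.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self):
        x = np.arange(20.0)
        S = prsnet.spearman_matrix(pd.DataFrame({"x": x, "y": -x}))
        assert S.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_ranked_toy_table(self):
        """5-row table without ties matches the classical 6*sum(d^2) formula;
        a tied table matches Pearson-on-midranks."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 9.0, 7.0, 3.0])
        S = prsnet.spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        assert S.matrix[0, 1] == pytest.approx(spearman_no_ties(x, y), abs=1e-12)

        xt = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        yt = np.array([2.0, 3.0, 3.0, 5.0, 1.0])
        St = prsnet.spearman_matrix(pd.DataFrame({"x": xt, "y": yt}))
        rx, ry = stats.rankdata(xt), stats.rankdata(yt)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert St.matrix[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "flat": [2.0, 2, 2, 2]})
        with pytest.raises(prsnet.EstimationError, match="flat"):
            prsnet.spearman_matrix(df)

    def test_too_few_complete_pairs_rejected(self):
        df = pd.DataFrame({
            "a": [1.0, 2, np.nan, np.nan, 3],
            "b": [np.nan, np.nan, 1.0, 2, 3],
            "c": [1.0, 3, 2, 5, 4],
        })
        with pytest.raises(prsnet.EstimationError, match="complete"):
            prsnet.spearman_matrix(df)

    def test_pairwise_complete_under_missingness(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 3))
        X[rng.random((200, 3)) < 0.1] = np.nan
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        S = prsnet.spearman_matrix(df)
        # oracle: scipy on each pair's complete cases
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            ok = df.iloc[:, i].notna() & df.iloc[:, j].notna()
            expected = stats.spearmanr(df.iloc[:, i][ok], df.iloc[:, j][ok]).statistic
            assert S.matrix[i, j] == pytest.approx(expected, abs=1e-12)
        assert S.n_effective <= 200

    def test_matrix_contract(self, small_corr):
        M = small_corr.matrix
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.all(np.diag(M) == 1.0)
        assert np.all(np.abs(M) <= 1 + 1e-12)
        assert np.linalg.eigvalsh(M)[0] > -1e-10

    def test_psd_repair_flag(self):
        # a rank-breaking pattern of missingness can make the pairwise
        # matrix indefinite; build one directly via monkey table
        df = pd.DataFrame({
            "a": [1.0, 2, 3, 4, 5, 6, np.nan, np.nan],
            "b": [2.0, 1, 4, 3, np.nan, np.nan, 1, 2],
            "c": [np.nan, np.nan, 1.0, 2, 5, 3, 2, 1],
            "d": [1.0, 3, np.nan, np.nan, 2, 5, 4, 2],
        })
        S = prsnet.spearman_matrix(df)
        assert np.linalg.eigvalsh(S.matrix)[0] >= -1e-10


class TestPrecisionToPcor:
    def test_two_by_two_formula(self):
        out = prsnet.precision_to_pcor(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        assert out[0, 1] == pytest.approx(0.5, abs=1e-15)
        assert out[0, 0] == 0

    def test_chain_conditional_independence_zero(self):
        # X - Y - Z chain: X independent of Z given Y
        rho = 0.6
        cov = np.array([[1, rho, rho * rho],
                        [rho, 1, rho],
                        [rho * rho, rho, 1.0]])
        pcor = prsnet.precision_to_pcor(np.linalg.inv(cov))
        assert abs(pcor[0, 2]) < 1e-12

    def test_matches_regression_residual_oracle(self):
        rng = np.random.default_rng(5)
        R = random_correlation_matrix(6, rng)
        pcor = prsnet.precision_to_pcor(np.linalg.inv(R))
        for i in range(6):
            for j in range(i + 1, 6):
                assert pcor[i, j] == pytest.approx(pcor_by_schur(R, i, j), abs=1e-8)

    def test_rejects_non_pd(self):
        with pytest.raises(prsnet.InputError):
            prsnet.precision_to_pcor(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestConstrainedFit:
    def test_saturated_equals_inverse(self, small_corr):
        p = small_corr.p
        adj = ~np.eye(p, dtype=bool)
        fit = prsnet.fit_constrained_ggm(small_corr, adj)
        assert np.max(np.abs(fit.precision - np.linalg.inv(small_corr.matrix))) < 1e-10

    def test_empty_gives_diagonal(self, small_corr):
        p = small_corr.p
        adj = np.zeros((p, p), dtype=bool)
        fit = prsnet.fit_constrained_ggm(small_corr, adj)
        expected = np.diag(1.0 / np.diag(small_corr.matrix))
        assert np.max(np.abs(fit.precision - expected)) < 1e-12

    def test_chain_moment_conditions_and_optimizer_oracle(self):
        rng = np.random.default_rng(7)
        S = random_correlation_matrix(4, rng)
        adj = np.zeros((4, 4), dtype=bool)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = True
        fit = prsnet.fit_constrained_ggm(S, adj, n=100)
        Kinv = np.linalg.inv(fit.precision)
        modeled = adj | np.eye(4, dtype=bool)
        assert np.max(np.abs((Kinv - S)[modeled])) < 1e-8
        assert np.max(np.abs(fit.precision[~modeled])) == 0.0
        K_oracle = constrained_mle_by_optimizer(S, adj)
        assert np.max(np.abs(fit.precision - K_oracle)) < 1e-6

    def test_idempotent_on_own_pattern(self, small_corr):
        model = prsnet.estimate_threshold(small_corr)
        refit = prsnet.fit_constrained_ggm(small_corr, model.adjacency)
        assert refit.loglik == pytest.approx(model.loglik, abs=1e-10)

    def test_saturated_pcor_matches_direct_computation(self, small_corr):
        p = small_corr.p
        adj = ~np.eye(p, dtype=bool)
        fit = prsnet.fit_constrained_ggm(small_corr, adj)
        via_fit = prsnet.precision_to_pcor(fit.precision)
        direct = prsnet.precision_to_pcor(np.linalg.inv(small_corr.matrix))
        assert np.max(np.abs(via_fit - direct)) < 1e-8


class TestModelBic:
    def test_reference_values(self):
        assert prsnet.model_bic(0.0, 0, 10) == 0.0
        assert prsnet.model_bic(0.0, 3, int(np.e ** 2)) == pytest.approx(
            3 * np.log(int(np.e ** 2)))

    def test_identity_prefers_empty_model(self):
        S = np.eye(4)
        adj_full = ~np.eye(4, dtype=bool)
        adj_empty = np.zeros((4, 4), dtype=bool)
        n = 500
        ll_full = prsnet.fit_constrained_ggm(S, adj_full, n).loglik
        ll_empty = prsnet.fit_constrained_ggm(S, adj_empty, n).loglik
        assert ll_full == pytest.approx(ll_empty, abs=1e-8)
        bic_full = prsnet.model_bic(ll_full, 4 + 6, n)
        bic_empty = prsnet.model_bic(ll_empty, 4, n)
        assert bic_empty < bic_full


class TestModselect:
    def test_bic_sequence_strictly_decreasing(self, small_corr):
        model = prsnet.estimate_modselect(small_corr)
        seq = model.settings["bic_sequence"]
        assert all(b2 < b1 for b1, b2 in zip(seq, seq[1:]))

    def test_weights_adjacency_consistency(self, small_corr):
        model = prsnet.estimate_modselect(small_corr)
        assert np.array_equal(model.weights != 0, model.adjacency)
        assert model.bic == pytest.approx(
            prsnet.model_bic(model.loglik, model.k_params, model.n))

    def test_recovers_planted_chain(self):
        """Stepwise BIC on ordinal data from a 6-node chain finds every chain
        edge; any spurious extra is weak (the 20-seed exact-recovery rate is
        exercised in the acceptance suite)."""
        from conftest import chain_network
        net = chain_network(p=6, rho=0.3)
        ds = prsnet.sample_dataset(net, 5000, seed=40)
        model = prsnet.estimate_modselect(prsnet.spearman_matrix(ds))
        assert np.all(model.adjacency[net.adjacency])  # sensitivity 1
        extras = model.adjacency & ~net.adjacency
        assert np.all(np.abs(model.weights[extras]) < 0.1)

    def test_start_empty_agrees_on_well_identified_data(self, small_corr):
        a = prsnet.estimate_modselect(small_corr, start="path_best")
        b = prsnet.estimate_modselect(small_corr, start="empty")
        # both local optima of the same BIC; on this well-identified dataset
        # they coincide
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_warns_when_n_below_p(self):
        rng = np.random.default_rng(9)
        S = random_correlation_matrix(5, rng)
        with pytest.warns(UserWarning, match="stepwise"):
            prsnet.estimate_modselect(S, n=5, start="empty", max_sweeps=2)


class TestEbicPath:
    def test_identity_selects_empty_graph(self):
        model = prsnet.estimate_ebic_path(np.eye(5), n=500)
        assert model.n_edges == 0

    def test_lambda_max_gives_empty_graph(self, small_corr):
        from sklearn.covariance import graphical_lasso
        lam_max = float(np.max(np.abs(
            small_corr.matrix[~np.eye(small_corr.p, dtype=bool)])))
        _, prec = graphical_lasso(small_corr.matrix, alpha=lam_max, mode="cd")
        off = prec[~np.eye(small_corr.p, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-8

    def test_recovers_planted_structure_reasonably(self, small_net, small_corr):
        model = prsnet.estimate_ebic_path(small_corr)
        true = np.triu(small_net.adjacency, 1)
        est = np.triu(model.adjacency, 1)
        sens = (true & est).sum() / true.sum()
        assert sens >= 0.8


class TestThreshold:
    def test_fisher_z_worked_example(self):
        """rho=0.1 among 43 variables at n=2180 survives alpha=0.01
        (independent normal-quantile computation)."""
        nvars, n, alpha, rho = 43, 2180, 0.01, 0.1
        z = np.arctanh(rho) * np.sqrt(n - (nvars - 2) - 3)
        crit = stats.norm.isf(alpha / 2)
        assert z > crit  # ~4.64 vs 2.5758

        # wire it through the estimator on a matrix with that partial corr
        K = np.eye(nvars)
        K[0, 1] = K[1, 0] = -rho
        S = np.linalg.inv(K)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        model = prsnet.estimate_threshold(S, n=n, alpha=alpha)
        assert model.adjacency[0, 1]

    def test_exact_zero_partial_never_retained(self):
        cov = np.array([[1, 0.6, 0.36], [0.6, 1, 0.6], [0.36, 0.6, 1.0]])
        model = prsnet.estimate_threshold(cov, n=1000, alpha=0.5)
        assert not model.adjacency[0, 2]  # X indep Z given Y in the chain

    def test_alpha_one_returns_saturated(self, small_corr):
        model = prsnet.estimate_threshold(small_corr, alpha=1.0)
        p = small_corr.p
        assert model.n_edges == p * (p - 1) // 2

    def test_df_exhausted_rejected(self):
        rng = np.random.default_rng(11)
        S = random_correlation_matrix(6, rng)
        with pytest.raises(prsnet.InputError, match="degrees of freedom"):
            prsnet.estimate_threshold(S, n=6)

    def test_retained_weights_are_saturated_values(self, small_corr):
        model = prsnet.estimate_threshold(small_corr)
        sat = prsnet.precision_to_pcor(np.linalg.inv(small_corr.matrix))
        assert np.allclose(model.weights[model.adjacency], sat[model.adjacency])


class TestEstimatorAgreement:
    def test_all_three_agree_on_strong_planted_network(self):
        """With all planted |rho| >= 0.25 and n = 10k, the three estimators
        return the same adjacency."""
        from conftest import chain_network
        net = chain_network(p=8, rho=0.3)
        ds = prsnet.sample_dataset(net, 10_000, seed=60)
        S = prsnet.spearman_matrix(ds)
        a = prsnet.estimate_modselect(S)
        b = prsnet.estimate_ebic_path(S)
        c = prsnet.estimate_threshold(S)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.adjacency, c.adjacency)
        assert np.array_equal(a.adjacency, net.adjacency)

    def test_planted_weights_recovered_within_tolerance(self):
        """Planted nonzero weights estimated within +-0.05 at n = 10k,
        against the discretization-attenuated oracle."""
        from conftest import chain_network
        net = chain_network(p=6, rho=0.3)
        ds = prsnet.sample_dataset(net, 10_000, seed=61)
        S = prsnet.spearman_matrix(ds)
        model = prsnet.estimate_modselect(S)
        # oracle weights: GGM of the large-n Spearman matrix (attenuated scale)
        big = prsnet.sample_dataset(net, 200_000, seed=62)
        Sbig = prsnet.spearman_matrix(big)
        oracle = prsnet.precision_to_pcor(np.linalg.inv(Sbig.matrix))
        for i, j in zip(*np.where(np.triu(net.adjacency, 1))):
            assert model.weights[i, j] == pytest.approx(oracle[i, j], abs=0.05)
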