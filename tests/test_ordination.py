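"""PCA, RDA, forward selection, FDR and variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from germfda.ordination import (collinearity_prune, fdr_bh, forward_select,
                                pca_unstandardized, permutation_test,
                                rda_adjusted_r2, variance_partition)


class TestCollinearityPrune:
    def test_perfect_pair_drops_one(self, rng):
        a = rng.standard_normal(30)
        env = pd.DataFrame({"A": a, "B": 2 * a, "C": rng.standard_normal(30)})
        pruned, log = collinearity_prune(env)
        assert pruned.shape[1] == 2
        assert len(log) == 1 and log[0]["reason"] == "collinear"

    def test_greedy_rule_drops_hub_variable(self, rng):
        # A correlated ~0.95 with both B and C, B-C weakly correlated:
        # A has the larger mean absolute correlation and must go
        n = 2000
        a = rng.standard_normal(n)
        b = 0.95 * a + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
        c = 0.95 * a - 0.93 * b * 0 + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
        env = pd.DataFrame({"A": a, "B": b, "C": c})
        r = env.corr()
        assert r.loc["A", "B"] > 0.9 and r.loc["A", "C"] > 0.9
        assert abs(r.loc["B", "C"]) < 0.95
        pruned, log = collinearity_prune(env)
        assert "A" not in pruned.columns
        assert set(pruned.columns) == {"B", "C"}

    def test_below_threshold_unchanged(self, rng):
        env = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("WXYZ"))
        pruned, log = collinearity_prune(env)
        assert list(pruned.columns) == list("WXYZ") and not log

    def test_constant_removed_with_warning(self, rng):
        env = pd.DataFrame({"K": np.ones(20), "X": rng.standard_normal(20),
                            "Y": rng.standard_normal(20)})
        with pytest.warns(UserWarning, match="constant"):
            pruned, _ = collinearity_prune(env)
        assert "K" not in pruned.columns


class TestPCA:
    def test_points_on_line_pc1_100pct(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([2 * t, -3 * t])
        pca = pca_unstandardized(X)
        assert pca.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_trace_conservation(self, rng):
        X = rng.standard_normal((20, 5))
        pca = pca_unstandardized(X)
        total_var = np.var(X, axis=0, ddof=1).sum()
        assert pca.eigenvalues_.sum() == pytest.approx(total_var)

    def test_matches_svd_oracle(self, rng):
        X = rng.standard_normal((6, 4))
        pca = pca_unstandardized(X)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        assert np.allclose(np.sort(pca.eigenvalues_),
                           np.sort(s**2 / 5), atol=1e-10)
        # scores match up to the deterministic sign rule
        ref = U * s
        for j in range(4):
            assert (np.allclose(pca.scores_[:, j], ref[:, j], atol=1e-10)
                    or np.allclose(pca.scores_[:, j], -ref[:, j], atol=1e-10))

    def test_sign_convention_reorder_invariant(self, rng):
        X = rng.standard_normal((15, 4))
        perm = rng.permutation(15)
        a = pca_unstandardized(X).scores_
        b = pca_unstandardized(X[perm]).scores_
        assert np.allclose(a[perm], b, atol=1e-8)

    def test_sklearn_cross_check(self, rng):
        from sklearn.decomposition import PCA

        X = rng.standard_normal((12, 5))
        ours = pca_unstandardized(X)
        ref = PCA().fit(X)
        assert np.allclose(ours.eigenvalues_, ref.explained_variance_, atol=1e-10)


class TestRDA:
    def test_exact_linear_r2_one(self, rng):
        X = rng.standard_normal((20, 3))
        Y = X @ rng.standard_normal((3, 4))
        assert rda_adjusted_r2(Y, X).r2_ == pytest.approx(1.0)

    def test_ezekiel_arithmetic(self, rng):
        # construct R2 = 0.5 exactly: fitted and residual of equal norm
        # then check 1 - 0.5*(19/16) = 0.40625 at n=20, p=3
        n, p = 20, 3
        X = rng.standard_normal((n, p))
        Xc = X - X.mean(axis=0)
        Q, _ = np.linalg.qr(Xc)
        u = Q[:, 0]
        r = rng.standard_normal(n)
        r -= r.mean()
        r -= Q @ (Q.T @ r)
        y = u / np.linalg.norm(u) + r / np.linalg.norm(r)
        fit = rda_adjusted_r2(y, X)
        assert fit.r2_ == pytest.approx(0.5, abs=1e-10)
        assert fit.adjusted_r2_ == pytest.approx(0.40625, abs=1e-10)

    def test_adjusted_r2_unbiased_under_null(self, rng):
        vals = [rda_adjusted_r2(rng.standard_normal((30, 1)),
                                rng.standard_normal((30, 5))).adjusted_r2_
                for _ in range(500)]
        assert abs(np.mean(vals)) < 0.02

    def test_aliased_columns_dropped(self, rng):
        X = rng.standard_normal((15, 2))
        X3 = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.warns(UserWarning, match="aliased"):
            fit = rda_adjusted_r2(rng.standard_normal((15, 2)), X3)
        assert fit.p_ == 2


class TestPermutationTest:
    def test_minimum_p(self, rng):
        X = rng.standard_normal((15, 1))
        Y = X * 2.0
        fit = rda_adjusted_r2(Y, X)
        assert permutation_test(fit, 999, seed=0) == pytest.approx(0.001)

    def test_null_uniformity(self, rng):
        from scipy import stats

        ps = []
        for _ in range(200):
            fit = rda_adjusted_r2(rng.standard_normal((12, 1)),
                                  rng.standard_normal((12, 1)))
            ps.append(permutation_test(fit, 99, seed=rng.integers(2**31 - 1)))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_predictor_order_invariance(self, rng):
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 2))
        p1 = permutation_test(rda_adjusted_r2(Y, X), 99, seed=5)
        p2 = permutation_test(rda_adjusted_r2(Y, X[:, ::-1]), 99, seed=5)
        assert p1 == p2


class TestForwardSelect:
    def test_single_perfect_candidate(self, rng):
        x = rng.standard_normal(20)
        sel = forward_select(x.copy(), pd.DataFrame({"v": x}), n_permutations=999,
                             seed=0)
        assert list(sel["variable"]) == ["v"]
        assert sel["p"].iloc[0] == pytest.approx(0.001)

    def test_recovery_of_true_driver(self, rng):
        hits = 0
        for _ in range(100):
            cand = pd.DataFrame(rng.standard_normal((60, 6)),
                                columns=[f"v{i}" for i in range(6)])
            y = cand["v3"].to_numpy() + 0.5 * rng.standard_normal(60)
            sel = forward_select(y, cand, n_permutations=99,
                                 seed=int(rng.integers(2**31 - 1)))
            if len(sel) and sel["variable"].iloc[0] == "v3":
                hits += 1
        assert hits >= 95

    def test_null_selection_rate(self, rng):
        total = 0
        for _ in range(40):
            cand = pd.DataFrame(rng.standard_normal((30, 5)),
                                columns=[f"v{i}" for i in range(5)])
            y = rng.standard_normal(30)
            total += len(forward_select(y, cand, n_permutations=99,
                                        seed=int(rng.integers(2**31 - 1))))
        # expected false selections <= alpha * candidates per replicate
        assert total <= 0.05 * 5 * 40 * 2  # 2x slack on the binomial mean

    def test_alpha_one_no_cap_selects_all(self, rng):
        cand = pd.DataFrame(rng.standard_normal((25, 4)),
                            columns=list("abcd"))
        y = rng.standard_normal(25)
        sel = forward_select(y, cand, alpha=1.0, n_permutations=9, seed=0,
                             r2_cap=False)
        assert set(sel["variable"]) == set("abcd")
        # decreasing marginal contribution
        gains = np.diff(np.concatenate([[0], sel["cumulative_r2"]]))
        assert np.all(np.diff(gains) <= 1e-9)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_stepup_hand_case(self):
        assert np.allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 20)
        assert np.all(fdr_bh(p) >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestVariancePartition:
    def test_empty_x2(self, rng):
        Y = rng.standard_normal((20, 3))
        X1 = rng.standard_normal((20, 2))
        part = variance_partition(Y, X1, np.empty((20, 0)), n_permutations=9)
        assert part.pure_x1 == pytest.approx(part.adj_x1)
        assert part.shared == 0.0

    def test_algebraic_identity(self, rng):
        for _ in range(5):
            Y = rng.standard_normal((25, 4))
            X1 = rng.standard_normal((25, 3))
            X2 = rng.standard_normal((25, 2))
            part = variance_partition(Y, X1, X2, n_permutations=9, seed=0)
            assert part.pure_x1 + part.pure_x2 + part.shared == pytest.approx(
                part.adj_combined, abs=1e-12)
            assert part.unexplained == pytest.approx(1 - part.adj_combined)

    def test_orthogonal_predictors_shared_near_zero(self, rng):
        # n large enough that the Ezekiel-adjustment bias of the shared
        # fraction (exact algebra: adj1 + adj2 - adj12 != 0 even under
        # orthogonality) is within the band
        shared_vals = []
        for _ in range(30):
            A = rng.standard_normal((100, 2))
            B = rng.standard_normal((100, 2))
            B -= A @ np.linalg.lstsq(A, B, rcond=None)[0]  # orthogonalize
            Y = (A.sum(axis=1) + B.sum(axis=1) + rng.standard_normal(100))[:, None]
            part = variance_partition(Y, A, B, n_permutations=9, seed=0)
            shared_vals.append(part.shared)
        assert abs(np.mean(shared_vals)) < 0.03

    def test_shared_column_warning(self, rng):
        X = rng.standard_normal((15, 2))
        with pytest.warns(UserWarning, match="identical"):
            variance_partition(rng.standard_normal((15, 2)), X, X[:, :1],
                               n_permutations=9, seed=0)
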