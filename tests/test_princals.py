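"""Optimal-scaling PCA: ALS fit, monotone regression, quantification rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st_

from stresstypo.princals import (
    PrincalsError,
    classify_loadings,
    cronbach_alpha,
    cronbach_alpha_from_eigenvalue,
    fit_princals,
    monotone_regression,
    quantify_nominal,
    update_object_scores,
)

# ---------------------------------------------------------------------------
# weighted monotone regression


def brute_force_monotone(y, w):
    """Exhaustive search over all consecutive level-set partitions."""
    y, w = np.asarray(y, float), np.asarray(w, float)
    n = len(y)
    best, best_sse = None, np.inf
    for split_mask in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, s in enumerate(split_mask) if s] + [n]
        fit = np.empty(n)
        means = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            mu = np.average(y[a:b], weights=w[a:b])
            means.append(mu)
            fit[a:b] = mu
        if np.all(np.diff(means) >= -1e-12):
            sse = float(w @ (y - fit) ** 2)
            if sse < best_sse - 1e-12:
                best, best_sse = fit, sse
    return best, best_sse


class TestMonotoneRegression:
    def test_violation_pools_to_mean(self):
        np.testing.assert_allclose(monotone_regression([3, 1, 2]), [2, 2, 2])

    def test_already_monotone_unchanged(self):
        np.testing.assert_allclose(monotone_regression([1, 2, 3], [5, 1, 2]), [1, 2, 3])

    def test_weighted_pooled_mean(self):
        np.testing.assert_allclose(monotone_regression([2, 0], [2, 1]), [4 / 3, 4 / 3])

    def test_matches_exhaustive_search(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 7))
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 5.0, size=n)
            fit = monotone_regression(y, w)
            oracle, oracle_sse = brute_force_monotone(y, w)
            np.testing.assert_allclose(fit, oracle, atol=1e-9)
            assert float(w @ (y - fit) ** 2) <= oracle_sse + 1e-9

    @given(st_.lists(st_.floats(-50, 50), min_size=1, max_size=12))
    def test_output_is_nondecreasing_and_idempotent(self, y):
        fit = monotone_regression(y)
        assert np.all(np.diff(fit) >= -1e-12)
        np.testing.assert_allclose(monotone_regression(fit), fit, atol=1e-12)

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            monotone_regression([1, 2], [1, 0])


# ---------------------------------------------------------------------------
# Cronbach alpha


class TestCronbachAlpha:
    @pytest.mark.parametrize(
        "m, vaf, expected",
        [(4, 0.842, 0.937), (9, 0.701, 0.947)],
    )
    def test_reproduces_published_alphas_from_vaf(self, m, vaf, expected):
        assert round(cronbach_alpha_from_eigenvalue(m * vaf, m), 3) == expected

    def test_unit_eigenvalue_gives_zero(self):
        assert cronbach_alpha_from_eigenvalue(1.0, 5) == 0.0

    @pytest.mark.parametrize("lam, m", [(0.0, 4), (-1.0, 4), (2.0, 1)])
    def test_domain_errors(self, lam, m):
        with pytest.raises(ValueError):
            cronbach_alpha_from_eigenvalue(lam, m)

    def test_classical_alpha_on_parallel_items(self, rng):
        latent = rng.normal(size=4000)
        items = np.column_stack([latent + rng.normal(size=4000) for _ in range(3)])
        # parallel items, loading 1, noise 1: alpha = 3*0.5/(1+2*0.5)
        assert cronbach_alpha(items) == pytest.approx(0.75, abs=0.03)


class TestClassifyLoadings:
    def test_threshold_rule(self):
        a = pd.DataFrame({"dim1": [0.975, 0.102, 0.4, -0.41, 0.39]})
        flags = classify_loadings(a)
        assert flags["dim1"].tolist() == [True, False, True, True, False]

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            classify_loadings(pd.DataFrame({"d": [0.5]}), threshold=1.5)


# ---------------------------------------------------------------------------
# ALS building blocks


class TestQuantifyNominal:
    def test_centroids_by_hand(self):
        codes = np.array([0, 0, 1, 1])
        X = np.array([1.0, 3.0, -1.0, -3.0])
        np.testing.assert_allclose(quantify_nominal(codes, X, 2).ravel(), [2.0, -2.0])

    def test_single_category_is_overall_mean(self, rng):
        X = rng.normal(size=10)
        X -= X.mean()
        cent = quantify_nominal(np.zeros(10, dtype=int), X, 1)
        assert abs(cent[0, 0]) < 1e-12

    def test_empty_category_errors(self):
        with pytest.raises(PrincalsError, match="empty category"):
            quantify_nominal(np.array([0, 0]), np.array([1.0, -1.0]), 2)


class TestUpdateObjectScores:
    def test_constraints_hold(self, rng):
        T = rng.normal(size=(40, 5))
        T -= T.mean(axis=0)
        A = rng.normal(size=(5, 2))
        X = update_object_scores(T, A)
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(X.T @ X / 40, np.eye(2), atol=1e-10)

    def test_p1_closed_form_is_scaled_row_mean(self, rng):
        T = rng.normal(size=(30, 4))
        T -= T.mean(axis=0)
        a = np.ones((4, 1))
        X = update_object_scores(T, a)
        target = T.sum(axis=1)
        target = (target - target.mean()) / np.linalg.norm(target - target.mean())
        np.testing.assert_allclose(np.abs(X.ravel()), np.abs(np.sqrt(30) * target), atol=1e-9)

    def test_rank_deficiency_detected(self):
        T = np.outer(np.arange(10.0) - 4.5, [1, 1, 1])
        with pytest.raises(PrincalsError, match="dimensions"):
            update_object_scores(T, np.ones((3, 2)))


# ---------------------------------------------------------------------------
# full fits


def classical_pca(df, p):
    Z = (df - df.mean()) / df.std(ddof=0)
    R = np.corrcoef(Z.to_numpy().T)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    return V[:, :p] * np.sqrt(w[:p]), w[:p]


class TestFitPrincals:
    def test_numeric_data_reproduces_classical_pca(self, rng):
        df = pd.DataFrame(
            rng.standard_normal((50, 3)) @ rng.standard_normal((3, 3)),
            columns=list("abc"),
        )
        res = fit_princals(df, p=2, levels={c: "numeric" for c in df.columns})
        A_pca, lam_pca = classical_pca(df, 2)
        np.testing.assert_allclose(
            np.abs(res.loadings.to_numpy()), np.abs(A_pca), atol=1e-6
        )
        np.testing.assert_allclose(res.eigenvalues, lam_pca, atol=1e-6)
        np.testing.assert_allclose(res.vaf_total, 100 * lam_pca.sum() / 3, atol=1e-6)

    def test_single_numeric_variable_identity(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30)})
        res = fit_princals(df, p=1, levels={"x": "numeric"})
        assert abs(abs(res.loadings.iloc[0, 0]) - 1) < 1e-10
        assert res.vaf_total == pytest.approx(100.0)

    def test_reversed_ordinal_order_is_symmetric(self, rng):
        codes = rng.integers(0, 4, 120)
        df = pd.DataFrame(
            {
                "o": pd.Categorical.from_codes(codes, categories=list("abcd")),
                "x": codes + rng.normal(0, 0.5, 120),
            }
        )
        levels = {"o": "ordinal", "x": "numeric"}
        res = fit_princals(df, p=1, levels=levels)
        df_rev = df.copy()
        df_rev["o"] = pd.Categorical(df["o"], categories=list("dcba"))
        res_rev = fit_princals(df_rev, p=1, levels=levels)
        assert res.vaf_total == pytest.approx(res_rev.vaf_total, abs=1e-6)
        q = res.quantifications["o"].quantifications
        q_rev = res_rev.quantifications["o"].quantifications
        np.testing.assert_allclose(q, -q_rev[::-1], atol=1e-6)

    def test_balanced_binary_quantifies_to_unit_values(self, rng):
        half = 60
        latent = np.concatenate([-np.ones(half), np.ones(half)])
        df = pd.DataFrame(
            {
                "b": np.where(latent > 0, "yes", "no"),
                "x": latent + rng.normal(0, 0.3, 2 * half),
            }
        )
        res = fit_princals(df, p=1, levels={"b": "nominal", "x": "numeric"})
        np.testing.assert_allclose(
            np.sort(res.quantifications["b"].quantifications), [-1.0, 1.0], atol=1e-8
        )

    def test_loss_trace_nonincreasing_and_invariants(self, rng):
        df = pd.DataFrame(
            {
                "o1": pd.Categorical.from_codes(
                    rng.integers(0, 5, 200), categories=list("abcde")
                ),
                "n1": rng.normal(size=200),
                "nom": pd.Categorical.from_codes(
                    rng.integers(0, 3, 200), categories=list("xyz")
                ),
            }
        )
        res = fit_princals(
            df, p=2, levels={"o1": "ordinal", "n1": "numeric", "nom": "nominal"}
        )
        assert np.all(np.diff(res.loss_trace) <= 1e-10)
        # lambda_d equals the d-th eigenvalue of the transformed correlation matrix
        T = res.transformed_frame().to_numpy()
        w = np.sort(np.linalg.eigvalsh(T.T @ T / len(T)))[::-1]
        np.testing.assert_allclose(res.eigenvalues, w[:2], atol=1e-8)
        # eigenvalue identity with loadings
        np.testing.assert_allclose(
            res.eigenvalues, (res.loadings.to_numpy() ** 2).sum(axis=0), atol=1e-8
        )
        assert np.all(np.abs(res.loadings.to_numpy()) <= 1 + 1e-10)
        # ordinal quantifications nondecreasing in declared order
        q = res.quantifications["o1"].quantifications
        assert np.all(np.diff(q) >= -1e-10)
        # object scores orthonormal
        X = res.scores.to_numpy()
        np.testing.assert_allclose(X.T @ X / len(X), np.eye(2), atol=1e-8)

    def test_two_rank_correlated_ordinals_share_one_dimension(self, rng):
        base = rng.integers(0, 5, 300)
        df = pd.DataFrame(
            {
                "o1": pd.Categorical.from_codes(base, categories=list("abcde")),
                "o2": pd.Categorical.from_codes(
                    np.minimum(base, 3), categories=list("wxyz")
                ),
            }
        )
        res = fit_princals(df, p=1, levels={"o1": "ordinal", "o2": "ordinal"})
        assert np.all(res.loadings.to_numpy() >= 0.999)
        assert res.vaf_total >= 99.9

    def test_degenerate_variable_named(self):
        df = pd.DataFrame({"flat": [1.0] * 20, "x": np.arange(20.0)})
        with pytest.raises(PrincalsError, match="flat"):
            fit_princals(df, p=1, levels={"flat": "numeric", "x": "numeric"})

    def test_p_out_of_range(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20)})
        with pytest.raises(PrincalsError):
            fit_princals(df, p=2, levels={"x": "numeric"})
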