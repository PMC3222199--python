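"""k-means with random starts, CH selection, outlier screening, full pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stresstypo.clustering import (
    ClusteringError,
    TypologyConfig,
    calinski_harabasz,
    ch_scan,
    detect_outliers,
    deviances,
    kmeans_random_starts,
    run_typology_pipeline,
)


def brute_force_kmeans(Z, k):
    """Exhaustive minimum within-deviance partition (small N only)."""
    n = len(Z)
    best_W, best_labels = np.inf, None
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        if len(np.unique(labels)) != k:
            continue
        W = 0.0
        for c in range(k):
            sub = Z[labels == c]
            W += ((sub - sub.mean(axis=0)) ** 2).sum()
        if W < best_W - 1e-12:
            best_W, best_labels = W, labels
    return best_labels, best_W


class TestKMeans:
    def test_two_triads_match_exhaustive_optimum(self, rng):
        Z = np.vstack(
            [rng.normal(0, 0.1, (3, 2)), rng.normal(5, 0.1, (3, 2))]
        )
        sol = kmeans_random_starts(Z, 2, n_starts=20, seed=0)
        _, W_opt = brute_force_kmeans(Z, 2)
        assert sol.within_deviance == pytest.approx(W_opt, abs=1e-9)

    def test_matches_exhaustive_on_random_instances(self, rng):
        hits = 0
        for _ in range(50):
            Z = rng.normal(size=(8, 2))
            sol = kmeans_random_starts(Z, 2, n_starts=100, seed=int(rng.integers(1 << 30)))
            _, W_opt = brute_force_kmeans(Z, 2)
            hits += abs(sol.within_deviance - W_opt) < 1e-9
        assert hits == 50

    def test_k_equals_n_is_degenerate(self, rng):
        Z = rng.normal(size=(6, 2))
        sol = kmeans_random_starts(Z, 6, n_starts=5, seed=1)
        assert sol.within_deviance == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(sol.assignments)) == 6

    def test_row_permutation_gives_same_partition(self, rng):
        Z = np.vstack([rng.normal(i * 4, 1, (20, 3)) for i in range(3)])
        sol = kmeans_random_starts(Z, 3, n_starts=100, seed=3)
        perm = rng.permutation(len(Z))
        sol_p = kmeans_random_starts(Z[perm], 3, n_starts=100, seed=4)
        assert adjusted_rand_score(sol.assignments[perm], sol_p.assignments) == 1.0

    def test_best_deviance_nonincreasing_in_nested_restarts(self, rng):
        Z = rng.normal(size=(60, 4))
        prev = np.inf
        for n_starts in (1, 5, 20, 50):
            sol = kmeans_random_starts(Z, 5, n_starts=n_starts, seed=7)
            assert sol.within_deviance <= prev + 1e-12
            prev = sol.within_deviance

    def test_within_deviance_matches_recomputation(self, rng):
        Z = rng.normal(size=(40, 3))
        sol = kmeans_random_starts(Z, 4, n_starts=10, seed=5)
        assert sol.within_deviance == pytest.approx(sol.recompute_within(Z), abs=1e-10)

    def test_no_empty_clusters(self, rng):
        Z = rng.normal(size=(30, 2))
        sol = kmeans_random_starts(Z, 10, n_starts=20, seed=6)
        assert np.bincount(sol.assignments, minlength=10).min() >= 1

    def test_too_many_clusters_for_distinct_rows(self):
        Z = np.array([[0.0, 0.0]] * 5 + [[1.0, 1.0]] * 5)
        with pytest.raises(ClusteringError, match="distinct"):
            kmeans_random_starts(Z, 3, n_starts=5, seed=0)


class TestCalinskiHarabasz:
    def test_hand_computed_1d_fixture(self):
        # two triads {0,1,2} and {10,11,12}: W=4, B=150, N=6, k=2
        Z = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        B, W = deviances(Z, labels)
        assert (B, W) == (150.0, 4.0)
        assert calinski_harabasz(Z, labels) == pytest.approx((150 / 2) / (4 / 4))
        assert calinski_harabasz(Z, labels, df_convention="classic") == pytest.approx(
            (150 / 1) / (4 / 4)
        )

    def test_duplication_scales_deviances(self, rng):
        Z = rng.normal(size=(20, 2))
        labels = rng.integers(0, 2, 20)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        B, W = deviances(Z, labels)
        B2, W2 = deviances(np.vstack([Z, Z]), np.concatenate([labels, labels]))
        assert (B2, W2) == pytest.approx((2 * B, 2 * W))
        ch2 = calinski_harabasz(np.vstack([Z, Z]), np.concatenate([labels, labels]))
        # CH changes only through the df: (2B/k)/(2W/(2N-k))
        assert ch2 == pytest.approx((2 * B / 2) / (2 * W / (40 - 2)))

    def test_orthogonal_rotation_invariance(self, rng):
        Z = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, 30)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = calinski_harabasz(Z, labels)
        b = calinski_harabasz(Z @ Q, labels)
        assert a == pytest.approx(b, abs=1e-8)

    def test_independent_recomputation(self, rng):
        Z = rng.normal(size=(50, 4))
        labels = rng.integers(0, 4, 50)
        ch = calinski_harabasz(Z, labels)
        # direct double-loop recomputation
        grand = Z.mean(axis=0)
        B = W = 0.0
        for c in np.unique(labels):
            sub = Z[labels == c]
            B += len(sub) * ((sub.mean(axis=0) - grand) ** 2).sum()
            for row in sub:
                W += ((row - sub.mean(axis=0)) ** 2).sum()
        k, N = len(np.unique(labels)), len(Z)
        assert ch == pytest.approx((B / k) / (W / (N - k)), abs=1e-10)

    def test_zero_within_warns_infinite(self):
        Z = np.array([[0.0], [0.0], [5.0], [5.0]])
        with pytest.warns(RuntimeWarning):
            assert np.isinf(calinski_harabasz(Z, np.array([0, 0, 1, 1])))

    def test_single_cluster_errors(self, rng):
        Z = rng.normal(size=(10, 2))
        with pytest.raises(ClusteringError):
            calinski_harabasz(Z, np.zeros(10, dtype=int))


class TestChScan:
    def test_three_separated_clusters_selected(self, rng):
        centers = rng.standard_normal((3, 4)) * 10
        Z = np.vstack([c + rng.standard_normal((100, 4)) for c in centers])
        prof = ch_scan(Z, k_range=range(2, 9), n_starts=10, seed=0)
        assert prof.argmax_k == 3

    def test_profile_bookkeeping(self, rng):
        Z = rng.normal(size=(60, 2))
        prof = ch_scan(Z, k_range=range(2, 16), n_starts=3, seed=1)
        assert len(prof.entries) == 14
        assert set(prof.entries) == set(range(2, 16))

    def test_two_cluster_data_prefers_small_k(self, rng):
        Z = np.vstack(
            [rng.normal(0, 1, (80, 3)), rng.normal(8, 1, (80, 3))]
        )
        prof = ch_scan(Z, k_range=range(2, 7), n_starts=10, seed=2)
        assert prof.entries[2] > prof.entries[6]

    def test_tie_break_prefers_larger_k_by_default(self, rng):
        Z = np.vstack([rng.normal(i * 10, 1, (50, 2)) for i in range(3)])
        prof = ch_scan(Z, k_range=range(2, 6), n_starts=10, seed=3, tie_tol=0.9999)
        # with an absurdly wide tie window everything ties: pick the largest k
        assert prof.argmax_k == 5
        prof_small = ch_scan(
            Z, k_range=range(2, 6), n_starts=10, seed=3, tie_tol=0.9999, prefer_larger_k=False
        )
        assert prof_small.argmax_k == 2


class TestDetectOutliers:
    def test_planted_five_plus_one(self, rng):
        N = 200
        Z = rng.normal(size=(N, 6))
        Z[:5, 3] += 9.0  # tight group: extreme on two variables
        Z[:5, 4] += 12.0
        Z[5, 5] += 20.0  # isolated extreme absentee
        df = pd.DataFrame(Z)
        df = (df - df.mean()) / df.std()
        rep = detect_outliers(df, k_range=range(2, 12), max_cluster_size=6, n_starts=10, seed=0)
        assert set(rep.outlier_row_ids) == set(range(6))
        assert len(rep.groups) == 2
        sizes = sorted(len(g.members) for g in rep.groups)
        assert sizes == [1, 5]

    def test_homogeneous_cohort_mostly_clean(self, rng):
        flagged = 0
        for s in range(10):
            Z = pd.DataFrame(rng.normal(size=(150, 4)))
            rep = detect_outliers(Z, k_range=range(2, 8), n_starts=5, seed=s)
            flagged += bool(rep)
        assert flagged <= 2

    def test_unsatisfiable_stability_gives_empty_report(self, rng):
        Z = pd.DataFrame(rng.normal(size=(50, 3)))
        rep = detect_outliers(Z, k_range=range(2, 5), min_stability=10, n_starts=5, seed=0)
        assert not rep.outlier_row_ids


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    centers = np.array(
        [
            [4, 0, 0, 0, 0, 0],
            [0, 4, 0, 0, 0, 0],
            [0, 0, 4, 0, 0, 0],
            [-4, -4, 0, 0, 0, 0],
        ],
        dtype=float,
    )
    labels = rng.integers(0, 4, 400)
    Z = centers[labels] + rng.standard_normal((400, 6))
    return pd.DataFrame(Z), labels


class TestTypologyPipeline:
    def test_recovers_planted_partition(self, planted):
        df, labels = planted
        cfg = TypologyConfig(k_range=(2, 8), n_starts=20, outlier_n_starts=10, seed=0)
        res = run_typology_pipeline(df, cfg)
        assert res.ch_profile.argmax_k == 4
        got = res.assignments_series()
        ari = adjusted_rand_score(labels[got.index], got.to_numpy())
        assert ari >= 0.8

    def test_deterministic_given_seed(self, planted):
        df, _ = planted
        cfg = TypologyConfig(k_range=(2, 6), n_starts=5, outlier_n_starts=5, seed=42)
        a = run_typology_pipeline(df, cfg)
        b = run_typology_pipeline(df, cfg)
        assert np.array_equal(a.solution.assignments, b.solution.assignments)
        assert a.ch_profile.entries == b.ch_profile.entries
        assert a.outliers.outlier_row_ids == b.outliers.outlier_row_ids

    def test_shares_and_sizes_consistent(self, planted):
        df, _ = planted
        cfg = TypologyConfig(k_range=(2, 6), n_starts=10, outlier_n_starts=5, seed=1)
        res = run_typology_pipeline(df, cfg)
        total = sum(t.size for t in res.typologies)
        assert total == len(res.classification)
        assert sum(t.share_pct for t in res.typologies) == pytest.approx(100.0, abs=0.2)
        # printed-count arithmetic of a 194-member cluster among 677
        assert round(100 * 194 / 677, 1) == 28.7

    def test_restandardized_columns(self, planted):
        df, _ = planted
        cfg = TypologyConfig(k_range=(2, 6), n_starts=5, outlier_n_starts=5, seed=2)
        res = run_typology_pipeline(df, cfg)
        Z = res.classification
        np.testing.assert_allclose(Z.mean().to_numpy(), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std().to_numpy(), 1, atol=1e-10)
        # removal + restandardization preserves within-column rank order
        kept = df.loc[Z.index]
        for col in df.columns:
            assert (
                kept[col].rank().to_numpy() == Z[col].rank().to_numpy()
            ).all()
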