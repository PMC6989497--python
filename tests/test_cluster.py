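"""Clustering, model-order selection, alignment and confusion summaries."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ppixmargin import (
    accuracy,
    align_clusters,
    bic_curve,
    confusion_summary,
    gap_statistic,
    gmm_fit,
    kmeans_fit,
    repeated_runs,
)
from ppixmargin.cluster import ClusterCountSelector


@pytest.fixture(scope="module")
def two_blobs():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(20, 1, (25, 3))])
    labels = np.repeat([0, 1], 25)
    return X, labels


@pytest.fixture(scope="module")
def four_blobs():
    rng = np.random.default_rng(1)
    centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], float)
    X = np.vstack([c + rng.normal(0, 1, (13, 3)) for c in centers])
    labels = np.repeat(np.arange(4), 13)
    return X, labels


class TestKMeans:
    def test_k1_dispersion_is_total_ss(self):
        rng = np.random.default_rng(0)
        X = rng.random((15, 4))
        run = kmeans_fit(X, 1, seed=0)
        assert run.inertia == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_square_corners_match_exhaustive_two_partition(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        run = kmeans_fit(X, 2, seed=0)

        def w(part):
            total = 0.0
            for side in (part, [i for i in range(4) if i not in part]):
                pts = X[list(side)]
                total += ((pts - pts.mean(0)) ** 2).sum()
            return total

        best = min(
            w(list(c)) for r in range(1, 4) for c in itertools.combinations(range(4), r)
        )
        assert run.inertia == pytest.approx(best)
        assert {tuple(sorted(np.where(run.labels == c)[0])) for c in (0, 1)} == {
            (0, 1), (2, 3)
        }

    def test_k_equals_n_gives_zero_dispersion(self):
        X = np.random.default_rng(1).random((6, 2))
        assert kmeans_fit(X, 6, seed=0).inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.ones((3, 2)), 4)

    def test_dispersion_nonincreasing_in_k(self):
        X = np.random.default_rng(2).random((20, 3))
        w = [kmeans_fit(X, k, seed=0, n_restarts=10).inertia for k in range(1, 21)]
        assert all(a >= b - 1e-9 for a, b in zip(w, w[1:]))
        assert w[-1] == pytest.approx(0.0, abs=1e-12)


class TestGMM:
    def test_separated_blobs_recover_generator_labels(self, two_blobs):
        X, labels = two_blobs
        run = gmm_fit(X, 2, seed=0)
        agree = max((run.labels == labels).mean(), (run.labels != labels).mean())
        assert agree == 1.0

    def test_k1_loglik_matches_closed_form(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 2))
        run = gmm_fit(X, 1, seed=0)
        mu = X.mean(0)
        cov = np.cov(X.T, bias=True) + 1e-6 * np.eye(2)
        oracle = multivariate_normal(mu, cov).logpdf(X).sum()
        assert run.loglik == pytest.approx(oracle, rel=1e-6)

    def test_duplicate_rows_get_identical_assignments(self, two_blobs):
        X, _ = two_blobs
        X = np.vstack([X, X[3]])
        run = gmm_fit(X, 2, seed=0)
        assert run.labels[3] == run.labels[-1]


class TestBIC:
    def test_single_blob_selects_one(self):
        X = np.random.default_rng(0).normal(0, 1, (30, 3))
        assert bic_curve(X, range(1, 7), seed=0).k_star_bic == 1

    def test_two_far_blobs_select_two(self, two_blobs):
        X, _ = two_blobs
        assert bic_curve(X, range(1, 7), seed=0).k_star_bic == 2

    def test_four_blobs_select_four(self, four_blobs):
        X, _ = four_blobs
        assert bic_curve(X, range(1, 9), seed=0).k_star_bic == 4

    def test_gmm_bic_two_blobs(self):
        # 2-D keeps the full-covariance parameter count modest at this n
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(12, 1, (25, 2))])
        res = bic_curve(X, range(1, 6), method="gmm", seed=0)
        assert res.k_star_bic == 2
        assert res.bic[0] - res.bic[1] > 50  # one component decisively rejected

    def test_planted_k_recovered_on_default_cohort(self):
        """GMM BIC on the PCA 3-D reduction of the default synthetic cohort
        recovers the four histological classes in most repetitions."""
        from ppixmargin import DatasetSpec, build_feature_matrix, pca_fit, simulate_dataset

        hits = 0
        for seed in range(5):
            fm = build_feature_matrix(simulate_dataset(DatasetSpec(seed=seed)))
            P = pca_fit(fm.values, n_components=3).scores
            hits += bic_curve(P, range(1, 9), method="gmm", seed=seed).k_star_bic == 4
        assert hits >= 4


class TestGapStatistic:
    def test_two_far_blobs(self, two_blobs):
        X, _ = two_blobs
        res = gap_statistic(X, range(1, 7), B=50, seed=0)
        assert res.k_star_gap == 2

    def test_four_blobs(self, four_blobs):
        X, _ = four_blobs
        assert gap_statistic(X, range(1, 9), B=50, seed=0).k_star_gap == 4

    def test_uniform_data_not_significantly_clustered(self):
        X = np.random.default_rng(5).random((40, 3))
        res = gap_statistic(X, range(1, 7), B=50, seed=0, rule="tibshirani")
        assert res.k_star_gap == 1

    def test_reference_dispersion_positive(self, two_blobs):
        X, _ = two_blobs
        res = gap_statistic(X, range(1, 5), B=12, seed=1)
        assert np.all(res.s_k >= 0)

    def test_small_B_rejected(self, two_blobs):
        X, _ = two_blobs
        with pytest.raises(ValueError):
            gap_statistic(X, range(1, 4), B=5)

    def test_constant_feature_tolerated(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([rng.random(30), np.full(30, 2.0)])
        res = gap_statistic(X, range(1, 4), B=12, seed=0)
        assert np.all(np.isfinite(res.gap))


class TestRepeatedRuns:
    def test_run_count_and_seeds(self):
        X = np.random.default_rng(0).random((12, 3))
        runs = repeated_runs(X, 3, n_runs=20, base_seed=5)
        assert len(runs) == 20
        assert [r.seed for r in runs] == list(range(5, 25))

    def test_reexecution_identical(self):
        X = np.random.default_rng(1).random((12, 3))
        a = repeated_runs(X, 3, n_runs=4, base_seed=9)
        b = repeated_runs(X, 3, n_runs=4, base_seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.labels, rb.labels)

    def test_single_run_summary_has_zero_sigma(self, two_blobs):
        X, labels = two_blobs
        runs = repeated_runs(X, 2, n_runs=1, base_seed=0)
        summary = confusion_summary(runs, labels, classes=("core", "healthy"))
        np.testing.assert_array_equal(summary.sigma, 0.0)


class TestAlignClusters:
    def test_pure_relabeling_reaches_full_agreement(self):
        true = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        pred = np.array([2, 2, 3, 3, 0, 0, 1, 1])
        aligned = align_clusters(pred, true)
        assert (aligned == true).all()

    def test_matches_brute_force_permutation_search(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            true = rng.integers(0, 4, 8)
            pred = rng.integers(0, 4, 8)
            aligned = align_clusters(pred, true, n_classes=4)
            best = max(
                sum(perm[p] == t for p, t in zip(pred, true))
                for perm in itertools.permutations(range(4))
            )
            assert (aligned == true).sum() == best

    def test_single_cluster_maps_to_largest_class(self):
        true = np.array([0, 0, 0, 1, 1, 2])
        pred = np.zeros(6, dtype=int)
        aligned = align_clusters(pred, true, n_classes=3)
        assert set(aligned) == {0}

    def test_invariant_to_cluster_index_permutation(self):
        rng = np.random.default_rng(1)
        true = rng.integers(0, 4, 30)
        pred = rng.integers(0, 4, 30)
        base = align_clusters(pred, true, n_classes=4)
        perm = np.array([3, 0, 2, 1])
        np.testing.assert_array_equal(align_clusters(perm[pred], true, n_classes=4), base)

    def test_more_clusters_than_classes(self):
        true = np.array([0, 0, 1, 1, 1, 1])
        pred = np.array([0, 0, 1, 1, 2, 2])
        aligned = align_clusters(pred, true, n_classes=2)
        assert (aligned == true).all()


class TestConfusionSummary:
    def _runs(self, labels_list):
        from ppixmargin.cluster import ClusterRun

        return [
            ClusterRun(method="kmeans", k=int(max(l)) + 1, seed=i,
                       labels=np.asarray(l), inertia=0.0)
            for i, l in enumerate(labels_list)
        ]

    def test_identical_runs_zero_sigma(self):
        true = ["core", "core", "healthy", "healthy"]
        runs = self._runs([[0, 0, 1, 1]] * 5)
        s = confusion_summary(runs, true, classes=("core", "healthy"))
        np.testing.assert_array_equal(s.sigma, 0.0)
        np.testing.assert_array_equal(s.mean_counts, [[2, 0], [0, 2]])

    def test_population_sigma_convention(self):
        # cell counts 8 and 6 across two runs -> mean 7, population sd 1
        true = ["core"] * 10 + ["healthy"] * 4
        run_a = [0] * 8 + [1] * 2 + [1] * 4
        run_b = [0] * 6 + [1] * 4 + [1] * 4
        s = confusion_summary(self._runs([run_a, run_b]), true,
                              classes=("core", "healthy"))
        assert s.mean_counts[0, 0] == pytest.approx(7.0)
        assert s.sigma[0, 0] == pytest.approx(1.0)

    def test_row_sums_equal_class_sizes(self, two_blobs):
        X, labels = two_blobs
        names = np.array(["core", "healthy"])[labels]
        runs = repeated_runs(X, 2, n_runs=6, base_seed=0)
        s = confusion_summary(runs, names, classes=("core", "healthy"))
        np.testing.assert_allclose(s.mean_counts.sum(axis=1), [25, 25])
        np.testing.assert_allclose(s.percent.sum(axis=1), 100.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_summary(self._runs([[0, 1]]), ["core"], classes=("core", "healthy"))


class TestAccuracy:
    def test_perfect_clustering_all_schemes(self):
        counts = np.diag([10.0, 24.0, 9.0, 7.0])
        for scheme in ("four_class", "merge_margins", "healthy_vs_rest"):
            assert accuracy(counts, scheme) == pytest.approx(1.0)

    def test_reported_matrix_four_class_value(self):
        counts = np.array([
            [8.0, 1.9, 0.0, 0.1],
            [1.3, 7.1, 9.7, 5.9],
            [0.0, 0.1, 5.6, 3.3],
            [0.0, 0.0, 1.0, 6.0],
        ])
        assert accuracy(counts, "four_class") == pytest.approx((8 + 7.1 + 5.6 + 6) / 50)

    def test_merging_never_decreases_accuracy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.random((4, 4)) * 10
            a4 = accuracy(counts, "four_class")
            assert accuracy(counts, "merge_margins") >= a4 - 1e-12
            assert accuracy(counts, "healthy_vs_rest") >= a4 - 1e-12

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.eye(4), "binary")


class TestClusterCountSelector:
    def test_two_blob_selection(self, two_blobs):
        X, _ = two_blobs
        sel = ClusterCountSelector(method="kmeans", k_min=1, k_max=5, B=20, seed=0).fit(X)
        assert sel.k_star_gap_ == 2 and sel.k_star_bic_ == 2 and sel.best_k_ == 2
        assert sel.bic_.shape == sel.gap_.shape == (5,)

    def test_sklearn_api(self):
        from sklearn.base import clone

        sel = ClusterCountSelector(method="gmm", B=15)
        assert clone(sel).get_params()["B"] == 15
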