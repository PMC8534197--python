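"""Clusterability, consensus k, WPGMA, PCA, outliers and BL/RL assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

import thyroclass as tc
from thyroclass.clustering import (
    DEFAULT_INDEX_PANEL,
    assign_negative_classes,
    bootstrapped_clusterability,
    consensus_cluster_number,
    flag_outliers,
    hopkins_statistic,
    pca_project,
    wpgma_cluster,
    wpgma_linkage,
)


def frame(X):
    """Samples-as-rows array -> genes x samples expression frame."""
    return pd.DataFrame(np.asarray(X, dtype=float).T,
                        columns=[f"s{i}" for i in range(len(X))])


class TestHopkins:
    def test_uniform_data_is_spatially_random(self):
        vals = [
            1 - hopkins_statistic(
                frame(np.random.default_rng(1000 + s).uniform(size=(200, 5))), seed=s
            )
            for s in range(100)
        ]
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_two_tight_clusters_are_clusterable(self):
        vals = []
        for s in range(100):
            rng = np.random.default_rng(2000 + s)
            X = np.vstack([rng.normal(0, 0.05, (100, 5)), rng.normal(1, 0.05, (100, 5))])
            vals.append(1 - hopkins_statistic(frame(X), seed=s))
        assert np.mean(vals) < 0.3

    def test_duplicated_points_drive_h_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        assert hopkins_statistic(frame(np.vstack([X, X])), seed=0) == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(tc.ValidationError):
            hopkins_statistic(frame(np.zeros((2, 3))))

    def test_single_rep_reduces_to_one_call(self, cohort_log_matrix):
        mean, _ = bootstrapped_clusterability(cohort_log_matrix, reps=1, seed=11)
        single = 1 - hopkins_statistic(cohort_log_matrix, seed=[11, 0])
        assert mean == pytest.approx(single)

    def test_bootstrap_deterministic_under_seed(self, cohort_log_matrix):
        a = bootstrapped_clusterability(cohort_log_matrix, reps=16, seed=5)
        b = bootstrapped_clusterability(cohort_log_matrix, reps=16, seed=5)
        assert a == b


def naive_wpgma(D):
    """O(n^3) WPGMA reference: returns [(id_a, id_b, height)] in scipy ids."""
    n = D.shape[0]
    d = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    alive = list(range(n))
    scipy_id = {i: i for i in range(n)}
    merges = []
    nid = n
    while len(alive) > 1:
        pairs = [(min(a, b), max(a, b)) for i, a in enumerate(alive) for b in alive[i + 1:]]
        key = min(pairs, key=lambda p: (d[p], p))
        a, b = key
        merges.append((min(scipy_id[a], scipy_id[b]), max(scipy_id[a], scipy_id[b]), d[key]))
        alive = [x for x in alive if x not in key]
        for c in alive:
            d[(min(nid, c), max(nid, c))] = 0.5 * (d[(min(a, c), max(a, c))] + d[(min(b, c), max(b, c))])
        scipy_id[nid] = n + len(merges) - 1
        alive.append(nid)
        nid += 1
    return merges


class TestWpgma:
    def test_three_point_hand_example(self):
        # d(A,B)=1, d(A,C)=4, d(B,C)=5: merge (A,B) at 1, then with C at (4+5)/2
        D = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        Z = wpgma_linkage(D)
        assert Z[0, :3].tolist() == [0.0, 1.0, 1.0]
        assert Z[1, 2] == pytest.approx(4.5)

    def test_matches_naive_reference_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            X = rng.normal(size=(10, 4))
            D = squareform(pdist(X))
            Z = wpgma_linkage(D)
            ref = naive_wpgma(D)
            got = {(int(min(r[0], r[1])), int(max(r[0], r[1])), round(float(r[2]), 9))
                   for r in Z}
            want = {(a, b, round(h, 9)) for a, b, h in ref}
            assert got == want

    def test_merge_heights_non_decreasing(self, cohort_log_matrix):
        Z, _ = wpgma_cluster(cohort_log_matrix, 2)
        assert (np.diff(Z[:, 2]) >= -1e-9).all()

    def test_k_equal_n_gives_singletons(self):
        m = frame(np.random.default_rng(0).normal(size=(6, 3)))
        _, labels = wpgma_cluster(m, 6)
        assert sorted(labels.values()) == [1, 2, 3, 4, 5, 6]

    def test_k_above_n_rejected(self):
        m = frame(np.zeros((3, 2)))
        with pytest.raises(tc.ValidationError):
            wpgma_cluster(m, 5)


def blobs(centers, n_per, scale=0.3, seed=0, dims=20):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, scale, size=(n_per, dims)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return frame(X), labels


class TestConsensus:
    def test_forced_vote_single_index(self):
        m, _ = blobs([0, 5], 6, seed=1)
        res = consensus_cluster_number(
            m, k_range=[2], indices={"sil": DEFAULT_INDEX_PANEL["silhouette"]},
            reps=1, seed=0,
        )
        assert res.chosen_k == 2 and res.per_k_votes == {2: 1}

    def test_votes_conservation(self, cohort_log_matrix):
        res = consensus_cluster_number(cohort_log_matrix, reps=10, seed=3)
        assert sum(res.per_k_votes.values()) == res.n_evaluations - res.n_invalid

    def test_three_separated_blobs_give_k3(self):
        m, _ = blobs([0, 6, 12], 8, seed=2)
        res = consensus_cluster_number(m, k_range=range(2, 6), reps=30, seed=2)
        assert res.chosen_k == 3

    def test_planted_two_archetype_k_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            cfg = tc.CohortConfig(seed=100 + seed)
            counts, _ = tc.generate_counts(cfg)
            expr = tc.build_expression_matrix(counts).values
            res = consensus_cluster_number(expr, k_range=range(2, 6), reps=20, seed=seed)
            hits += res.chosen_k == 2
        assert hits >= 19  # >= 95% of 20 generator seeds

    def test_invalid_k_range_rejected(self):
        m = frame(np.zeros((4, 3)))
        with pytest.raises(tc.ValidationError):
            consensus_cluster_number(m, k_range=range(2, 10), reps=1)


class TestLabelRecovery:
    def test_archetype_labels_recovered(self, cohort_log_matrix, cohort):
        _, truth = cohort
        _, labels = wpgma_cluster(cohort_log_matrix, 2)
        planted = [truth.archetype[s] for s in cohort_log_matrix.columns]
        predicted = [labels[s] for s in cohort_log_matrix.columns]
        assert adjusted_rand_score(planted, predicted) > 0.9


class TestPca:
    def test_identical_samples_project_to_origin(self):
        m = frame(np.ones((5, 8)))
        coords = pca_project(m)
        assert np.allclose(coords.to_numpy(), 0.0, atol=1e-8)

    def test_first_component_separates_two_clusters(self):
        m, planted = blobs([0, 4], 15, seed=4)
        coords = pca_project(m)
        assert silhouette_score(coords[["PC1"]], planted) > 0.5

    def test_component_variances_ordered(self, cohort_log_matrix):
        coords = pca_project(cohort_log_matrix, n_components=2)
        assert coords["PC1"].var() >= coords["PC2"].var()

    def test_sign_convention_is_stable(self, cohort_log_matrix):
        a = pca_project(cohort_log_matrix)
        b = pca_project(cohort_log_matrix)
        assert a.equals(b)

    def test_excess_components_rejected(self):
        with pytest.raises(tc.ValidationError):
            pca_project(frame(np.zeros((3, 2))), n_components=5)


class TestOutliers:
    def test_homogeneous_cloud_rarely_flags(self):
        # With 30 samples and z = 3 the familywise false-alarm rate of a
        # max-z rule is a few percent (~4% even for an exactly normal
        # statistic), so "rarely" means: the large majority of homogeneous
        # cohorts flag nothing, and flagged cohorts flag a single sample.
        flagged_runs, flagged_samples = 0, 0
        for s in range(100):
            m = frame(np.random.default_rng(5000 + s).normal(size=(30, 10)))
            hits = flag_outliers(m)
            flagged_runs += bool(hits)
            flagged_samples += len(hits)
        assert flagged_runs <= 15
        assert flagged_samples <= flagged_runs + 2

    def test_displaced_sample_is_flagged(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 10))
        X[0] += 20 * X.std()
        assert "s0" in flag_outliers(frame(X))

    def test_identical_quartet_flags_nothing(self):
        assert flag_outliers(frame(np.ones((4, 5)))) == set()

    def test_too_few_samples_rejected(self):
        with pytest.raises(tc.ValidationError):
            flag_outliers(frame(np.zeros((3, 2))))


class TestNegativeAssignment:
    def test_negatives_inherit_braf_majority(self):
        labels = {s: 1 for s in "abcde"}
        status = {"a": "positive-BRAF", "b": "positive-BRAF",
                  "c": "negative", "d": "negative", "e": "negative"}
        out = assign_negative_classes(labels, status)
        assert out == {"c": "negative-BL", "d": "negative-BL", "e": "negative-BL"}

    def test_ras_only_cluster_without_negatives_is_empty(self):
        labels = {"a": 1, "b": 1}
        status = {"a": "positive-RAS", "b": "positive-PAX8-PPARg"}
        assert assign_negative_classes(labels, status) == {}

    def test_tied_cluster_raises_instead_of_guessing(self):
        labels = {s: 1 for s in "abcde"}
        status = {"a": "positive-BRAF", "b": "positive-BRAF",
                  "c": "positive-RAS", "d": "positive-PAX8-PPARg", "e": "negative"}
        with pytest.raises(tc.UnresolvedClusterError) as err:
            assign_negative_classes(labels, status)
        assert err.value.negatives == ["e"]

    def test_cluster_without_positives_raises(self):
        with pytest.raises(tc.UnresolvedClusterError):
            assign_negative_classes({"a": 1}, {"a": "negative"})

    def test_flagged_histology_reported_separately(self):
        labels = {"a": 1, "b": 1, "c": 1}
        status = {"a": "positive-RAS", "b": "negative", "c": "negative"}
        out = assign_negative_classes(labels, status, histology={"c": "HCC"})
        assert out == {"b": "negative-RL", "c": "negative-other"}

    def test_missing_driver_status_is_an_error(self):
        with pytest.raises(tc.ValidationError):
            assign_negative_classes({"a": 1}, {})
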