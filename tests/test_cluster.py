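from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from situp import (WardSilhouetteClustering, cluster_cohort, cut_tree,
                   distance_matrix, select_k, silhouette, ward_linkage)


def brute_force_ward(X):
    """Exhaustive agglomeration: evaluate every candidate merge's dESS.

    Independent oracle: no Lance-Williams recurrence — cluster centroids are
    recomputed from the raw points at every step.  Returns (heights,
    leaf-set sequence) with heights sqrt(2 * dESS) and ties broken on the
    smallest (left, right) cluster-id pair.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    heights, leafsets = [], []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            pa, pb = X[clusters[a]], X[clusters[b]]
            na, nb = len(pa), len(pb)
            dess = na * nb / (na + nb) * float(
                np.sum((pa.mean(0) - pb.mean(0)) ** 2))
            key = (dess, a, b)
            if best is None or key < best:
                best = key
        dess, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = merged
        next_id += 1
        heights.append(np.sqrt(2 * dess))
        leafsets.append(frozenset(merged))
    return np.array(heights), leafsets


def linkage_leafsets(linkage):
    sets = {i: frozenset([i]) for i in range(linkage.n)}
    out = []
    for t, (l, r, _, _) in enumerate(linkage.merges):
        s = sets[l] | sets[r]
        sets[linkage.n + t] = s
        out.append(s)
    return out


class TestDistanceMatrix:
    def test_three_four_five(self):
        d = distance_matrix(np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == d[1, 1] == 0.0

    def test_identical_rows_distance_zero(self):
        d = distance_matrix(np.array([[1.0, 2.0, 3.0]] * 3))
        assert np.allclose(d, 0.0)

    def test_triangle_inequality_on_random_rows(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3)) * 20
        d = distance_matrix(X)
        assert np.allclose(d, d.T)
        idx = rng.integers(0, 100, size=(300, 3))
        for i, j, k in idx:
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_nonfinite_feature_names_subject(self):
        X = np.array([[0.0, 0.0, 0.0], [np.nan, 1.0, 1.0]])
        with pytest.raises(ValueError, match="S17"):
            distance_matrix(X, subject_ids=["S16", "S17"])


class TestWardLinkage:
    def test_two_singletons_merge_at_euclidean_distance(self):
        d = distance_matrix(np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]))
        L = ward_linkage(d)
        assert len(L.merges) == 1
        assert L.merges[0][2] == pytest.approx(5.0)

    def test_identical_points_merge_at_height_zero(self):
        X = np.ones((6, 3))
        L = ward_linkage(distance_matrix(X))
        assert all(m[2] == pytest.approx(0.0, abs=1e-9) for m in L.merges)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_dess_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        X = rng.normal(size=(n, 3)) * 10
        L = ward_linkage(distance_matrix(X))
        h_oracle, sets_oracle = brute_force_ward(X)
        h_ours = np.array([m[2] for m in L.merges])
        assert np.allclose(h_ours, h_oracle, atol=1e-8)
        assert linkage_leafsets(L) == sets_oracle

    def test_matches_scipy_ward(self):
        from scipy.cluster.hierarchy import fcluster
        from scipy.cluster.hierarchy import linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3)) * 15
        d = distance_matrix(X)
        L = ward_linkage(d)
        Z = scipy_linkage(squareform(d, checks=False), method="ward")
        assert np.allclose(np.array([m[2] for m in L.merges]), Z[:, 2], atol=1e-8)
        for k in (2, 5, 8):
            assert adjusted_rand_score(cut_tree(L, k),
                                       fcluster(Z, k, "maxclust")) == 1.0

    def test_heights_non_decreasing_property(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X = rng.normal(size=(int(rng.integers(5, 60)), 3)) * 30
            L = ward_linkage(distance_matrix(X))
            h = [m[2] for m in L.merges]
            assert all(b >= a - 1e-9 for a, b in zip(h, h[1:]))


class TestCutTree:
    def triads(self):
        a = np.array([[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0]])
        b = a + 100.0
        return np.vstack([a, b, [[50, 50, 50]], [[-50, 0, 0]]])

    def test_trivial_cuts(self):
        X = np.random.default_rng(0).normal(size=(7, 3))
        L = ward_linkage(distance_matrix(X))
        assert len(np.unique(cut_tree(L, 7))) == 7
        assert len(np.unique(cut_tree(L, 1))) == 1

    def test_triads_recovered_at_k4(self):
        X = self.triads()
        L = ward_linkage(distance_matrix(X))
        labels = cut_tree(L, 4)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert len({labels[0], labels[3], labels[6], labels[7]}) == 4

    def test_labels_ordered_by_first_leaf_appearance(self):
        X = self.triads()
        L = ward_linkage(distance_matrix(X))
        labels = cut_tree(L, 4)
        assert labels[0] == 1  # leaf 0 always in cluster 1
        first_seen = []
        for lab in labels:
            if lab not in first_seen:
                first_seen.append(lab)
        assert first_seen == sorted(first_seen)

    def test_out_of_range_k_rejected(self):
        L = ward_linkage(distance_matrix(np.eye(3)))
        with pytest.raises(ValueError):
            cut_tree(L, 0)
        with pytest.raises(ValueError):
            cut_tree(L, 4)


class TestSilhouette:
    def test_perfect_separation_scores_one(self):
        X = np.array([[0, 0, 0]] * 3 + [[10, 0, 0]] * 3, dtype=float)
        d = distance_matrix(X)
        mean, s = silhouette(d, np.array([1, 1, 1, 2, 2, 2]))
        assert mean == pytest.approx(1.0)

    def test_singleton_scores_zero(self):
        X = np.array([[0.0, 0, 0], [1.0, 0, 0], [10.0, 0, 0]])
        _, s = silhouette(distance_matrix(X), np.array([1, 1, 2]))
        assert s[2] == 0.0

    def test_four_points_on_line_closed_form(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        d = distance_matrix(X)
        mean, s = silhouette(d, np.array([1, 1, 2, 2]))
        s0 = (10.5 - 1) / 10.5  # a=1, b=(10+11)/2
        s1 = (9.5 - 1) / 9.5
        assert mean == pytest.approx((2 * s0 + 2 * s1) / 4)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_direct_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        X = rng.normal(size=(n, 3)) * 10
        k = int(rng.integers(2, 6))
        labels = rng.integers(1, k + 1, size=n)
        if len(np.unique(labels)) < 2:
            labels[0] = 1
            labels[1] = 2
        d = distance_matrix(X)
        mean, s = silhouette(d, labels)
        # independent direct evaluation
        exp = []
        for i in range(n):
            own = [j for j in range(n) if labels[j] == labels[i] and j != i]
            if not own:
                exp.append(0.0)
                continue
            a = np.mean([d[i, j] for j in own])
            b = min(np.mean([d[i, j] for j in range(n) if labels[j] == c])
                    for c in np.unique(labels) if c != labels[i])
            exp.append((b - a) / max(a, b))
        assert np.allclose(s, exp)
        assert mean == pytest.approx(np.mean(exp))

    def test_requires_two_clusters(self):
        d = distance_matrix(np.eye(3))
        with pytest.raises(ValueError):
            silhouette(d, np.array([1, 1, 1]))


class TestSelectK:
    def test_three_blobs_give_k3(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0, 0], [100, 0, 0], [0, 100, 0]], dtype=float)
        X = np.vstack([c + rng.normal(0, 2, size=(12, 3)) for c in centers])
        d = distance_matrix(X)
        L = ward_linkage(d)
        k, profile = select_k(d, L, (2, 10))
        assert k == 3
        assert all(-1 <= v <= 1 for v in profile.values())

    def test_fallback_to_global_max_when_no_interior_maximum(self):
        X = np.array([[0.0, 0, 0], [0.2, 0, 0], [10.0, 0, 0], [10.2, 0, 0]])
        d = distance_matrix(X)
        L = ward_linkage(d)
        k, profile = select_k(d, L, (2, 3))  # no interior k exists
        assert k == max(profile, key=profile.get)


class TestEstimatorAndCohort:
    def features(self, seed=0):
        from situp import generate_cohort
        profs = generate_cohort(seed=seed)
        return (pd.DataFrame({
            "subject_id": [p.subject_id for p in profs],
            "d_sbp": [p.target_dsbp for p in profs],
            "d_dbp": [p.target_ddbp for p in profs],
            "d_hr": [p.target_dhr for p in profs],
        }), np.array([p.cluster_id for p in profs]))

    def test_sklearn_estimator_contract(self):
        est = WardSilhouetteClustering(n_clusters=3)
        params = est.get_params()
        assert params["n_clusters"] == 3 and "standardize" in params
        est2 = clone(est).set_params(n_clusters=2)
        X = np.random.default_rng(0).normal(size=(20, 3))
        labels = est2.fit_predict(X)
        assert est2.k_ == 2 and len(np.unique(labels)) == 2
        assert np.array_equal(labels, est2.labels_)
        assert hasattr(est2, "linkage_") and est2.n_features_in_ == 3

    def test_template_centroids_at_zero_noise_are_8_distinct_leaves(self):
        from situp import make_cluster_templates
        X = np.array([[t.sbp_med, t.dbp_med, t.hr_med]
                      for t in make_cluster_templates()], dtype=float)
        res = cluster_cohort(X, n_clusters=8)
        assert res.linkage.n == 8 and len(np.unique(res.assignments)) == 8

    def test_default_cohort_recovers_generating_labels(self):
        df, truth = self.features(seed=0)
        res = cluster_cohort(df)
        assert res.k == 8
        assert adjusted_rand_score(truth, res.assignments) >= 0.9
        assert res.subject_ids[0] == "S000"

    def test_row_permutation_invariance(self):
        df, _ = self.features(seed=1)
        X = df[["d_sbp", "d_dbp", "d_hr"]].to_numpy()
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(X))
        a = WardSilhouetteClustering(n_clusters=8).fit_predict(X)
        b = WardSilhouetteClustering(n_clusters=8).fit_predict(X[perm])
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_per_feature_translation_invariance(self):
        df, _ = self.features(seed=2)
        X = df[["d_sbp", "d_dbp", "d_hr"]].to_numpy()
        Y = X.copy()
        Y[:, 1] += 57.0
        a = WardSilhouetteClustering(n_clusters=8).fit_predict(X)
        b = WardSilhouetteClustering(n_clusters=8).fit_predict(Y)
        assert np.array_equal(a, b)

    def test_standardize_option_runs_and_differs_in_general(self):
        X = np.random.default_rng(1).normal(size=(30, 3)) * [1, 1, 100]
        a = WardSilhouetteClustering(n_clusters=3, standardize=False).fit(X)
        b = WardSilhouetteClustering(n_clusters=3, standardize=True).fit(X)
        assert a.k_ == b.k_ == 3

    def test_missing_feature_column_rejected(self):
        with pytest.raises(ValueError, match="d_hr"):
            cluster_cohort(pd.DataFrame({"d_sbp": [1, 2], "d_dbp": [1, 2]}))
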