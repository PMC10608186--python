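import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from nocturne.cgm_io import N_SLOTS
from nocturne.clustering import (
    hierarchical_cluster,
    medoid,
    select_k,
    silhouette,
    summarize_cluster,
)
from nocturne.nh_detection import detect_nh_episodes

from conftest import make_segment


def make_bundles(rng, centers, n_per, spread=0.05):
    """Tight Gaussian bundles around given center vectors."""
    X, truth = [], []
    for c, center in enumerate(centers):
        X.append(center + rng.normal(0, spread, (n_per, len(center))))
        truth += [c] * n_per
    return np.vstack(X), np.array(truth)


def brute_force_ward(X):
    """Independent Ward oracle: exhaustively pick, at each step, the merge
    with the minimum increase in total within-cluster variance
    (|A||B|/(|A|+|B|) * ||mean_A - mean_B||^2).  Returns the sequence of
    merged index-sets."""
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best, best_pair = None, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                A = np.array(sorted(clusters[a]))
                B = np.array(sorted(clusters[b]))
                d = X[A].mean(axis=0) - X[B].mean(axis=0)
                cost = len(A) * len(B) / (len(A) + len(B)) * float(d @ d)
                if best is None or cost < best - 1e-12:
                    best, best_pair = cost, (a, b)
        a, b = best_pair
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def scipy_merge_sets(Z, n):
    sets = [frozenset([i]) for i in range(n)]
    merges = []
    for row in Z:
        merged = sets[int(row[0])] | sets[int(row[1])]
        merges.append(merged)
        sets.append(merged)
    return merges


class TestHierarchicalCluster:
    def test_two_separated_bundles_perfectly_recovered(self, rng):
        X, truth = make_bundles(rng, [np.zeros(N_SLOTS), np.ones(N_SLOTS) * 5], 20)
        sol = hierarchical_cluster(X, 2)
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_identical_series_merge_at_height_zero(self):
        X = np.tile(np.linspace(0, 1, N_SLOTS), (6, 1))
        sol = hierarchical_cluster(X, 2)
        assert np.allclose(sol.linkage[:, 2], 0.0)

    def test_merge_sequence_matches_exhaustive_ward_oracle(self, rng):
        # toy length-2 series: 2 trios on a line
        X = np.array([[0.0, 0], [0.1, 0], [0.25, 0], [4.0, 0], [4.2, 0], [4.5, 0]])
        sol = hierarchical_cluster(X, 2)
        assert scipy_merge_sets(sol.linkage, 6) == brute_force_ward(X)

    def test_merge_sequence_matches_oracle_on_random_data(self, rng):
        X = rng.normal(0, 1, (12, 4))
        sol = hierarchical_cluster(X, 2)
        assert scipy_merge_sets(sol.linkage, 12) == brute_force_ward(X)

    def test_merge_heights_non_decreasing(self, rng):
        X = rng.normal(0, 1, (40, N_SLOTS))
        sol = hierarchical_cluster(X, 5)
        assert (np.diff(sol.linkage[:, 2]) >= -1e-12).all()

    def test_labels_numbered_by_decreasing_size(self, rng):
        X, _ = make_bundles(rng, [np.zeros(4), np.ones(4) * 9], n_per=10)
        X = np.vstack([X, np.ones(4) * 9 + 0.01])  # second bundle has 11
        sol = hierarchical_cluster(X, 2)
        sizes = [(sol.labels == c).sum() for c in (1, 2)]
        assert sizes[0] >= sizes[1]

    def test_nested_partitions_differ_by_one_split(self, rng):
        X = rng.normal(0, 1, (30, 8))
        sol = hierarchical_cluster(X, 2)
        for k in range(2, 8):
            a = fcluster(sol.linkage, t=k, criterion="maxclust")
            b = fcluster(sol.linkage, t=k + 1, criterion="maxclust")
            # each coarse cluster maps onto >=1 fine cluster; exactly one onto 2
            fine_per_coarse = [len(set(b[a == c])) for c in set(a)]
            assert sorted(fine_per_coarse) == [1] * (len(set(a)) - 1) + [2]

    def test_invalid_k_raises(self, rng):
        X = rng.normal(0, 1, (5, 3))
        with pytest.raises(ValueError):
            hierarchical_cluster(X, 1)
        with pytest.raises(ValueError):
            hierarchical_cluster(X, 6)

    def test_permutation_invariance_up_to_relabelling(self, rng):
        X, _ = make_bundles(rng, [np.zeros(6), np.ones(6) * 4, np.ones(6) * -3], 8)
        perm = rng.permutation(len(X))
        sol1 = hierarchical_cluster(X, 3)
        sol2 = hierarchical_cluster(X[perm], 3)
        assert adjusted_rand_score(sol1.labels[perm], sol2.labels) == 1.0


def silhouette_by_definition(X, labels):
    """Hand-rolled silhouette: mean over points of (b-a)/max(a,b), singleton
    points scoring 0."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            scores.append(0.0)
            continue
        a = D[i][own].sum() / (own.sum() - 1)
        b = min(D[i][labels == c].mean() for c in set(labels) if c != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestSilhouette:
    def test_well_separated_bundles_score_above_0_9(self, rng):
        X, truth = make_bundles(rng, [np.zeros(10), np.ones(10) * 8], 15)
        assert silhouette(X, truth) > 0.9

    def test_matches_by_definition_implementation(self, rng):
        X = rng.normal(0, 1, (25, 6))
        labels = rng.integers(0, 3, 25)
        labels[:3] = [0, 1, 2]  # ensure all clusters present
        assert silhouette(X, labels) == pytest.approx(
            silhouette_by_definition(X, labels), abs=1e-10
        )

    def test_singleton_cluster_contributes_zero(self, rng):
        X = rng.normal(0, 1, (10, 4))
        labels = np.array([1] * 9 + [2])
        assert silhouette(X, labels) == pytest.approx(
            silhouette_by_definition(X, labels), abs=1e-10
        )

    def test_random_labels_on_structureless_data_near_zero(self, rng):
        X = rng.normal(0, 1, (200, 10))
        labels = rng.integers(0, 4, 200)
        assert abs(silhouette(X, labels)) < 0.1

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette(rng.normal(0, 1, (5, 3)), np.ones(5))


class TestSelectK:
    def test_recovers_four_archetype_bundles(self, rng):
        centers = [rng.normal(0, 1, 12) * 4 for _ in range(4)]
        X, _ = make_bundles(rng, centers, 25, spread=0.3)
        sel = select_k(X, 2, 10)
        assert sel.k_best == 4
        assert len(sel.ks) == 9

    def test_tie_tolerance_prefers_smallest_k(self, rng):
        X, _ = make_bundles(rng, [np.zeros(6), np.ones(6) * 5], 10, spread=0.1)
        sel = select_k(X, 2, 6, tie_tol=2.0)  # everything ties
        assert sel.k_best == 2

    def test_override_pins_k(self, rng):
        centers = [rng.normal(0, 1, 12) * 4 for _ in range(3)]
        X, _ = make_bundles(rng, centers, 15, spread=0.3)
        sel = select_k(X, 2, 10, override=7)
        assert sel.solution.k == 7 and sel.overridden
        assert sel.k_best == 3  # curve still reports the argmax

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(0, 1, (10, 3)), k_min=5, k_max=3)


class TestMedoid:
    def test_singleton(self):
        assert medoid(np.array([[1.0, 2.0]])) == 0

    def test_identical_members_tie_to_first(self):
        assert medoid(np.tile([1.0, 2.0], (3, 1))) == 0

    @pytest.mark.parametrize("n", [2, 7, 23, 50])
    def test_matches_exhaustive_search(self, n, rng):
        X = rng.normal(0, 1, (n, 9))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        assert medoid(X) == int(np.argmin(D.sum(axis=1)))


class TestSummarizeCluster:
    def test_initial_is_mean_of_first_three(self):
        seg = make_segment([5.0, 5.2, 5.4] + [7.0] * 69)
        s = summarize_cluster([seg])
        assert s.initial_glucose["median"] == pytest.approx(5.2)

    def test_constant_member_has_zero_change(self):
        seg = make_segment(np.full(N_SLOTS, 6.0))
        s = summarize_cluster([seg])
        assert s.final_glucose["median"] == 6.0
        assert s.glucose_change["median"] == 0.0

    def test_change_is_exactly_final_minus_initial(self, rng):
        members = [make_segment(rng.uniform(3, 15, N_SLOTS), patient_id=f"p{i}") for i in range(9)]
        s = summarize_cluster(members)
        values = np.array([m.values for m in members])
        change = values[:, -3:].mean(1) - values[:, :3].mean(1)
        q1, med, q3 = np.percentile(change, [25, 50, 75])
        assert s.glucose_change["median"] == pytest.approx(med)
        assert s.glucose_change["q1"] == pytest.approx(q1)
        assert s.glucose_change["q3"] == pytest.approx(q3)
        assert s.glucose_change["min"] == change.min()
        assert s.glucose_change["max"] == change.max()

    def test_nh_statistics_omitted_without_episodes(self, rng):
        members = [make_segment(rng.uniform(5, 9, N_SLOTS))]
        eps = [detect_nh_episodes(m) for m in members]
        s = summarize_cluster(members, episodes=eps)
        assert s.nh_start_time is None

    def test_nh_start_time_summarized_when_present(self):
        values = np.full(N_SLOTS, 6.0)
        values[24:28] = 3.0
        member = make_segment(values)
        s = summarize_cluster([member], episodes=[detect_nh_episodes(member)])
        assert s.nh_start_time["median"] == pytest.approx(2.0)

    def test_medoid_is_member_index(self, rng):
        members = [make_segment(rng.uniform(3, 15, N_SLOTS)) for _ in range(5)]
        s = summarize_cluster(members)
        assert 0 <= s.medoid_index < 5

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            summarize_cluster([])
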