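from itertools import combinations

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from mrsport.core_data import ValidationError
from mrsport.embed_cluster import (
    ParallelAnalysisPCA,
    embed2d,
    marker_metabolites,
    pca,
    select_nontrivial,
    snn_cluster,
    snn_graph,
)


def _spiked(rank, strength, seed, n=200, p=34):
    # spike scales ~[1, 0.9, 0.8, ...] of `strength` so all planted
    # components clear the permutation null together
    rng = np.random.default_rng(seed)
    scales = strength * (1.0 - 0.1 * np.arange(rank))
    U = rng.normal(size=(n, rank)) * scales
    V = rng.normal(size=(rank, p))
    return U @ V + rng.normal(size=(n, p))


class TestPCA:
    def test_rank_one_concentrates_first_share(self, rng):
        X = rng.random((50, 1)) @ rng.random((1, 10))
        res = pca(X, n_components=5)
        assert res.explained_share[0] > 0.999999
        assert np.all(res.explained_share[1:] < 1e-9)

    def test_scores_reconstruct_centered_matrix(self, rng):
        X = rng.random((40, 10))
        res = pca(X, n_components=10)
        assert np.allclose(res.scores @ res.eigenvectors.T, X - X.mean(0),
                           atol=1e-8)

    def test_eigenvalues_sum_to_total_variance(self, rng):
        X = rng.random((40, 10))
        res = pca(X, n_components=10)
        assert res.eigenvalues.sum() == pytest.approx(
            X.var(0, ddof=1).sum(), abs=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_eigenvectors_orthonormal(self, rng):
        X = rng.random((60, 12))
        res = pca(X, n_components=12)
        G = res.eigenvectors.T @ res.eigenvectors
        assert np.allclose(G, np.eye(12), atol=1e-8)

    def test_isotropic_data_has_flat_spectrum(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(3000, 5))
        res = pca(X, n_components=5)
        assert np.all(np.abs(res.explained_share - 0.2) < 0.2 * 0.2)

    def test_too_few_rows_reduces_with_warning(self, rng):
        with pytest.warns(UserWarning, match="reducing n_components"):
            res = pca(rng.random((10, 34)), n_components=30)
        assert res.n_components == 9


class TestSelectNontrivial:
    def test_pure_noise_selects_at_most_one(self):
        hits = sum(
            len(select_nontrivial(
                np.random.default_rng(s).normal(size=(200, 34)), seed=s)) <= 1
            for s in range(20))
        assert hits >= 18

    def test_planted_rank_three_recovered(self):
        hits = sum(
            len(select_nontrivial(_spiked(3, 6.0, s), seed=s)) == 3
            for s in range(20))
        assert hits >= 18

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(100, 20))
        assert select_nontrivial(X, seed=4) == select_nontrivial(X, seed=4)

    def test_monotone_in_spike_strength(self):
        """Stronger planted signal never selects fewer components."""
        counts = [len(select_nontrivial(_spiked(3, s, seed=2), seed=2))
                  for s in (0.5, 2.0, 4.0, 8.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestSNN:
    def test_hand_enumerated_jaccard_weights(self):
        # 5 points on a line; k=2 nearest (incl. self-augmented sets)
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        G = snn_graph(X, k_neighbors=2, prune=0.0)
        # neighbor sets: 0:{0,1} 1:{1,0} 2:{2,1} 3:{3,4} 4:{4,3}
        assert G[0][1]["weight"] == pytest.approx(1.0)  # {0,1} vs {1,0}
        assert G[1][2]["weight"] == pytest.approx(1.0 / 3.0)  # {0,1} vs {1,2}
        assert G[3][4]["weight"] == pytest.approx(1.0)
        assert not G.has_edge(2, 3)

    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([c + rng.normal(0, 0.1, (100, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 100)
        res = snn_cluster(X, k_neighbors=20, seed=0)
        assert res.n_clusters == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.95

    def test_identical_points_form_one_cluster(self):
        X = np.zeros((30, 3))
        res = snn_cluster(X, k_neighbors=5, seed=0)
        assert res.n_clusters == 1

    def test_row_permutation_only_permutes_labels(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.1, (50, 2)),
                       rng.normal(5, 0.1, (50, 2))])
        labels = snn_cluster(X, k_neighbors=10, seed=1).labels
        perm = rng.permutation(100)
        labels_p = snn_cluster(X[perm], k_neighbors=10, seed=1).labels
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValidationError):
            snn_cluster(rng.random((5, 2)), k_neighbors=10)


class TestEmbed2d:
    def test_shape_and_determinism(self, rng):
        X = rng.random((60, 5))
        a = embed2d(X, seed=3)
        b = embed2d(X, seed=3)
        assert a.shape == (60, 2) and np.array_equal(a, b)

    def test_blobs_stay_separated(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.2, (60, 4)),
                       rng.normal(8, 0.2, (60, 4))])
        emb = embed2d(X, seed=0)
        a, b = emb[:60], emb[60:]
        within = (np.mean([np.linalg.norm(p - q) for p, q in combinations(a[:25], 2)])
                  + np.mean([np.linalg.norm(p - q) for p, q in combinations(b[:25], 2)])) / 2
        between = np.mean([np.linalg.norm(p - q) for p in a[:25] for q in b[:25]])
        assert within < between


class TestMarkers:
    def test_planted_enrichment_is_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(10, 1, size=(100, 34))
        labels = np.repeat([1, 2], 50)
        X[labels == 1, 5] *= 2.0  # metabolite 5 enriched in cluster 1
        df = marker_metabolites(X, labels)
        hit = df[(df.cluster == 1) & (df.metabolite == "m5")]
        assert bool(hit.is_marker.iloc[0])

    def test_small_group_pvalue_matches_exact_enumeration(self):
        a = np.array([1.3, 2.9, 0.4])
        b = np.array([2.1, 0.8, 3.5])
        obs = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact").pvalue
        # brute force over all C(6,3) assignments of the pooled ranks
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:3].sum() - 3 * 4 / 2
        stat_obs = min(u_obs, 9 - u_obs)
        count = 0
        total = 0
        for idx in combinations(range(6), 3):
            u = ranks[list(idx)].sum() - 3 * 4 / 2
            total += 1
            if min(u, 9 - u) <= stat_obs:
                count += 1
        assert obs == pytest.approx(count / total, abs=1e-12)
        df = marker_metabolites(
            np.concatenate([a, b])[:, None] * np.ones((1, 2)),
            np.repeat([1, 2], 3))
        assert df.p.iloc[0] == pytest.approx(obs, abs=1e-12)

    def test_null_false_positive_rate_is_controlled(self):
        """Mini null calibration (full 200-run version in acceptance)."""
        fracs = []
        for s in range(30):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(60, 34))
            labels = np.repeat([1, 2, 3], 20)
            df = marker_metabolites(X, labels)
            fracs.append((df.p_adj < 0.05).mean())
        assert np.mean(fracs) <= 0.05 + 2 * np.std(fracs) / np.sqrt(len(fracs))

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValidationError):
            marker_metabolites(rng.random((10, 4)), np.ones(10))

    def test_adjusted_p_not_smaller_than_p(self, rng):
        X = rng.random((40, 10))
        df = marker_metabolites(X, np.repeat([1, 2], 20))
        assert (df.p_adj >= df.p - 1e-12).all()
        assert df.p.between(0, 1).all()
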