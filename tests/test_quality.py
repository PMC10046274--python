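import math

import numpy as np
import pytest

import chemclust as cc
from chemclust.errors import ValidationError
from chemclust.quality import SIZE_PERCENTILES

from conftest import make_fps
from _oracles import (
    naive_calinski_harabasz,
    naive_davies_bouldin,
    naive_silhouette,
    naive_tanimoto_matrix,
)


def random_instance(seed, n_max=200, k_max=10):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, n_max + 1))
    k = int(rng.integers(2, min(k_max, n // 2) + 1))
    x = rng.normal(size=(n, int(rng.integers(2, 8))))
    labels = rng.integers(0, k, n)
    # re-index so labels cover 0..k'-1 without gaps
    _, labels = np.unique(labels, return_inverse=True)
    return x, labels


class TestSilhouette:
    def test_perfectly_tight_clusters_score_one(self):
        x = np.array([[0.0], [0.0], [5.0], [5.0]])
        labels = np.array([0, 0, 1, 1])
        mean, _ = cc.silhouette_mean(x, labels)
        assert mean == pytest.approx(1.0)

    def test_hand_computed_1d_example(self):
        # {0,1} vs {5,6}: per-point SC = 0.8182, 0.7778, 0.7778, 0.8182
        x = np.array([[0.0], [1.0], [5.0], [6.0]])
        labels = np.array([0, 0, 1, 1])
        mean, terms = cc.silhouette_mean(x, labels)
        assert terms.sc == pytest.approx([9 / 11, 7 / 9, 7 / 9, 9 / 11], abs=1e-4)
        assert mean == pytest.approx(0.7980, abs=1e-4)

    def test_singleton_contributes_zero(self):
        x = np.array([[0.0], [1.0], [9.0]])
        labels = np.array([0, 0, 1])
        _, terms = cc.silhouette_mean(x, labels)
        assert terms.sc[2] == 0.0

    def test_all_singletons_mean_zero(self):
        x = np.arange(4, dtype=float)[:, None]
        mean, _ = cc.silhouette_mean(x, np.arange(4))
        assert mean == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            cc.silhouette_mean(np.zeros((3, 1)), np.zeros(3, dtype=int))

    def test_accepts_precomputed_distances(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, 30)
        from scipy.spatial.distance import pdist, squareform

        direct, _ = cc.silhouette_mean(x, labels)
        pre, _ = cc.silhouette_mean(squareform(pdist(x)), labels, precomputed=True)
        assert direct == pytest.approx(pre, abs=1e-12)

    def test_per_point_values_bounded(self):
        for seed in range(10):
            x, labels = random_instance(seed, n_max=80)
            _, terms = cc.silhouette_mean(x, labels)
            assert np.all(terms.sc >= -1.0) and np.all(terms.sc <= 1.0)


class TestCalinskiHarabasz:
    def test_hand_computed_1d_example(self):
        # {0,1} and {10,11}: tr_W = 1, tr_B = 100, CH = 100 * (4-2)/(2-1)
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        ch, terms = cc.calinski_harabasz(x, np.array([0, 0, 1, 1]))
        assert terms.tr_w == pytest.approx(1.0)
        assert terms.tr_b == pytest.approx(100.0)
        assert ch == pytest.approx(200.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            cc.calinski_harabasz(np.zeros((3, 1)), np.zeros(3, dtype=int))

    def test_zero_dispersion_gives_infinity_sentinel(self):
        x = np.array([[0.0], [10.0]])
        ch, _ = cc.calinski_harabasz(x, np.array([0, 1]))
        assert math.isinf(ch)

    def test_scatter_conservation(self):
        for seed in range(20):
            x, labels = random_instance(seed)
            _, terms = cc.calinski_harabasz(x, labels)
            total = float(((x - x.mean(axis=0)) ** 2).sum())
            assert terms.tr_w + terms.tr_b == pytest.approx(total, abs=1e-9 * max(1, total))


class TestDaviesBouldin:
    def test_hand_computed_1d_example(self):
        # {0,2} and {10,12}: s = (1,1), centroid distance 10, DB = 0.2
        x = np.array([[0.0], [2.0], [10.0], [12.0]])
        db, terms = cc.davies_bouldin(x, np.array([0, 0, 1, 1]))
        assert np.allclose(terms.s, [1.0, 1.0])
        assert db == pytest.approx(0.2)

    def test_coincident_centroids_give_infinity(self):
        x = np.array([[0.0], [2.0], [0.0], [2.0]])
        db, _ = cc.davies_bouldin(x, np.array([0, 0, 1, 1]))
        assert math.isinf(db)

    def test_collapsed_distinct_clusters_score_zero(self):
        x = np.array([[0.0], [0.0], [5.0], [5.0]])
        db, _ = cc.davies_bouldin(x, np.array([0, 0, 1, 1]))
        assert db == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            cc.davies_bouldin(np.zeros((3, 1)), np.zeros(3, dtype=int))


class TestOracleEquivalence:
    """The three indices against naive transcriptions of their definitions."""

    @pytest.mark.parametrize("seed", range(30))
    def test_all_three_match_naive_oracles(self, seed):
        from scipy.spatial.distance import pdist, squareform

        x, labels = random_instance(seed)
        sil, _ = cc.silhouette_mean(x, labels)
        ch, _ = cc.calinski_harabasz(x, labels)
        db, _ = cc.davies_bouldin(x, labels)
        d = squareform(pdist(x))
        assert sil == pytest.approx(naive_silhouette(d, labels), abs=1e-9)
        assert ch == pytest.approx(naive_calinski_harabasz(x, labels), rel=1e-9)
        assert db == pytest.approx(naive_davies_bouldin(x, labels), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_all_three_match_sklearn(self, seed):
        from sklearn.metrics import (
            calinski_harabasz_score,
            davies_bouldin_score,
            silhouette_score,
        )

        x, labels = random_instance(seed + 500)
        sil, _ = cc.silhouette_mean(x, labels)
        ch, _ = cc.calinski_harabasz(x, labels)
        db, _ = cc.davies_bouldin(x, labels)
        assert sil == pytest.approx(silhouette_score(x, labels), abs=1e-9)
        assert ch == pytest.approx(calinski_harabasz_score(x, labels), rel=1e-9)
        assert db == pytest.approx(davies_bouldin_score(x, labels), rel=1e-9)


class TestAverageSimilarityMatrix:
    def test_forced_values_two_tight_clusters(self):
        bits = [[1, 1, 0, 0]] * 2 + [[0, 0, 1, 1]] * 2
        asm = cc.average_similarity_matrix(make_fps(bits), np.array([0, 0, 1, 1]))
        assert asm.matrix[0, 0] == pytest.approx(1.0)
        assert asm.matrix[1, 1] == pytest.approx(1.0)
        assert asm.matrix[0, 1] == pytest.approx(0.0)

    def test_singleton_diagonal_missing(self):
        # two singletons sharing 2 of 5 set bits: similarity 2/(2+3) ... use
        # m1={b0,b1,b2}, m2={b0,b3,b4}: inter 1, union 5 -> 0.2
        bits = [[1, 1, 1, 0, 0], [1, 0, 0, 1, 1]]
        asm = cc.average_similarity_matrix(make_fps(bits), np.array([0, 1]))
        assert math.isnan(asm.matrix[0, 0]) and math.isnan(asm.matrix[1, 1])
        assert asm.matrix[0, 1] == pytest.approx(0.2)

    def test_pair_enumeration_mixed_clusters(self):
        rng = np.random.default_rng(0)
        bits = (rng.random((7, 32)) < 0.4).astype(np.uint8)
        labels = np.array([0, 0, 0, 1, 1, 2, 2])
        asm = cc.average_similarity_matrix(make_fps(bits), labels)
        sim = naive_tanimoto_matrix(bits)
        # diagonal: mean over distinct unordered within pairs
        members0 = [0, 1, 2]
        expect = np.mean([sim[i, j] for i in members0 for j in members0 if i < j])
        assert asm.matrix[0, 0] == pytest.approx(expect, abs=1e-12)
        # off-diagonal: mean over all cross pairs, symmetric
        expect01 = np.mean([sim[i, j] for i in members0 for j in [3, 4]])
        assert asm.matrix[0, 1] == pytest.approx(expect01, abs=1e-12)
        assert asm.matrix[1, 0] == asm.matrix[0, 1]

    def test_diagonal_dominance_on_planted_clusters(self, planted_fps):
        asm = cc.average_similarity_matrix(planted_fps, planted_fps.labels_true)
        assert asm.diagonal_dominant()

    def test_planted_beats_random_relabeling(self, planted_fps):
        x = planted_fps.bits.astype(float)
        good, _ = cc.silhouette_mean(x, planted_fps.labels_true)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(planted_fps.labels_true)
        bad, _ = cc.silhouette_mean(x, shuffled)
        assert good > bad


class TestClusterSizeSummary:
    def test_direct_arithmetic(self):
        # sizes [1, 1, 2]
        labels = np.array([0, 1, 2, 2])
        s = cc.cluster_size_summary(labels)
        assert s["min"] == 1 and s["max"] == 2
        assert s["mean"] == pytest.approx(4 / 3)

    def test_constant_sizes_have_zero_std(self):
        labels = np.repeat(np.arange(4), 5)
        assert cc.cluster_size_summary(labels)["std"] == 0.0

    def test_percentile_set_and_consistency(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 6, 100)
        _, labels = np.unique(labels, return_inverse=True)
        s = cc.cluster_size_summary(labels)
        assert {f"p{p}" for p in SIZE_PERCENTILES} <= set(s)
        sizes = np.bincount(labels)
        assert s["mean"] * s["n_clusters"] == pytest.approx(labels.size)
        assert s["p50"] == pytest.approx(np.percentile(sizes, 50))
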