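import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import chemclust as cc
from chemclust.errors import ValidationError

from conftest import condensed_from_sim, make_fps
from _oracles import brute_force_ward


def random_condensed(n, seed):
    rng = np.random.default_rng(seed)
    return pdist(rng.random((n, 4)))


class TestWardLinkage:
    def test_two_molecules_merge_at_their_distance(self):
        tree = cc.ward_linkage(condensed_from_sim([[1, 0.2], [0.2, 1]]))
        assert tree.merges[0, 2] == pytest.approx(0.8)
        assert tree.merges[0, 3] == 2

    def test_identical_molecules_merge_at_zero(self):
        tree = cc.ward_linkage(np.zeros(6))  # 4 points, all distances 0
        assert np.allclose(tree.merges[:, 2], 0.0)

    @pytest.mark.parametrize("n,seed", [(6, 0), (6, 1), (20, 2), (50, 3)])
    def test_matches_brute_force_greedy_oracle(self, n, seed):
        d = random_condensed(n, seed)
        tree = cc.ward_linkage(d)
        oracle = brute_force_ward(squareform(d))
        assert np.allclose(tree.merges[:, 2], oracle[:, 2], atol=1e-9)
        assert np.array_equal(tree.merges[:, 3], oracle[:, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_ward_exactly(self, seed):
        d = random_condensed(30, seed + 10)
        mine = cc.ward_linkage(d).to_scipy()
        ref = linkage(d, "ward")
        assert np.allclose(mine[:, 2], ref[:, 2], atol=1e-9)
        for k in (2, 3, 7):
            a = cc.cut_tree_k(cc.ward_linkage(d), k).labels
            b = fcluster(ref, k, criterion="maxclust")
            assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_heights_non_decreasing(self):
        for seed in range(5):
            tree = cc.ward_linkage(random_condensed(25, seed + 50))
            assert np.all(np.diff(tree.merges[:, 2]) >= 0)

    def test_single_molecule_rejected(self):
        with pytest.raises(ValidationError):
            cc.ward_linkage(np.array([]))


class TestCutTree:
    def _tree(self, n=15, seed=0):
        return cc.ward_linkage(random_condensed(n, seed))

    def test_cutoff_above_root_gives_one_cluster(self):
        tree = self._tree()
        assert cc.cut_tree(tree, tree.merges[-1, 2] + 1).n_clusters == 1

    def test_cutoff_below_first_merge_gives_singletons(self):
        tree = self._tree()
        first = tree.merges[0, 2]
        assert cc.cut_tree(tree, first * 0.5).n_clusters == tree.n_leaves

    def test_two_leaf_tree(self):
        tree = cc.ward_linkage(condensed_from_sim([[1, 0.2], [0.2, 1]]))
        assert cc.cut_tree(tree, 0.5).n_clusters == 2
        assert cc.cut_tree(tree, 0.8).n_clusters == 1  # <= rule admits the merge

    def test_labels_in_first_leaf_order(self):
        tree = self._tree()
        labels = cc.cut_tree(tree, float(np.median(tree.merges[:, 2]))).labels
        seen = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        assert seen == sorted(seen)

    def test_non_positive_cutoff_rejected(self):
        with pytest.raises(ValidationError):
            cc.cut_tree(self._tree(), 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 1000), st.floats(0.01, 3.0), st.floats(0.01, 3.0))
    def test_cluster_count_non_increasing_in_cutoff(self, seed, c1, c2):
        tree = self._tree(n=12, seed=seed)
        lo, hi = min(c1, c2), max(c1, c2)
        assert cc.cut_tree(tree, lo).n_clusters >= cc.cut_tree(tree, hi).n_clusters


class TestButina:
    def test_complete_graph_is_one_cluster(self):
        sim = np.ones((4, 4))
        assign = cc.butina_cluster(condensed_from_sim(sim), 0.9)
        assert assign.n_clusters == 1
        assert assign.butina_role.count("centroid") == 1
        assert "singleton" not in assign.butina_role

    def test_empty_graph_is_all_singletons(self):
        sim = np.eye(5)
        assign = cc.butina_cluster(condensed_from_sim(sim), 0.35)
        assert assign.n_clusters == 5
        assert assign.butina_role == ["singleton"] * 5

    def test_false_singleton_hand_trace(self):
        # molecule 5's only neighbor (2) is absorbed by the better centroid 1
        sim = np.eye(5)
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 4)]:
            sim[i, j] = sim[j, i] = 0.9
        assign = cc.butina_cluster(condensed_from_sim(sim), 0.9)
        assert list(assign.labels) == [0, 0, 0, 0, 1]
        assert assign.butina_role == ["centroid", "member", "member", "member", "singleton"]

    def test_members_within_centroid_sphere(self):
        rng = np.random.default_rng(0)
        bits = (rng.random((60, 64)) < 0.3).astype(np.uint8)
        fps = make_fps(bits)
        d = cc.pairwise_distances(fps)
        cutoff = 0.4
        assign = cc.butina_cluster(d, cutoff)
        sim = 1.0 - d.square()
        for label in range(assign.n_clusters):
            members = np.flatnonzero(assign.labels == label)
            if len(members) == 1:
                continue
            centroid = [m for m in members if assign.butina_role[m] == "centroid"]
            assert len(centroid) == 1
            assert all(sim[centroid[0], m] >= cutoff for m in members)

    def test_cluster_count_non_decreasing_in_cutoff(self):
        # relaxing (lowering) the similarity cutoff grows the exclusion
        # spheres and merges molecules into fewer clusters
        rng = np.random.default_rng(1)
        fps = make_fps((rng.random((50, 64)) < 0.3).astype(np.uint8))
        d = cc.pairwise_distances(fps)
        counts = [cc.butina_cluster(d, c).n_clusters for c in (0.2, 0.4, 0.6, 0.8, 0.95)]
        assert counts == sorted(counts)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValidationError):
            cc.butina_cluster(condensed_from_sim(np.eye(3)), 0.0)


class TestUmapRoute:
    def test_embedding_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        fps = make_fps((rng.random((100, 128)) < 0.2).astype(np.uint8))
        cfg = cc.UmapConfig(n_neighbors=10, min_dist=0.1, n_clusters=2, seed=42)
        e1 = cc.umap_embed(fps, cfg)
        e2 = cc.umap_embed(fps, cfg)
        assert e1.shape == (100, 2)
        assert np.array_equal(e1, e2)

    def test_too_few_points_rejected(self):
        fps = make_fps(np.eye(5, dtype=np.uint8))
        with pytest.raises(ValidationError):
            cc.umap_embed(fps, cc.UmapConfig(n_neighbors=10, n_clusters=2))

    def test_planted_two_cluster_recovery(self):
        spec = cc.SyntheticSpec(
            n_clusters=2, members_per_cluster=200, eps_off=0.1, eps_on=0.005,
            n_outliers=0, seed=0,
        )
        fps = cc.generate_planted_fingerprints(spec)
        cfg = cc.UmapConfig(n_neighbors=15, min_dist=0.1, n_clusters=2, seed=42)
        labels = cc.agglomerative_on_embedding(cc.umap_embed(fps, cfg), 2).labels
        assert adjusted_rand_score(fps.labels_true, labels) >= 0.9


class TestAgglomerativeOnEmbedding:
    def _blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, (20, 2))
        b = rng.normal(8, 0.3, (20, 2))
        return np.vstack([a, b])

    def test_k_extremes(self):
        pts = self._blobs()
        assert cc.agglomerative_on_embedding(pts, 1).n_clusters == 1
        assert cc.agglomerative_on_embedding(pts, len(pts)).n_clusters == len(pts)

    def test_separated_blobs_recovered_exactly(self):
        pts = self._blobs()
        labels = cc.agglomerative_on_embedding(pts, 2).labels
        truth = np.array([0] * 20 + [1] * 20)
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_matches_sklearn_agglomerative(self):
        from sklearn.cluster import AgglomerativeClustering

        rng = np.random.default_rng(3)
        pts = rng.random((40, 2))
        for k in (2, 4, 6):
            mine = cc.agglomerative_on_embedding(pts, k).labels
            ref = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(pts)
            assert adjusted_rand_score(mine, ref) == pytest.approx(1.0)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            cc.agglomerative_on_embedding(self._blobs(), 99)
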