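import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tractembed import (BundleEmbedding, bundle_distance_matrix, classify_topk,
                        cluster_kmeans, flag_outlier_streamlines,
                        hierarchical_dissect, latent_distance, project_2d,
                        query_by_distance, topk_accuracy)


def _bundles(n, dim=16, seed=0):
    rng = np.random.default_rng(seed)
    return [BundleEmbedding(label=f"b{i:02d}", vector=rng.normal(size=dim), n=1)
            for i in range(n)]


class TestLatentDistance:
    def test_identity_and_pythagoras(self):
        v = np.array([1.0, 2.0])
        assert latent_distance(v, v) == 0.0
        assert latent_distance(np.zeros(2), np.array([3.0, 4.0])) == 5.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=128), rng.normal(size=128)
        brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        assert latent_distance(a, b) == pytest.approx(brute, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            latent_distance(np.zeros(3), np.zeros(4))

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 8))
            assert latent_distance(a, b) >= 0
            assert latent_distance(a, b) == pytest.approx(latent_distance(b, a))
            assert latent_distance(a, c) <= latent_distance(a, b) + latent_distance(b, c) + 1e-12


class TestClassifyTopk:
    def test_exact_match_ranks_first_with_zero_distance(self):
        bundles = _bundles(5)
        res = classify_topk(bundles[3].vector, bundles, k=2)
        assert res.ranked_labels[0] == "b03"
        assert res.distances[0] == 0.0

    def test_full_ranking_sorted_and_matches_brute_force(self):
        bundles = _bundles(25, seed=3)
        rng = np.random.default_rng(4)
        v = rng.normal(size=16)
        res = classify_topk(v, bundles, k=25)
        assert all(res.distances[i] <= res.distances[i + 1] for i in range(24))
        brute = sorted(range(25), key=lambda i: (np.linalg.norm(v - bundles[i].vector), i))
        assert list(res.ranked_labels) == [bundles[i].label for i in brute]

    def test_tie_break_prefers_earlier_bundle(self):
        v = np.ones(4)
        dup = [BundleEmbedding("z_first", np.zeros(4), 1),
               BundleEmbedding("a_second", np.zeros(4), 1)]
        res = classify_topk(v, dup, k=2)
        assert res.ranked_labels == ("z_first", "a_second")

    def test_bounds(self):
        with pytest.raises(ValueError):
            classify_topk(np.zeros(16), _bundles(3), k=4)
        with pytest.raises(ValueError):
            classify_topk(np.zeros(16), [], k=1)


class TestTopkAccuracy:
    def _results(self, ranks):
        # place the true label at the given 1-based rank for each item
        out = []
        for i, r in enumerate(ranks):
            labels = [f"wrong{j}" for j in range(10)]
            labels.insert(r - 1, "true")
            out.append(type("R", (), {"streamline_id": i,
                                      "ranked_labels": tuple(labels[:10]),
                                      "distances": tuple(range(10))})())
        return out, {i: "true" for i in range(len(ranks))}

    def test_all_correct(self):
        res, truth = self._results([1, 1, 1])
        assert topk_accuracy(res, truth, [1, 3, 5]) == {1: 1.0, 3: 1.0, 5: 1.0}

    def test_hand_tallied_ranks(self):
        # ranks 1,2,6,3,1,9,4,1,2,5: three at rank 1; six within 3; eight within 5
        res, truth = self._results([1, 2, 6, 3, 1, 9, 4, 1, 2, 5])
        acc = topk_accuracy(res, truth, [1, 3, 5])
        assert acc == {1: 0.3, 3: 0.6, 5: 0.8}

    def test_monotone_in_k(self):
        res, truth = self._results([1, 4, 7, 2, 9])
        acc = topk_accuracy(res, truth, [1, 2, 3, 5, 8])
        vals = [acc[k] for k in sorted(acc)]
        assert vals == sorted(vals)

    def test_missing_truth_rejected(self):
        res, truth = self._results([1, 2])
        del truth[1]
        with pytest.raises(KeyError):
            topk_accuracy(res, truth, [1])


class TestQuery:
    def _pool(self, n=50, seed=5):
        rng = np.random.default_rng(seed)
        return {i: rng.normal(size=8) for i in range(n)}

    def test_zero_threshold_returns_the_seed(self):
        pool = self._pool()
        hits = query_by_distance(pool[7], pool, 0.0)
        assert 7 in hits

    def test_max_threshold_returns_everything(self):
        pool = self._pool()
        dmax = max(np.linalg.norm(pool[0] - v) for v in pool.values())
        assert query_by_distance(pool[0], pool, dmax) == set(pool)

    def test_result_sets_nested_in_threshold(self):
        pool = self._pool(200, seed=6)
        seed_vec = pool[0]
        sets = [query_by_distance(seed_vec, pool, t) for t in (0.5, 1.0, 2.0, 4.0, 8.0)]
        for small, big in zip(sets, sets[1:]):
            assert small <= big
        # brute-force check of one threshold
        brute = {i for i, v in pool.items() if np.linalg.norm(seed_vec - v) <= 2.0}
        assert sets[2] == brute

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            query_by_distance(np.zeros(2), {}, -0.1)


class TestKMeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(7)
        a = {i: rng.normal(size=8) for i in range(40)}
        b = {100 + i: rng.normal(size=8) + 50 for i in range(40)}
        assign = cluster_kmeans({**a, **b}, 2, seed=0)
        truth = [0] * 40 + [1] * 40
        pred = [assign[i] for i in sorted({**a, **b})]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_k_equals_n_zero_variance(self):
        rng = np.random.default_rng(8)
        vecs = {i: rng.normal(size=4) * 10 for i in range(6)}
        assign = cluster_kmeans(vecs, 6, seed=0)
        assert len(set(assign.values())) == 6

    def test_duplicates_co_cluster(self):
        v = np.ones(4)
        vecs = {0: v, 1: v.copy(), 2: v + 30, 3: v + 30.0001}
        assign = cluster_kmeans(vecs, 2, seed=0)
        assert assign[0] == assign[1] and assign[2] == assign[3]

    def test_invalid_k(self):
        vecs = {i: np.zeros(2) + i for i in range(3)}
        with pytest.raises(ValueError):
            cluster_kmeans(vecs, 4)
        with pytest.raises(ValueError):
            cluster_kmeans(vecs, 1)


class TestHierarchicalDissect:
    def _vecs(self, n=80, seed=9):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=60, size=(8, 8))
        return {i: centers[i % 8] + rng.normal(size=8) for i in range(n)}

    def test_partition_invariant_at_every_level(self):
        tree = hierarchical_dissect(self._vecs(), branching=2, depth=3, min_leaf=2, seed=0)

        def check(node):
            if node.children:
                union = set()
                for ch in node.children:
                    assert not union & set(ch.member_ids)
                    union |= set(ch.member_ids)
                    check(ch)
                assert union == set(node.member_ids)

        check(tree)
        assert set(tree.member_ids) == set(self._vecs())
        assert len(tree.leaves()) <= 8

    def test_depth_one_equals_flat_kmeans_partition(self):
        vecs = self._vecs(seed=10)
        tree = hierarchical_dissect(vecs, branching=2, depth=1, min_leaf=1, seed=3)
        flat = cluster_kmeans(vecs, 2, seed=3)
        ids = sorted(vecs)
        tree_assign = {i: j for j, leaf in enumerate(tree.leaves()) for i in leaf.member_ids}
        assert adjusted_rand_score([flat[i] for i in ids], [tree_assign[i] for i in ids]) == 1.0

    def test_min_leaf_stops_recursion(self):
        vecs = self._vecs(16, seed=11)
        tree = hierarchical_dissect(vecs, branching=2, depth=5, min_leaf=8, seed=0)
        # 16 members < 8*2 at the children -> they stay leaves
        assert all(len(l.member_ids) >= 1 for l in tree.leaves())
        assert tree.level == 0 and all(l.level <= 2 for l in tree.leaves())

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            hierarchical_dissect({0: np.zeros(2), 1: np.ones(2)}, branching=1)
        with pytest.raises(ValueError):
            hierarchical_dissect({0: np.zeros(2), 1: np.ones(2)}, depth=0)


class TestBundleDistanceMatrix:
    def test_identical_bundles_all_zero(self):
        v = np.ones(8)
        dm = bundle_distance_matrix([BundleEmbedding("a", v, 1), BundleEmbedding("b", v.copy(), 1)])
        np.testing.assert_array_equal(dm.values, np.zeros((2, 2)))

    def test_symmetric_zero_diagonal(self):
        dm = bundle_distance_matrix(_bundles(6, seed=12))
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(dm.values), 0.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bundle_distance_matrix([BundleEmbedding("a", np.zeros(3), 1),
                                    BundleEmbedding("b", np.zeros(4), 1)])


class TestOutlierFlagging:
    def test_identical_points_unflagged(self):
        vecs = {i: np.ones(4) for i in range(20)}
        labels = {i: 0 for i in range(20)}
        assert flag_outlier_streamlines(vecs, labels, 0.9) == set()

    def test_single_far_point_flagged(self):
        rng = np.random.default_rng(13)
        vecs = {i: rng.normal(size=8) for i in range(100)}
        vecs[999] = np.full(8, 100.0)
        labels = {i: 0 for i in vecs}
        assert flag_outlier_streamlines(vecs, labels, 0.99) == {999}

    def test_flag_count_bounded_by_quantile(self):
        rng = np.random.default_rng(14)
        vecs = {i: rng.normal(size=8) for i in range(200)}
        labels = {i: i % 3 for i in vecs}
        q = 0.9
        flagged = flag_outlier_streamlines(vecs, labels, q)
        assert len(flagged) <= int(np.ceil((1 - q) * len(vecs))) + 3

    def test_singleton_cluster_never_flagged(self):
        vecs = {0: np.zeros(4), 1: np.ones(4), 2: np.ones(4) * 2}
        labels = {0: 0, 1: 1, 2: 1}
        assert 0 not in flag_outlier_streamlines(vecs, labels, 0.5)

    def test_quantile_validated(self):
        with pytest.raises(ValueError):
            flag_outlier_streamlines({0: np.zeros(2)}, {0: 0}, 1.0)


class TestProject2D:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(15)
        vecs = {i: rng.normal(size=16) for i in range(30)}
        a = project_2d(vecs, seed=0)
        b = project_2d(vecs, seed=0)
        assert all(a[i].shape == (2,) for i in vecs)
        for i in vecs:
            np.testing.assert_array_equal(a[i], b[i])

    def test_separated_groups_stay_separated_in_2d(self):
        rng = np.random.default_rng(16)
        vecs = {i: rng.normal(size=16) + (0 if i < 60 else 40) for i in range(120)}
        layout = project_2d(vecs, seed=1)
        assign = cluster_kmeans(layout, 2, seed=0)
        truth = [0 if i < 60 else 1 for i in sorted(vecs)]
        pred = [assign[i] for i in sorted(vecs)]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            project_2d({0: np.zeros(4), 1: np.ones(4)})
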