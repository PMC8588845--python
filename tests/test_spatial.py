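import numpy as np
import pytest

from segsom import spatial
from segsom.synthetic import gen_two_condition_dataset


def brute_force_interaction(centroids, classes, kernel, n_nodes):
    """O(n^2) double-loop oracle for the class-pair mean proximity matrix."""
    I = np.zeros((n_nodes, n_nodes))
    for k in range(n_nodes):
        for l in range(n_nodes):
            vals = []
            for i in np.flatnonzero(classes == k):
                for j in np.flatnonzero(classes == l):
                    if k == l and i == j:
                        continue
                    d = np.linalg.norm(centroids[i] - centroids[j])
                    vals.append(kernel(d))
            I[k, l] = np.mean(vals) if vals else 0.0
    return I


class TestProximity:
    def test_zero_separation_is_one(self):
        assert spatial.proximity((3.0, 4.0), (3.0, 4.0)) == 1.0

    def test_sigma_separation_closed_form(self):
        assert spatial.proximity((0, 0), (50, 0)) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_far_separation_vanishes(self):
        assert spatial.proximity((0, 0), (500, 0)) == pytest.approx(np.exp(-50), abs=1e-21)

    def test_exponential_variant(self):
        k = spatial.ProximityKernel(sigma=50, form="exponential")
        assert k(50.0) == pytest.approx(np.exp(-50 / 5000))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            spatial.ProximityKernel(sigma=0)


class TestInteractionMatrix:
    def test_coincident_pair_full_interaction(self):
        I = spatial.interaction_matrix(np.array([[5.0, 5.0], [5.0, 5.0]]),
                                       np.array([0, 1]), n_nodes=2)
        assert I[0, 1] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        cent = np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]])
        I = spatial.interaction_matrix(cent, np.array([0, 1, 1]), n_nodes=2)
        assert I[0, 1] == pytest.approx((np.exp(-0.5) + np.exp(-2.0)) / 2.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        cent = rng.uniform(0, 200, (n, 2))
        classes = rng.integers(0, 6, n)
        kernel = spatial.ProximityKernel()
        fast = spatial.interaction_matrix(cent, classes, kernel, 6)
        slow = brute_force_interaction(cent, classes, kernel, 6)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_symmetry_and_translation_invariance(self):
        rng = np.random.default_rng(7)
        cent = rng.uniform(0, 300, (40, 2))
        classes = rng.integers(0, 5, 40)
        I = spatial.interaction_matrix(cent, classes, n_nodes=5)
        np.testing.assert_allclose(I, I.T, atol=0)
        I_shift = spatial.interaction_matrix(cent + [123.4, -77.0], classes, n_nodes=5)
        np.testing.assert_allclose(I, I_shift, atol=1e-12)

    def test_sigma_limits(self):
        rng = np.random.default_rng(8)
        cent = rng.uniform(0, 100, (20, 2))
        classes = rng.integers(0, 3, 20)
        I_wide = spatial.interaction_matrix(cent, classes,
                                            spatial.ProximityKernel(sigma=1e9), 3)
        nonempty = np.isin(np.arange(3), classes)
        np.testing.assert_allclose(I_wide[np.ix_(nonempty, nonempty)], 1.0, atol=1e-9)
        I_narrow = spatial.interaction_matrix(cent, classes,
                                              spatial.ProximityKernel(sigma=1e-6), 3)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(I_narrow[off], 0.0, atol=1e-12)

    def test_empty_and_singleton_conventions(self):
        I = spatial.interaction_matrix(np.array([[0.0, 0.0]]), np.array([2]), n_nodes=4)
        assert I[2, 2] == 0.0  # singleton diagonal
        assert I[0, 1] == 0.0  # empty classes


class TestFlattening:
    def test_two_by_two(self):
        I = np.array([[1.0, 2.0], [2.0, 3.0]])
        np.testing.assert_array_equal(spatial.flatten_interactions(I), [1, 2, 3])

    def test_default_grid_length(self):
        v = spatial.flatten_interactions(np.zeros((49, 49)))
        assert v.shape == (1225,)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        A = rng.random((7, 7))
        I = (A + A.T) / 2
        np.testing.assert_allclose(
            spatial.unflatten_interactions(spatial.flatten_interactions(I)), I)

    def test_asymmetric_input_rejected(self):
        I = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            spatial.flatten_interactions(I)


class TestNMF:
    def test_rank_one_matrix_exactly_recovered(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, 1.0, 0.25, 2.0, 1.5])
        X = np.outer(u, v)
        basis, loadings = spatial.fit_nmf(X, k=1, seed=0)
        np.testing.assert_allclose(loadings @ basis, X, atol=1e-6)

    def test_factors_nonnegative(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 15))
        basis, loadings = spatial.fit_nmf(X, k=4, seed=0)
        assert basis.min() >= 0 and loadings.min() >= 0

    def test_three_archetype_mixture_reconstructed(self):
        rng = np.random.default_rng(0)
        archetypes = rng.random((3, 60))
        weights = rng.random((200, 3))
        X = weights @ archetypes
        basis, loadings = spatial.fit_nmf(X, k=3, seed=0)
        recon = loadings @ basis
        ss_res = ((X - recon) ** 2).sum()
        ss_tot = ((X - X.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot > 0.95

    def test_negative_entries_rejected_and_k_clamped(self):
        with pytest.raises(ValueError):
            spatial.fit_nmf(np.array([[-1.0, 2.0]]), k=1)
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning):
            basis, _ = spatial.fit_nmf(rng.random((5, 8)), k=10, seed=0)
        assert basis.shape[0] == 5


class TestSelection:
    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, 10))
        X[:, 3] = y * 3.0 + rng.normal(0, 0.3, n)
        sel = spatial.select_l1(X, y, n_selected=5, seed=0)
        assert sel[0] == 3

    def test_returns_exactly_five_by_default(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        sel = spatial.select_l1(rng.random((40, 12)), y, seed=0)
        assert len(sel) == 5

    def test_extreme_penalty_falls_back_with_warning(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 15)
        with pytest.warns(UserWarning):
            sel = spatial.select_l1(rng.normal(0, 1e-8, (30, 8)), y,
                                    l1_weight=1e6, seed=0)
        np.testing.assert_array_equal(sel, np.arange(5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            spatial.select_l1(np.random.default_rng(0).random((10, 4)),
                              np.zeros(10))


class TestClassifyCV:
    def test_deterministic_label_gives_near_perfect_auc(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 8))
        y = (X[:, 2] > 0.5).astype(int)
        X[:, 2] += 0.3 * y  # margin at the decision boundary
        res = spatial.classify_cv(X, y, folds=5, iterations=5, seed=0)
        assert res.auc.mean() > 0.99

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 8))
        y = rng.permutation(np.repeat([0, 1], 30))
        res = spatial.classify_cv(X, y, folds=5, iterations=20, seed=0)
        assert 0.4 <= res.auc.mean() <= 0.6

    def test_f1_is_harmonic_mean_of_reported_precision_recall(self):
        rng = np.random.default_rng(3)
        X = rng.random((40, 6))
        y = (X[:, 0] + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        res = spatial.classify_cv(X, y, folds=5, iterations=10, seed=1)
        for p, r, f in zip(res.precision, res.recall, res.f1):
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert f == pytest.approx(expected, abs=1e-9)

    def test_seeded_repeatability(self):
        rng = np.random.default_rng(4)
        X = rng.random((40, 6))
        y = np.repeat([0, 1], 20)
        a = spatial.classify_cv(X, y, folds=5, iterations=3, seed=9)
        b = spatial.classify_cv(X, y, folds=5, iterations=3, seed=9)
        np.testing.assert_array_equal(a.auc, b.auc)


class TestFeatureOnGrid:
    def test_single_pair_highlights_two_nodes(self):
        v = np.zeros(10)  # 4-node triangle length 10
        iu = np.triu_indices(4)
        idx = int(np.flatnonzero((iu[0] == 1) & (iu[1] == 3))[0])
        v[idx] = 2.0
        scores, pair = spatial.feature_on_grid(v)
        assert set(np.flatnonzero(scores > 0)) == {1, 3}
        assert pair[1, 3] == 1.0 and pair[3, 1] == 1.0

    def test_uniform_component_equal_scores(self):
        scores, _ = spatial.feature_on_grid(np.ones(spatial.np.triu_indices(5)[0].size))
        np.testing.assert_allclose(scores, scores[0])

    def test_node_scores_match_counting_oracle(self):
        rng = np.random.default_rng(0)
        W = rng.random((6, 6))
        I = (W + W.T) / 2
        scores, _ = spatial.feature_on_grid(spatial.flatten_interactions(I))
        oracle = I.sum(axis=1)
        np.testing.assert_allclose(scores, oracle / oracle.max(), atol=1e-12)


class TestPlantedSignalEndToEnd:
    def test_planted_pair_recovered_with_high_auc(self):
        images, labels = gen_two_condition_dataset(n_per_arm=(20, 20), seed=0)
        feats = np.stack([spatial.flatten_interactions(
            spatial.interaction_matrix(im["centroids"], im["nodes"], n_nodes=49))
            for im in images])
        with pytest.warns(UserWarning):  # k clamped to n_images
            basis, loadings = spatial.fit_nmf(feats, k=100, seed=0)
        res = spatial.classify_cv(loadings, labels, folds=5, iterations=10, seed=0)
        assert res.auc.mean() >= 0.9
        # the most-selected component loads on the planted pair (10, 30)
        counts = np.zeros(basis.shape[0])
        for sel in res.selected:
            counts[np.asarray(sel)] += 1
        top = np.argsort(-counts, kind="stable")[:5]
        iu = np.triu_indices(49)
        pair_idx = int(np.flatnonzero((iu[0] == 10) & (iu[1] == 30))[0])
        assert any(pair_idx in np.argsort(-basis[f])[:10] for f in top)
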