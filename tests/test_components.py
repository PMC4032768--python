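import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metaclust.components import (
    DISTANCE_TOKENS,
    EVALUATE_TOKENS,
    compute_distance,
    initialize_representatives,
    internal_score,
    pairwise_distances,
    update_representatives,
)

finite_vectors = arrays(
    np.float64,
    st.integers(2, 8),
    elements=st.floats(-50, 50, allow_nan=False, width=32),
)


class TestDistances:
    @pytest.mark.parametrize(
        "x, y, kind, expected",
        [
            ((0, 0), (3, 4), "EUCLIDEAN", 5.0),
            ((1, 2), (4, 6), "CITY", 7.0),
            ((1, 2, 4), (1, 2, 4), "CORREL", 0.0),
            ((1, 0), (0, 1), "COSINE", 1.0),
        ],
    )
    def test_hand_values(self, x, y, kind, expected):
        assert compute_distance(x, y, kind) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_distance([1, 2], [1, 2, 3], "EUCLIDEAN")

    def test_degenerate_vectors_map_to_one(self):
        assert compute_distance([2, 2, 2], [1, 5, 9], "CORREL") == 1.0
        assert compute_distance([0, 0], [1, 1], "COSINE") == 1.0

    @given(x=finite_vectors.filter(lambda v: len(set(v.tolist())) > 1))
    def test_zero_on_self_and_symmetry(self, x):
        for kind in DISTANCE_TOKENS:
            assert compute_distance(x, x, kind) == pytest.approx(0.0, abs=1e-9)
            y = x[::-1].copy()
            assert compute_distance(x, y, kind) == pytest.approx(
                compute_distance(y, x, kind), abs=1e-12
            )

    @given(
        data=arrays(np.float64, (3, 5), elements=st.floats(-20, 20, allow_nan=False, width=32))
    )
    def test_metric_axioms_for_euclidean_and_city(self, data):
        x, y, z = data
        for kind in ("EUCLIDEAN", "CITY"):
            dxy = compute_distance(x, y, kind)
            dyz = compute_distance(y, z, kind)
            dxz = compute_distance(x, z, kind)
            assert dxz <= dxy + dyz + 1e-9

    @given(x=finite_vectors, y=finite_vectors)
    def test_correlation_and_cosine_bounded_by_two(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        for kind in ("CORREL", "COSINE"):
            assert 0.0 <= compute_distance(x, y, kind) <= 2.0 + 1e-12


class TestInitializers:
    def test_random_with_k_equal_n_is_a_permutation_of_rows(self, blobs):
        x = blobs.values
        centers = initialize_representatives(x, x.shape[0], "RANDOM", "EUCLIDEAN", seed=3)
        assert sorted(map(tuple, centers)) == sorted(map(tuple, x))

    def test_kmeanspp_d2_sampling_always_selects_lone_outlier(self):
        x = np.vstack([np.zeros((10, 2)), [[100.0, 100.0]]])
        hits = sum(
            any(np.allclose(c, [100, 100]) for c in
                initialize_representatives(x, 2, "KMEANS++", "EUCLIDEAN", seed=s))
            for s in range(200)
        )
        # D^2 weights make the outlier a certain pick whichever point seeds
        assert hits >= 199

    def test_diana_splinter_split_on_two_blobs(self):
        x = np.array([[0.0], [0.1], [0.2], [10.0], [10.1]])
        centers = initialize_representatives(x, 2, "DIANA", "EUCLIDEAN")
        assert sorted(centers.ravel().tolist()) == pytest.approx([0.1, 10.05])

    @pytest.mark.parametrize("kind", ["DIANA", "RANDOM", "XMEANS", "GMEANS", "PCA", "KMEANS++", "SPSS"])
    def test_shape_determinism_and_finiteness(self, blobs, kind):
        x = blobs.values
        a = initialize_representatives(x, 4, kind, "EUCLIDEAN", seed=7)
        b = initialize_representatives(x, 4, kind, "EUCLIDEAN", seed=7)
        assert a.shape == (4, x.shape[1])
        assert np.isfinite(a).all()
        np.testing.assert_array_equal(a, b)

    def test_k_bounds_rejected(self, blobs):
        with pytest.raises(ValueError):
            initialize_representatives(blobs.values, 1, "RANDOM", "EUCLIDEAN")
        with pytest.raises(ValueError):
            initialize_representatives(blobs.values, blobs.n_instances + 1, "RANDOM", "EUCLIDEAN")

    def test_unknown_token_named(self, blobs):
        with pytest.raises(ValueError, match="FOO"):
            initialize_representatives(blobs.values, 2, "FOO", "EUCLIDEAN")


class TestUpdates:
    def test_mean_update(self):
        x = np.array([[0.0, 0.0], [2.0, 2.0]])
        out = update_representatives(x, [0, 0], np.zeros((1, 2)), "MEAN", "EUCLIDEAN")
        np.testing.assert_allclose(out[0], [1.0, 1.0])

    def test_median_is_robust_to_one_extreme_point(self):
        x = np.array([[0.0], [1.0], [100.0]])
        out = update_representatives(x, [0, 0, 0], np.zeros((1, 1)), "MEDIAN", "EUCLIDEAN")
        assert out[0, 0] == 1.0

    def test_online_single_point_halves_the_gap(self):
        out = update_representatives(
            np.array([[4.0]]), [0], np.array([[0.0]]), "ONLINE", "EUCLIDEAN", seed=0
        )
        assert out[0, 0] == pytest.approx(2.0)

    def test_online_pass_is_running_mean_including_prior_center(self, rng):
        x = rng.normal(size=(7, 3))
        prev = rng.normal(size=(1, 3))
        out = update_representatives(x, np.zeros(7, dtype=int), prev, "ONLINE", "EUCLIDEAN", seed=9)
        expected = np.vstack([prev, x]).mean(axis=0)  # order-free for a single cluster
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_empty_cluster_keeps_previous_center(self):
        x = np.array([[1.0], [2.0]])
        prev = np.array([[0.0], [50.0]])
        out = update_representatives(x, [0, 0], prev, "MEAN", "EUCLIDEAN")
        assert out[1, 0] == 50.0

    def test_out_of_range_cluster_index_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            update_representatives(np.ones((2, 1)), [0, 5], np.ones((2, 1)), "MEAN", "EUCLIDEAN")


class TestInternalScores:
    def test_compact_zero_when_instances_sit_on_representatives(self):
        x = np.array([[0.0, 0.0], [5.0, 5.0]])
        score, orient = internal_score(x, [0, 1], x.copy(), "COMPACT", "EUCLIDEAN")
        assert score == 0.0 and orient == "lower_better"

    def test_connectivity_zero_without_neighbourhood_violations(self, blobs):
        labels = np.unique(blobs.true_labels, return_inverse=True)[1]
        centers = np.vstack([blobs.values[labels == c].mean(axis=0) for c in range(3)])
        score, _ = internal_score(blobs.values, labels, centers, "CONN", "EUCLIDEAN")
        assert score == 0.0

    def test_silhouette_matches_hand_enumeration(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        reps = np.array([[0.05], [10.05]])
        # s(i) enumerated from the 6 pairwise distances
        expected = np.mean([
            (10.05 - 0.1) / 10.05, (9.95 - 0.1) / 9.95,
            (9.95 - 0.1) / 9.95, (10.05 - 0.1) / 10.05,
        ])
        score, orient = internal_score(x, labels, reps, "SILHOU", "EUCLIDEAN")
        assert orient == "higher_better"
        assert score == pytest.approx(expected, abs=1e-12)

    def test_silhouette_matches_sklearn_on_random_partitions(self, rng):
        from sklearn.metrics import silhouette_score

        x = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, size=30)
        reps = np.vstack([x[labels == c].mean(axis=0) for c in range(3)])
        ours, _ = internal_score(x, labels, reps, "SILHOU", "EUCLIDEAN")
        assert ours == pytest.approx(silhouette_score(x, labels), abs=1e-10)

    def test_xie_beni_closed_arithmetic(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        reps = np.array([[0.05], [10.05]])
        expected = (4 * 0.05**2) / (4 * 10.0**2)
        score, _ = internal_score(x, labels, reps, "XB", "EUCLIDEAN")
        assert score == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("kind", ["SILHOU", "XB"])
    def test_single_cluster_undefined(self, blobs, kind):
        reps = blobs.values.mean(axis=0, keepdims=True)
        with pytest.raises(ValueError, match="single cluster"):
            internal_score(blobs.values, np.zeros(blobs.n_instances, dtype=int), reps, kind, "EUCLIDEAN")

    def test_bic_exceeds_aic_for_n_at_least_8(self, rng):
        # penalty p*ln(n) > 2p as soon as ln n > 2
        x = rng.normal(size=(8, 3))
        labels = rng.integers(0, 2, size=8)
        labels[:2] = [0, 1]
        reps = np.vstack([x[labels == c].mean(axis=0) for c in range(2)])
        aic, _ = internal_score(x, labels, reps, "AIC", "EUCLIDEAN")
        bic, _ = internal_score(x, labels, reps, "BIC", "EUCLIDEAN")
        assert bic > aic

    @pytest.mark.parametrize("kind", EVALUATE_TOKENS)
    def test_invariance_to_cluster_id_permutation(self, rng, kind):
        x = rng.normal(size=(25, 4))
        labels = rng.integers(0, 3, size=25)
        labels[:3] = [0, 1, 2]
        reps = np.vstack([x[labels == c].mean(axis=0) for c in range(3)])
        perm = np.array([2, 0, 1])
        score, _ = internal_score(x, labels, reps, kind, "CITY")
        permuted, _ = internal_score(x, perm[labels], reps[np.argsort(perm)], kind, "CITY")
        assert score == pytest.approx(permuted, rel=1e-12)


def test_pairwise_distance_matrix_agrees_with_vector_calls(rng):
    x = rng.normal(size=(6, 5))
    y = rng.normal(size=(4, 5))
    for kind in DISTANCE_TOKENS:
        mat = pairwise_distances(x, y, kind)
        for i in (0, 3):
            for j in (0, 2):
                assert mat[i, j] == pytest.approx(compute_distance(x[i], y[j], kind), abs=1e-12)
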