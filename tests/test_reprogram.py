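from collections import Counter

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from treeclass import (ReprogramConfig, nearest_neighbors, pairwise_distances,
                       reprogram_labels)


def brute_force_neighbors(coords, n):
    """Full-sort-of-distance-matrix oracle with (distance, index) ties."""
    D = cdist(coords, coords)
    out = []
    for k in range(len(coords)):
        order = sorted(
            (j for j in range(len(coords)) if j != k),
            key=lambda j: (D[k, j], j),
        )
        out.append(order[:n])
    return np.array(out)


def simulate_reprogram(coords, labels, n, order=None):
    """Independent step-by-step trace of the sequential relabeling pass."""
    neigh = brute_force_neighbors(coords, n)
    labels = list(labels)
    for k in order if order is not None else range(len(labels)):
        counts = Counter(labels[j] for j in neigh[k])
        top = max(counts.values())
        tied = {c for c, v in counts.items() if v == top}
        if len(tied) == 1:
            labels[k] = tied.pop()
        elif labels[k] in tied:
            pass  # keep current
        else:
            labels[k] = next(labels[j] for j in neigh[k] if labels[j] in tied)
    return np.array(labels)


class TestDistances:
    def test_pythagorean_triple(self):
        S = pairwise_distances(np.array([[0, 0, 0], [1, 2, 2]], dtype=float))
        assert S[0, 1] == 3.0 and S[1, 0] == 3.0

    def test_single_point(self):
        S = pairwise_distances(np.zeros((1, 3)))
        assert S.shape == (1, 1) and S[0, 0] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(-2, 2, size=(200, 3))
        S = pairwise_distances(coords)
        expected = np.zeros((200, 200))
        for i in range(200):
            for j in range(200):
                expected[i, j] = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
        np.testing.assert_allclose(S, expected, atol=1e-12)
        np.testing.assert_allclose(S, S.T)
        assert np.all(np.diag(S) == 0)

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances(np.array([[0, 0, np.inf]]))


class TestNearestNeighbors:
    def test_collinear_three_points(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0]], dtype=float)
        ni = nearest_neighbors(coords, 1)
        np.testing.assert_array_equal(ni.indices.ravel(), [1, 0, 1])

    def test_full_neighborhood_is_a_permutation(self, rng):
        coords = rng.uniform(0, 1, size=(15, 3))
        ni = nearest_neighbors(coords, 14)
        for k in range(15):
            assert sorted(ni.indices[k]) == [j for j in range(15) if j != k]

    def test_matches_full_sort_oracle_on_random_points(self, rng):
        coords = rng.uniform(0, 1, size=(300, 3))
        ni = nearest_neighbors(coords, 12)
        np.testing.assert_array_equal(ni.indices, brute_force_neighbors(coords, 12))

    def test_tie_handling_on_a_lattice(self):
        # integer lattice forces many exact distance ties
        g = np.arange(4)
        coords = np.array([[x, y, z] for x in g for y in g for z in g], float)
        ni = nearest_neighbors(coords, 12)
        np.testing.assert_array_equal(ni.indices, brute_force_neighbors(coords, 12))

    def test_kdtree_and_dense_paths_agree(self, rng):
        coords = rng.uniform(0, 1, size=(500, 3))
        dense = nearest_neighbors(coords, 12, dense_cap=10_000)
        tree = nearest_neighbors(coords, 12, dense_cap=10)
        np.testing.assert_array_equal(dense.indices, tree.indices)

    def test_oversized_n_clips_with_warning(self, rng):
        coords = rng.uniform(0, 1, size=(5, 3))
        with pytest.warns(UserWarning):
            ni = nearest_neighbors(coords, 12)
        assert ni.n_neighbors == 4


class TestReprogram:
    def test_unanimous_neighborhood_wins(self, rng):
        # one Wood point in the middle of a Leaf blob
        coords = np.vstack([np.zeros(3), rng.normal(0, 0.1, size=(12, 3))])
        labels = np.array([3] + [4] * 12)
        out, changed = reprogram_labels(coords, labels, ReprogramConfig(n_neighbors=12))
        assert out[0] == 4 and changed[0]

    def test_homogeneous_cloud_is_a_fixed_point(self, rng):
        coords = rng.uniform(0, 1, size=(40, 3))
        labels = np.full(40, 2)
        out, changed = reprogram_labels(coords, labels, ReprogramConfig())
        np.testing.assert_array_equal(out, labels)
        assert not changed.any()

    def test_two_cluster_trace_oracle_corrects_planted_mislabels(self, rng):
        # 30 points: two spatially tight clusters of 15, labels Wood vs Leaf,
        # with 3 planted wrong labels in each cluster
        c1 = rng.normal([0, 0, 0], 0.05, size=(15, 3))
        c2 = rng.normal([5, 0, 0], 0.05, size=(15, 3))
        coords = np.vstack([c1, c2])
        labels = np.array([3] * 15 + [4] * 15)
        planted = [1, 7, 12, 16, 22, 28]
        truth = labels.copy()
        labels[planted] = np.where(labels[planted] == 3, 4, 3)
        cfg = ReprogramConfig(n_neighbors=12)
        out, changed = reprogram_labels(coords, labels, cfg)
        expected = simulate_reprogram(coords, labels, 12)
        np.testing.assert_array_equal(out, expected)
        np.testing.assert_array_equal(out, truth)  # all 6 corrected
        assert set(np.flatnonzero(changed)) == set(planted)

    def test_sequential_matches_trace_on_random_clouds(self, rng):
        for _ in range(5):
            coords = rng.uniform(0, 1, size=(40, 3))
            labels = rng.integers(1, 5, size=40)
            out, _ = reprogram_labels(coords, labels, ReprogramConfig(n_neighbors=5))
            np.testing.assert_array_equal(out, simulate_reprogram(coords, labels, 5))

    def test_no_new_classes_invented(self, rng):
        for _ in range(20):
            coords = rng.uniform(0, 1, size=(30, 3))
            labels = rng.choice([2, 4], size=30)
            out, _ = reprogram_labels(coords, labels, ReprogramConfig(n_neighbors=7))
            assert set(out) <= set(labels)

    def test_frozen_mode_is_permutation_equivariant(self, rng):
        coords = rng.uniform(0, 1, size=(60, 3))
        labels = rng.integers(1, 5, size=60)
        cfg = ReprogramConfig(n_neighbors=8, update_mode="frozen")
        out, _ = reprogram_labels(coords, labels, cfg)
        perm = rng.permutation(60)
        out_perm, _ = reprogram_labels(coords[perm], labels[perm], cfg)
        np.testing.assert_array_equal(out_perm, out[perm])

    def test_pure_agreeing_neighborhoods_are_identity(self, rng):
        # two far-apart homogeneous blobs: every neighborhood pure
        c1 = rng.normal([0, 0, 0], 0.1, size=(20, 3))
        c2 = rng.normal([10, 0, 0], 0.1, size=(20, 3))
        labels = np.array([1] * 20 + [3] * 20)
        out, changed = reprogram_labels(
            np.vstack([c1, c2]), labels, ReprogramConfig(n_neighbors=12)
        )
        np.testing.assert_array_equal(out, labels)
        assert not changed.any()

    def test_frozen_uses_input_labels_only(self):
        # chain where sequential propagates a flip but frozen does not
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.2, 0, 0]])
        labels = np.array([1, 1, 2, 2])
        seq, _ = reprogram_labels(coords, labels,
                                  ReprogramConfig(n_neighbors=2))
        frz, _ = reprogram_labels(coords, labels,
                                  ReprogramConfig(n_neighbors=2, update_mode="frozen"))
        expected_frozen = simulate_frozen(coords, labels, 2)
        np.testing.assert_array_equal(frz, expected_frozen)
        np.testing.assert_array_equal(seq, simulate_reprogram(coords, labels, 2))


def simulate_frozen(coords, labels, n):
    neigh = brute_force_neighbors(coords, n)
    src = list(labels)
    out = list(labels)
    for k in range(len(labels)):
        counts = Counter(src[j] for j in neigh[k])
        top = max(counts.values())
        tied = {c for c, v in counts.items() if v == top}
        if len(tied) == 1:
            out[k] = tied.pop()
        elif src[k] in tied:
            out[k] = src[k]
        else:
            out[k] = next(src[j] for j in neigh[k] if src[j] in tied)
    return np.array(out)
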