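"""L1 k-means oracle equivalence, vectorization round-trips, and
structure-similarity ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfcstates import (
    devectorize_fc,
    kmeans_l1,
    make_state_templates,
    make_structural_connectome,
    rank_states,
    structure_similarity,
    vectorize_fc,
)


def brute_force_kmedians(points: np.ndarray, k: int) -> float:
    """Exhaustive search over all k-partitions with median centroids.

    Independent oracle: enumerates every assignment of points to k
    (unordered) groups and returns the minimum total L1 deviation.
    """
    n = points.shape[0]
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        assign = np.asarray(assign)
        total = 0.0
        for j in range(k):
            grp = points[assign == j]
            total += np.abs(grp - np.median(grp, axis=0)).sum()
        best = min(best, total)
    return best


class TestVectorize:
    def test_pair_order_3x3(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        np.testing.assert_array_equal(vectorize_fc(m), [1.0, 2.0, 3.0])

    def test_feature_count_82_rois(self):
        z = np.zeros((2, 82, 82))
        assert vectorize_fc(z).shape == (2, 3321)

    @given(st.integers(0, 2**31 - 1), st.integers(3, 12))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_identity(self, seed, n):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        np.testing.assert_allclose(devectorize_fc(vectorize_fc(m), n), m)


class TestKMeansL1:
    def test_repeated_distinct_points_zero_inertia(self):
        pts = np.array([[0.0, 0.0], [5.0, 5.0], [-3.0, 4.0]])
        x = np.repeat(pts, 4, axis=0)
        model = kmeans_l1(x, k=3, n_init=10, seed=0)
        assert model.inertia == 0.0
        assert sorted(map(tuple, model.centroids.tolist())) == sorted(
            map(tuple, pts.tolist())
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_inertia_matches_exhaustive_partition_optimum(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 2))
        model = kmeans_l1(x, k=2, n_init=40, seed=seed)
        assert np.isclose(model.inertia, brute_force_kmedians(x, 2), rtol=1e-10)

    def test_three_cluster_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(9, 3))
        model = kmeans_l1(x, k=3, n_init=60, seed=7)
        assert np.isclose(model.inertia, brute_force_kmedians(x, 3), rtol=1e-10)

    def test_labels_one_based_and_sized(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 4))
        model = kmeans_l1(x, k=5, n_init=5, seed=1)
        assert model.labels.min() >= 1 and model.labels.max() <= 5
        assert np.all(np.bincount(model.labels - 1, minlength=5) > 0)

    def test_determinism_and_argument_errors(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 3))
        a = kmeans_l1(x, k=4, n_init=3, seed=9)
        b = kmeans_l1(x, k=4, n_init=3, seed=9)
        assert a.inertia == b.inertia
        assert np.array_equal(a.labels, b.labels)
        with pytest.raises(ValueError, match="at least"):
            kmeans_l1(x[:3], k=4)
        x_bad = x.copy()
        x_bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            kmeans_l1(x_bad, k=2)

    def test_pca_init_agrees_with_plusplus_on_separated_data(self):
        rng = np.random.default_rng(3)
        centers = rng.normal(scale=10, size=(3, 120))
        x = np.vstack([c + rng.normal(size=(40, 120)) for c in centers])
        a = kmeans_l1(x, k=3, n_init=10, seed=0, init="pca")
        b = kmeans_l1(x, k=3, n_init=10, seed=0, init="++")
        assert np.isclose(a.inertia, b.inertia, rtol=1e-6)


class TestStructureSimilarity:
    def test_proportional_matrix_similarity_one(self):
        sc = make_structural_connectome(20, 0.5, seed=0)
        assert np.isclose(structure_similarity(3.0 * sc.weights, sc), 1.0)

    def test_sign_scrambled_structure_near_zero(self):
        sc = make_structural_connectome(60, 0.5, seed=1)
        rng = np.random.default_rng(2)
        iu = np.triu_indices(60, 1)
        scram = np.zeros((60, 60))
        scram[iu] = sc.weights[iu] * rng.choice([-1, 1], size=iu[0].size)
        scram += scram.T
        assert abs(structure_similarity(scram, sc)) < 0.1

    def test_constant_matrix_warns_zero(self):
        sc = make_structural_connectome(10, 0.5, seed=3)
        with pytest.warns(UserWarning, match="constant"):
            assert structure_similarity(np.ones((10, 10)), sc) == 0.0

    def test_template_similarity_monotone_in_mixing(self):
        sc = make_structural_connectome(30, 0.4, seed=4)
        templates = make_state_templates(sc, 5, seed=5)
        sims = [structure_similarity(t.covariance, sc) for t in templates]
        assert np.all(np.diff(sims) > 0)


class TestRankStates:
    @staticmethod
    def _fit(sc, x, index, k, seed=0):
        model = kmeans_l1(x, k=k, n_init=10, seed=seed)
        return model, rank_states(model, sc, index)

    def test_similarity_nondecreasing_and_partition_preserved(self):
        sc = make_structural_connectome(12, 0.6, seed=0)
        rng = np.random.default_rng(1)
        # windows drawn near three synthetic patterns
        base = [rng.normal(size=(12, 12)) for _ in range(3)]
        mats = []
        for b in base:
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            for _ in range(15):
                n = rng.normal(scale=0.05, size=(12, 12))
                mats.append(b + (n + n.T) / 2)
        z = np.stack(mats)
        x = vectorize_fc(z)
        index = [("a", "s1", 25), ("b", "s2", 20)]
        model, ranked = self._fit(sc, x, index, k=3)
        assert np.all(np.diff(ranked.similarity) >= 0)
        # relabeling is a permutation: same multiset of cluster sizes
        sizes_raw = sorted(np.bincount(model.labels - 1, minlength=3))
        seqs = np.concatenate(
            [ranked.label_sequences[("a", "s1")], ranked.label_sequences[("b", "s2")]]
        )
        assert sorted(np.bincount(seqs - 1, minlength=3)) == sizes_raw
        assert ranked.label_sequences[("a", "s1")].size == 25

    def test_k_equals_one_trivially_ranked(self):
        sc = make_structural_connectome(8, 0.6, seed=2)
        rng = np.random.default_rng(3)
        z = rng.normal(size=(6, 8, 8))
        z = (z + z.transpose(0, 2, 1)) / 2
        x = vectorize_fc(z)
        model = kmeans_l1(x, k=1, n_init=2, seed=0)
        ranked = rank_states(model, sc, [("c", "s", 6)])
        assert ranked.k == 1
        assert np.all(ranked.label_sequences[("c", "s")] == 1)

    def test_index_mismatch_rejected(self):
        sc = make_structural_connectome(8, 0.6, seed=2)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 28))
        model = kmeans_l1(x, k=2, n_init=2, seed=0)
        with pytest.raises(ValueError, match="window count"):
            rank_states(model, sc, [("c", "s", 7)])
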