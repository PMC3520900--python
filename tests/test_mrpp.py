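import math

import numpy as np
import pytest

from cladebin.formats_io import BINARY, MISSING, MorphMatrix
from cladebin.mrpp import (
    CORRELATION,
    EUCLIDEAN,
    DistanceMatrix,
    mrpp_delta,
    mrpp_exact,
    mrpp_test,
    pairwise_distances,
)


def binary_matrix(taxa, rows):
    return MorphMatrix(
        taxa=list(taxa),
        characters=[f"c{i}" for i in range(len(rows[0]))],
        states=np.array(rows, dtype=np.int16),
        kinds=[BINARY] * len(rows[0]),
    )


def random_distance_matrix(n, rng):
    X = rng.random((n, 3))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"t{i}" for i in range(n)], D, EUCLIDEAN)


class TestPairwiseDistances:
    def test_hand_computed_example(self):
        m = binary_matrix("AB", [[0, 0, 1], [1, 1, 0]])
        assert pairwise_distances(m, EUCLIDEAN).values[0, 1] == pytest.approx(
            math.sqrt(3)
        )
        assert pairwise_distances(m, CORRELATION).values[0, 1] == pytest.approx(
            2.0
        )

    def test_identical_rows_have_zero_distance(self):
        m = binary_matrix("AB", [[0, 0, 1], [0, 0, 1]])
        for metric in (EUCLIDEAN, CORRELATION):
            assert pairwise_distances(m, metric).values[0, 1] == 0.0

    def test_missing_cells_rescale_euclidean(self):
        m = binary_matrix("AB", [[0, MISSING, 1], [1, 1, 0]])
        # 2 shared characters, both differing: sqrt(2 * 3/2)
        assert pairwise_distances(m, EUCLIDEAN).values[0, 1] == pytest.approx(
            math.sqrt(3)
        )

    def test_zero_variance_profile_gets_r_zero(self):
        m = binary_matrix("AB", [[1, 1, 1], [0, 1, 0]])
        assert pairwise_distances(m, CORRELATION).values[0, 1] == 1.0

    def test_symmetric_zero_diagonal(self, rng):
        for _ in range(10):
            states = rng.integers(0, 2, size=(6, 8)).astype(np.int16)
            m = binary_matrix([f"t{i}" for i in range(6)], states.tolist())
            D = pairwise_distances(m, EUCLIDEAN)
            assert np.allclose(D.values, D.values.T)
            assert np.all(np.diag(D.values) == 0)

    def test_too_few_shared_characters_rejected(self):
        m = binary_matrix(
            "AB", [[0, MISSING, MISSING], [1, 1, 0]]
        )
        with pytest.raises(ValueError, match="correlation"):
            pairwise_distances(m, CORRELATION)


class TestDelta:
    def test_identical_points_give_zero(self):
        D = DistanceMatrix(list("ABCD"), np.zeros((4, 4)), EUCLIDEAN)
        groups = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        assert mrpp_delta(D, groups) == 0.0

    def test_constant_distances_force_delta(self):
        vals = np.full((6, 6), 2.5)
        np.fill_diagonal(vals, 0.0)
        D = DistanceMatrix([f"t{i}" for i in range(6)], vals, EUCLIDEAN)
        groups = {f"t{i}": ("a" if i < 3 else "b") for i in range(6)}
        assert mrpp_delta(D, groups) == pytest.approx(2.5)

    def test_matches_direct_recomputation(self, rng):
        D = random_distance_matrix(6, rng)
        groups = {f"t{i}": ("a" if i < 3 else "b") for i in range(6)}
        xi_a = np.mean([D.values[i, j] for i in range(3) for j in range(3) if i < j])
        xi_b = np.mean([D.values[i, j] for i in range(3, 6) for j in range(3, 6) if i < j])
        assert mrpp_delta(D, groups) == pytest.approx(0.5 * xi_a + 0.5 * xi_b)

    def test_invariant_to_relabeling(self, rng):
        D = random_distance_matrix(8, rng)
        g1 = {f"t{i}": ("x" if i % 2 else "y") for i in range(8)}
        g2 = {f"t{i}": ("north" if i % 2 else "south") for i in range(8)}
        assert mrpp_delta(D, g1) == pytest.approx(mrpp_delta(D, g2))

    def test_singleton_group_rejected(self, rng):
        D = random_distance_matrix(5, rng)
        groups = {"t0": "a", "t1": "a", "t2": "a", "t3": "a", "t4": "b"}
        with pytest.raises(ValueError, match="fewer than 2"):
            mrpp_delta(D, groups)


class TestExact:
    def test_enumerates_all_assignments(self, rng):
        D = random_distance_matrix(6, rng)
        groups = {f"t{i}": ("a" if i < 3 else "b") for i in range(6)}
        assert mrpp_exact(D, groups).n_perm == 20  # C(6,3)

    def test_unique_minimum_has_smallest_p(self):
        # two tight clusters far apart: the observed split is the unique
        # delta minimiser among all C(6,3)=20 assignments
        X = np.array([0.0, 0.01, 0.02, 10.0, 10.01, 10.02])
        D = np.abs(X[:, None] - X[None, :])
        dist = DistanceMatrix([f"t{i}" for i in range(6)], D, EUCLIDEAN)
        groups = {f"t{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = mrpp_exact(dist, groups)
        assert res.p_value == pytest.approx(2 / 20)  # observed + its mirror
        assert res.A > 0

    def test_combinatorial_bound_enforced(self, rng):
        D = random_distance_matrix(30, rng)
        groups = {f"t{i}": ("a" if i < 15 else "b") for i in range(30)}
        with pytest.raises(ValueError, match="mrpp_test"):
            mrpp_exact(D, groups)


class TestPermutationTest:
    def test_converges_to_exact_p(self, rng):
        """Monte-Carlo p within 3 MC standard errors of enumeration."""
        for _ in range(5):
            D = random_distance_matrix(8, rng)
            groups = {f"t{i}": ("a" if i < 4 else "b") for i in range(8)}
            exact = mrpp_exact(D, groups)
            mc = mrpp_test(D, groups, n_perm=20000, seed=rng)
            se = math.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
            assert abs(mc.p_value - exact.p_value) <= 3 * se + 1e-4

    def test_separated_clusters_are_significant(self, rng):
        X = np.concatenate([rng.normal(0, 0.2, (10, 2)), rng.normal(5, 0.2, (10, 2))])
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        dist = DistanceMatrix([f"t{i}" for i in range(20)], D, EUCLIDEAN)
        groups = {f"t{i}": ("a" if i < 10 else "b") for i in range(20)}
        res = mrpp_test(dist, groups, n_perm=9999, seed=1)
        assert res.p_value <= 0.001
        assert res.A > 0.5

    def test_all_equal_distances_give_p_one(self):
        vals = np.full((6, 6), 1.0)
        np.fill_diagonal(vals, 0.0)
        D = DistanceMatrix([f"t{i}" for i in range(6)], vals, EUCLIDEAN)
        groups = {f"t{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = mrpp_test(D, groups, n_perm=200, seed=0)
        assert res.p_value == 1.0
        assert res.A == pytest.approx(0.0, abs=1e-12)

    def test_add_one_p_never_zero(self, rng):
        D = random_distance_matrix(10, rng)
        groups = {f"t{i}": ("a" if i < 5 else "b") for i in range(10)}
        res = mrpp_test(D, groups, n_perm=99, seed=2)
        assert 0 < res.p_value <= 1

    def test_reproducible_for_fixed_seed(self, rng):
        D = random_distance_matrix(9, rng)
        groups = {f"t{i}": ("a" if i < 4 else "b") for i in range(9)}
        a = mrpp_test(D, groups, n_perm=500, seed=11)
        b = mrpp_test(D, groups, n_perm=500, seed=11)
        assert (a.p_value, a.expected_delta, a.A) == (
            b.p_value, b.expected_delta, b.A
        )

    def test_type_one_error_is_calibrated(self):
        """Random labels on iid data: rejection rate at alpha=0.05 stays
        inside binomial 99% bounds (small screening run; the acceptance
        suite repeats this with 1000 simulations)."""
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            X = rng.random((10, 4))
            D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
            dist = DistanceMatrix([f"t{i}" for i in range(10)], D, EUCLIDEAN)
            groups = {f"t{i}": ("a" if i < 5 else "b") for i in range(10)}
            if mrpp_test(dist, groups, n_perm=199, seed=rng).p_value <= 0.05:
                rejections += 1
        rate = rejections / n_sim
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= half
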