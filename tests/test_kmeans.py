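from itertools import product

import numpy as np
import pytest

from metaclust.kmeans_clustering import (
    assign,
    choose_k,
    init_centers,
    run_kmeans,
    select_k,
    update_centers,
)
from conftest import make_matrix


def brute_force_bipartition(rows):
    """Optimal 2-cluster objective: enumerate every bipartition, mean centers."""
    rows = np.asarray(rows, dtype=float)
    n = len(rows)
    best = np.inf
    for mask_bits in range(1, 2 ** (n - 1)):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        cost = 0.0
        for side in (mask, ~mask):
            group = rows[side]
            cost += ((group - group.mean(axis=0)) ** 2).sum()
        best = min(best, cost)
    return best


class TestInitCenters:
    def test_values_within_global_range(self):
        matrix = make_matrix(np.array([[0.0, 9.0], [3.0, 5.0]]))
        centers = init_centers(matrix, 4, np.random.default_rng(0))
        assert centers.shape == (4, 2)
        assert centers.min() >= 0.0 and centers.max() <= 9.0

    def test_deterministic_given_seed(self):
        matrix = make_matrix(np.random.default_rng(1).uniform(0, 10, (5, 3)))
        a = init_centers(matrix, 3, np.random.default_rng(99))
        b = init_centers(matrix, 3, np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)

    def test_constant_matrix_degenerate_range(self):
        matrix = make_matrix(np.full((3, 4), 7.0))
        centers = init_centers(matrix, 2, np.random.default_rng(0))
        np.testing.assert_array_equal(centers, np.full((2, 4), 7.0))

    def test_k_below_one_errors(self):
        matrix = make_matrix(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            init_centers(matrix, 0, np.random.default_rng(0))


class TestAssign:
    def test_exact_match(self):
        matrix = make_matrix([[0.0, 0.0], [10.0, 10.0]])
        a, total = assign(matrix, np.array([[0.0, 0.0], [10.0, 10.0]]))
        assert a.tolist() == [0, 1]
        assert total == 0.0

    def test_single_center_closed_form(self):
        rows = np.array([[1.0, 2.0], [3.0, 4.0], [0.0, 0.0]])
        center = np.array([[2.0, 2.0]])
        a, total = assign(make_matrix(rows), center)
        assert a.tolist() == [0, 0, 0]
        assert total == pytest.approx(((rows - center) ** 2).sum())

    def test_tie_breaks_to_lowest_index(self):
        matrix = make_matrix([[5.0, 5.0]])
        a, _ = assign(matrix, np.array([[0.0, 0.0], [10.0, 10.0]]))
        assert a.tolist() == [0]

    def test_absolute_distance_mode(self):
        matrix = make_matrix([[0.0, 4.0]])
        _, total = assign(matrix, np.array([[1.0, 1.0]]), distance="absolute")
        assert total == pytest.approx(1 + 3)


class TestUpdateCenters:
    def test_mean_of_members(self):
        matrix = make_matrix([[0.0, 0.0], [2.0, 2.0], [9.0, 9.0]])
        centers = update_centers(matrix, np.array([0, 0, 1]), 2,
                                 np.random.default_rng(0))
        np.testing.assert_allclose(centers[0], [1.0, 1.0])
        np.testing.assert_allclose(centers[1], [9.0, 9.0])  # singleton

    def test_empty_cluster_reseeded_to_farthest_row(self):
        matrix = make_matrix([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]])
        centers = update_centers(matrix, np.array([0, 0, 0]), 2,
                                 np.random.default_rng(0))
        np.testing.assert_allclose(centers[1], [9.0, 9.0])
        np.testing.assert_allclose(centers[0], [0.0, 0.0])  # mean without the donor row

    def test_fallback_when_no_spare_rows(self):
        matrix = make_matrix([[2.0, 2.0]])
        centers = update_centers(matrix, np.array([0]), 2, np.random.default_rng(0))
        np.testing.assert_allclose(centers[0], [2.0, 2.0])
        np.testing.assert_allclose(centers[1], [2.0, 2.0])  # random in degenerate range


class TestRunKmeans:
    def test_k1_closed_form(self):
        rows = np.random.default_rng(3).uniform(0, 10, (6, 4))
        model = run_kmeans(make_matrix(rows), 1, np.random.default_rng(0))
        np.testing.assert_allclose(model.centers[0], rows.mean(axis=0))
        assert model.total_distance == pytest.approx(
            ((rows - rows.mean(axis=0)) ** 2).sum()
        )

    def test_identical_rows_zero_distance(self):
        rows = np.tile([1.0, 2.0, 3.0], (5, 1))
        for k in (1, 2, 3):
            model = run_kmeans(make_matrix(rows), k, np.random.default_rng(k))
            assert model.total_distance == pytest.approx(0.0)

    def test_k_above_n_errors(self):
        with pytest.raises(ValueError):
            run_kmeans(make_matrix(np.zeros((3, 2))), 4, np.random.default_rng(0))

    def test_converged_centers_are_member_means(self):
        rng = np.random.default_rng(5)
        rows = rng.uniform(0, 10, (30, 5))
        model = run_kmeans(make_matrix(rows), 3, rng)
        for c in range(model.k):
            members = rows[model.assignments == c]
            if len(members):
                np.testing.assert_allclose(model.centers[c], members.mean(axis=0),
                                           atol=1e-9)

    def test_total_distance_is_recomputable(self):
        rng = np.random.default_rng(6)
        rows = rng.uniform(0, 10, (20, 4))
        model = run_kmeans(make_matrix(rows), 3, rng)
        recomputed = sum(
            ((rows[i] - model.centers[model.assignments[i]]) ** 2).sum()
            for i in range(len(rows))
        )
        assert model.total_distance == pytest.approx(recomputed, abs=1e-9)

    def test_objective_monotone_within_run(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            rows = rng.uniform(0, 10, (25, 6))
            model = run_kmeans(make_matrix(rows), 4, rng)
            diffs = np.diff(model.objective_history)
            assert np.all(diffs <= 1e-9), model.objective_history

    def test_two_separated_groups_match_brute_force(self):
        rng = np.random.default_rng(11)
        rows = np.vstack([
            rng.uniform(0, 1, (3, 2)),
            100 + rng.uniform(0, 1, (3, 2)),
        ])
        matrix = make_matrix(rows)
        best = min(
            run_kmeans(matrix, 2, np.random.default_rng(s)).total_distance
            for s in range(50)
        )
        assert best == pytest.approx(brute_force_bipartition(rows), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        rows = rng.uniform(0, 10, (12, 3))
        perm = rng.permutation(12)
        a = run_kmeans(make_matrix(rows), 3, np.random.default_rng(42))
        b = run_kmeans(make_matrix(rows[perm], ids=[f"f{i}" for i in perm]), 3,
                       np.random.default_rng(42))
        np.testing.assert_array_equal(a.assignments[perm], b.assignments)
        np.testing.assert_allclose(a.centers, b.centers)


class TestChooseK:
    def test_forced_stopping_sequence(self):
        # 100 -> 50 is a 50% improvement, 50 -> 45 is 10% <= 20%: select k=2
        assert choose_k([100.0, 50.0, 45.0], threshold=0.20) == 2

    def test_boundary_equality_counts_as_stop(self):
        assert choose_k([100.0, 80.0], threshold=0.20) == 1

    def test_zero_first_distance(self):
        assert choose_k([0.0, 0.0]) == 1

    def test_zero_later_distance(self):
        assert choose_k([100.0, 0.0]) == 2

    def test_never_fires_returns_last(self):
        assert choose_k([100.0, 10.0, 1.0], threshold=0.20) == 3


class TestSelectK:
    def test_identical_rows_select_k1(self):
        matrix = make_matrix(np.tile([4.0, 4.0], (6, 1)))
        model, trace = select_k(matrix, rng=np.random.default_rng(0))
        assert model.k == 1
        assert trace.entries[0] == (1, 0.0, None)

    def test_trace_ks_consecutive_and_d_nonincreasing(self):
        rng = np.random.default_rng(17)
        rows = np.vstack([rng.normal(loc, 0.5, (15, 4)) for loc in (0, 10, 20)])
        model, trace = select_k(make_matrix(np.abs(rows)), rng=np.random.default_rng(2))
        ks = [k for k, _, _ in trace.entries]
        assert ks == list(range(1, len(ks) + 1))
        ds = trace.distances()
        assert all(b <= a + 1e-9 for a, b in zip(ds, ds[1:]))

    def test_three_separated_groups_select_k3(self):
        rng = np.random.default_rng(19)
        rows = np.vstack([
            np.abs(rng.normal(loc, 0.3, (20, 5))) for loc in (0.0, 10.0, 30.0)
        ])
        model, _ = select_k(make_matrix(rows), rng=np.random.default_rng(3))
        assert model.k == 3

    def test_threshold_validation(self):
        matrix = make_matrix(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            select_k(matrix, threshold=0.0)
        with pytest.raises(ValueError):
            select_k(matrix, threshold=1.0)

    def test_k_max_cap_returns_model(self):
        rng = np.random.default_rng(23)
        rows = rng.uniform(0, 100, (40, 3))  # unstructured: improvement stays high
        model, trace = select_k(make_matrix(rows), rng=np.random.default_rng(4),
                                k_max=3)
        assert model.k <= 3
        assert len(trace.entries) <= 3


class TestBruteForceOracleEquivalence:
    def test_tiny_instances(self):
        """Best-of-50-restart k-means vs exhaustive bipartition enumeration."""
        rng = np.random.default_rng(101)
        n_match = 0
        n_total = 200
        for _ in range(n_total):
            n = int(rng.integers(3, 9))
            L = int(rng.integers(1, 5))
            rows = rng.uniform(0, 10, (n, L))
            matrix = make_matrix(rows)
            optimum = brute_force_bipartition(rows)
            best = min(
                run_kmeans(matrix, 2, rng).total_distance for _ in range(50)
            )
            assert best >= optimum - 1e-9  # never beats the true optimum
            if best <= optimum + 1e-9:
                n_match += 1
        assert n_match / n_total >= 0.95
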