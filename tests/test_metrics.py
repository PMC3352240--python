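"""Clustering, event/cluster matching, and the four evaluation statistics."""

import numpy as np
import pytest

import hebbsort as h
from hebbsort.exceptions import InvalidInputError
from hebbsort.metrics import SortingResult, false_positive_rate, true_positive_rate


class TestClusterKmeans:
    def test_separated_clouds_partitioned_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(50, 2))
        b = rng.normal(5, 0.1, size=(60, 2))
        X = np.vstack([a, b])
        result = h.cluster_kmeans(X, K=2, seed=1)
        first, second = result.assignments[:50], result.assignments[50:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_k_equals_one_and_k_equals_n(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 2))
        assert len(set(h.cluster_kmeans(X, K=1, seed=0).assignments)) == 1
        res = h.cluster_kmeans(X, K=8, seed=0)
        assert len(set(res.assignments)) == 8  # inertia 0: one point per cluster

    def test_determinism_and_too_few_points(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 2))
        a = h.cluster_kmeans(X, K=3, seed=5).assignments
        b = h.cluster_kmeans(X, K=3, seed=5).assignments
        assert np.array_equal(a, b)
        with pytest.raises(InvalidInputError):
            h.cluster_kmeans(X, K=31, seed=0)


class TestMatchEvents:
    def test_identical_lists_pair_perfectly(self):
        t = np.array([10, 50, 90])
        p = h.match_events(t, h.GroundTruth(t, np.zeros(3)), tol=5)
        assert p.n_paired == 3
        assert len(p.unpaired_det) == len(p.unpaired_truth) == 0

    def test_offset_beyond_tolerance_unpaired(self):
        truth = h.GroundTruth([100], [0])
        p = h.match_events(np.array([106]), truth, tol=5)
        assert p.n_paired == 0
        p = h.match_events(np.array([105]), truth, tol=5)
        assert p.n_paired == 1

    def test_jitter_within_half_tolerance_all_paired(self):
        rng = np.random.default_rng(3)
        truth_times = np.arange(100, 5000, 100)
        jitter = rng.integers(-5, 6, size=len(truth_times))
        det = truth_times + jitter
        p = h.match_events(det, h.GroundTruth(truth_times, np.zeros(len(truth_times))), tol=10)
        assert p.n_paired == len(truth_times)

    def test_one_to_one(self):
        """Two detections near one truth spike: only one pairs."""
        truth = h.GroundTruth([100], [0])
        p = h.match_events(np.array([98, 102]), truth, tol=5)
        assert p.n_paired == 1
        assert len(p.unpaired_det) == 1


class TestMatchClusters:
    def test_aligned_labels_identity_mapping(self):
        labels = np.array([0, 0, 1, 1, 1])
        result = SortingResult(np.array([0, 0, 1, 1, 1]), K=2)
        matched = h.match_clusters(result, labels)
        assert matched.mapping == {0: 0, 1: 1}

    def test_permutation_invariance_of_tpr(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, size=200)
        assignments = labels.copy()
        flip = rng.random(200) < 0.1
        assignments[flip] = 1 - assignments[flip]
        counts = {0: int((labels == 0).sum()), 1: int((labels == 1).sum())}
        m1 = h.match_clusters(SortingResult(assignments, K=2), labels)
        m2 = h.match_clusters(SortingResult(1 - assignments, K=2), labels)
        assert true_positive_rate(m1, labels, counts) == pytest.approx(
            true_positive_rate(m2, labels, counts)
        )

    def test_surplus_cluster_left_unmapped(self):
        labels = np.array([0, 0, 0, 1, 1, 1, -1, -1])
        assignments = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        matched = h.match_clusters(SortingResult(assignments, K=3), labels)
        assert set(matched.mapping.keys()) == {0, 1}


class TestErrorMean:
    def test_zero_when_equal(self):
        assert h.error_mean([1.0, -2.0], [1.0, -2.0]) == 0.0

    def test_direct_evaluation(self):
        assert h.error_mean([1.0, 1.0], [2.0, 2.0]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        mu1, mu2 = np.array([1.0, 3.0]), np.array([2.0, 2.5])
        assert h.error_mean(3.7 * mu1, 3.7 * mu2) == pytest.approx(
            h.error_mean(mu1, mu2)
        )

    def test_zero_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            h.error_mean([1.0], [0.0])


class TestErrorPc:
    def test_parallel_and_antiparallel_are_zero(self):
        v = np.array([1.0, 2.0, -1.0])
        assert h.error_pc(v, v) == pytest.approx(0.0)
        assert h.error_pc(v, -v) == pytest.approx(0.0)
        assert h.error_pc(v, 2.5 * v) == pytest.approx(0.0)

    def test_orthogonal_is_one(self):
        assert h.error_pc([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_range_and_zero_vector(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            e = h.error_pc(rng.standard_normal(6), rng.standard_normal(6))
            assert 0.0 <= e <= 1.0
        with pytest.raises(InvalidInputError):
            h.error_pc(np.zeros(3), np.ones(3))


class TestRates:
    def test_perfect_sorting(self):
        labels = np.array([0] * 10 + [1] * 10)
        result = SortingResult(labels.copy(), K=2, mapping={0: 0, 1: 1})
        counts = {0: 10, 1: 10}
        assert true_positive_rate(result, labels, counts) == 1.0
        assert false_positive_rate(result, labels) == 0.0

    def test_tpr_worked_example(self):
        """Neuron 1: 8/10 correct; neuron 2: 15/20 -> (0.8+0.75)/2 = 0.775."""
        labels = np.array([1] * 10 + [2] * 20)
        assignments = np.concatenate([
            np.array([0] * 8 + [1] * 2),  # neuron-1 spikes
            np.array([1] * 15 + [0] * 5),  # neuron-2 spikes
        ])
        result = SortingResult(assignments, K=2, mapping={0: 1, 1: 2})
        tpr = true_positive_rate(result, labels, {1: 10, 2: 20})
        assert tpr == pytest.approx(0.775)

    def test_tpr_missed_detections_count_in_denominator(self):
        labels = np.array([1] * 8)  # only 8 of 10 spikes detected
        result = SortingResult(np.zeros(8, dtype=int), K=1, mapping={0: 1})
        assert true_positive_rate(result, labels, {1: 10}) == pytest.approx(0.8)

    def test_fpr_worked_example(self):
        """Neuron 1 receives 2 of its 20 false spikes, neuron 2 receives 5
        of its 10 -> (0.1+0.5)/2 = 0.3."""
        # 10 spikes of neuron 1, 20 of neuron 2; for neuron 1 the false pool
        # is the 20 neuron-2 spikes, for neuron 2 the 10 neuron-1 spikes.
        labels = np.array([1] * 10 + [2] * 20)
        assignments = np.concatenate([
            np.array([1] * 5 + [0] * 5),  # 5 neuron-1 spikes land in cluster 1
            np.array([0] * 2 + [1] * 18),  # 2 neuron-2 spikes land in cluster 0
        ])
        result = SortingResult(assignments, K=2, mapping={0: 1, 1: 2})
        assert false_positive_rate(result, labels) == pytest.approx(0.3)

    def test_fpr_single_cluster_takes_all(self):
        labels = np.array([1, 1, -1, -1, -1])
        result = SortingResult(np.zeros(5, dtype=int), K=1, mapping={0: 1})
        assert false_positive_rate(result, labels) == 1.0

    def test_everything_misassigned_gives_zero_tpr(self):
        labels = np.array([1] * 5 + [2] * 5)
        assignments = np.array([1] * 5 + [0] * 5)
        result = SortingResult(assignments, K=2, mapping={0: 1, 1: 2})
        assert true_positive_rate(result, labels, {1: 5, 2: 5}) == 0.0

    def test_rates_bounded(self, parity_sweeps):
        for sweep in parity_sweeps.values():
            for row in sweep:
                for r in row["runs"]:
                    assert 0.0 <= r["tpr_she"] <= 1.0
                    assert 0.0 <= r["fpr_she"] <= 1.0


class TestEvaluateSorting:
    def test_end_to_end_on_easy_data(self, short_train, detected):
        _, _, rec, truth = short_train
        n = detected.n // 2
        res = h.StreamingHebbianEigenfilter(n_mean=n, n_learn=n).fit(
            iter(detected.spikes)
        )
        sort = h.cluster_kmeans(res.project(detected), K=2, seed=0)
        out = h.evaluate_sorting(detected.event_times, sort, truth, rec.fs)
        assert out["tpr"] > 0.8
        assert out["fpr"] < 0.2
        assert out["n_paired"] <= min(out["n_detected"], out["n_truth"])
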