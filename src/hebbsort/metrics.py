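"""Clustering and the four spike-sorting evaluation statistics.

* ``error_mean`` — relative L1 discrepancy between two mean vectors,
  sum|mu1 - mu2| / sum|mu2|; quantifies how well one block's mean stands in
  for the next block's under pseudo-stationarity.
* ``error_pc`` — angular deviation between a learned weight vector and a
  reference principal component, 1 - |w_hat . pc_hat| (zero when the vectors
  are parallel or antiparallel).
* ``true_positive_rate`` / ``false_positive_rate`` — per-neuron-averaged
  fractions of correctly classified spikes and of false spikes wrongly
  assigned, computed after a one-to-one cluster-to-neuron matching.

Clustering is K-means with K fixed to the expected neuron count; event-to
-truth pairing is greedy nearest-in-time; cluster-to-neuron matching is the
Hungarian assignment maximizing correctly classified spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .core import FeatureScores, GroundTruth
from .exceptions import InvalidInputError

#: default detection/truth pairing tolerance in seconds
DEFAULT_MATCH_TOL_S = 0.0005


@dataclass
class SortingResult:
    """Cluster assignments plus an optional cluster -> neuron mapping."""

    assignments: np.ndarray  # cluster id per spike, in [0, K)
    K: int
    mapping: dict = field(default_factory=dict)  # cluster id -> neuron id

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if self.assignments.size and (
            self.assignments.min() < 0 or self.assignments.max() >= self.K
        ):
            raise InvalidInputError("cluster assignments outside [0, K)")
        if len(set(self.mapping.values())) != len(self.mapping):
            raise InvalidInputError("cluster -> neuron mapping must be injective")


@dataclass
class EventPairing:
    """One-to-one pairing between detected events and ground-truth spikes."""

    det_index: np.ndarray  # indices into the detection list
    truth_index: np.ndarray  # matching indices into the truth list
    unpaired_det: np.ndarray  # false detections
    unpaired_truth: np.ndarray  # missed spikes

    @property
    def n_paired(self) -> int:
        return len(self.det_index)


def cluster_kmeans(scores: FeatureScores | np.ndarray, K: int, seed: int = 0,
                   n_init: int = 10) -> SortingResult:
    """K-means in feature space with K fixed to the expected neuron count."""
    X = scores.scores if isinstance(scores, FeatureScores) else np.atleast_2d(np.asarray(scores))
    if K < 1:
        raise InvalidInputError("K must be >= 1")
    if X.shape[0] < K:
        raise InvalidInputError(f"cannot form K={K} clusters from {X.shape[0]} spikes")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    return SortingResult(km.fit_predict(X), K=K)


def match_events(detected_times: np.ndarray, truth: GroundTruth | np.ndarray,
                 tol: int) -> EventPairing:
    """Greedy nearest-time one-to-one pairing within ``±tol`` samples."""
    if tol < 0:
        raise InvalidInputError("tol must be >= 0")
    det = np.asarray(detected_times, dtype=np.int64)
    tru = truth.spike_times if isinstance(truth, GroundTruth) else np.asarray(truth, dtype=np.int64)
    candidates = []
    for i, td in enumerate(det):
        lo = np.searchsorted(tru, td - tol)
        hi = np.searchsorted(tru, td + tol, side="right")
        for k in range(lo, hi):
            candidates.append((abs(int(td) - int(tru[k])), i, k))
    candidates.sort()
    used_det: set[int] = set()
    used_tru: set[int] = set()
    pairs = []
    for _, i, k in candidates:
        if i in used_det or k in used_tru:
            continue
        used_det.add(i)
        used_tru.add(k)
        pairs.append((i, k))
    pairs.sort()
    det_idx = np.array([p[0] for p in pairs], dtype=np.int64)
    tru_idx = np.array([p[1] for p in pairs], dtype=np.int64)
    return EventPairing(
        det_index=det_idx,
        truth_index=tru_idx,
        unpaired_det=np.setdiff1d(np.arange(len(det)), det_idx),
        unpaired_truth=np.setdiff1d(np.arange(len(tru)), tru_idx),
    )


def match_clusters(result: SortingResult, paired_labels: np.ndarray) -> SortingResult:
    """Assign clusters to neurons maximizing total correct spikes (Hungarian).

    ``paired_labels`` gives, per detected spike, the matched truth neuron id,
    or -1 for a false detection. Surplus clusters stay unmapped.
    """
    labels = np.asarray(paired_labels, dtype=np.int64)
    if len(labels) != len(result.assignments):
        raise InvalidInputError("paired_labels must align with assignments")
    neurons = np.unique(labels[labels >= 0])
    if len(neurons) == 0:
        raise InvalidInputError("no labelled spikes to match against")
    conf = np.zeros((result.K, len(neurons)), dtype=np.int64)
    for c in range(result.K):
        for kn, neu in enumerate(neurons):
            conf[c, kn] = np.sum((result.assignments == c) & (labels == neu))
    rows, cols = linear_sum_assignment(conf, maximize=True)
    mapping = {int(c): int(neurons[k]) for c, k in zip(rows, cols)}
    return SortingResult(result.assignments, K=result.K, mapping=mapping)


def error_mean(mu1: np.ndarray, mu2: np.ndarray) -> float:
    """Relative L1 discrepancy between two mean vectors: sum|mu1-mu2|/sum|mu2|."""
    mu1 = np.asarray(mu1, dtype=np.float64)
    mu2 = np.asarray(mu2, dtype=np.float64)
    if mu1.shape != mu2.shape:
        raise InvalidInputError("mean vectors must have equal length")
    denom = np.sum(np.abs(mu2))
    if denom == 0:
        raise InvalidInputError("reference mean is identically zero")
    return float(np.sum(np.abs(mu1 - mu2)) / denom)


def error_pc(w: np.ndarray, pc: np.ndarray) -> float:
    """Deviation between directions: 1 - |w_hat . pc_hat|.

    Zero for parallel or antiparallel vectors; 1 for orthogonal ones.
    """
    w = np.asarray(w, dtype=np.float64)
    pc = np.asarray(pc, dtype=np.float64)
    nw, npc = np.linalg.norm(w), np.linalg.norm(pc)
    if nw == 0 or npc == 0:
        raise InvalidInputError("cannot compare a zero vector")
    return float(1.0 - abs(w @ pc) / (nw * npc))


def true_positive_rate(result: SortingResult, paired_labels: np.ndarray,
                       truth_counts: dict) -> float:
    """Unweighted mean over matched neurons of correct / total spikes.

    ``truth_counts`` maps neuron id -> total ground-truth spikes (missed
    detections therefore count in the denominator).
    """
    labels = np.asarray(paired_labels, dtype=np.int64)
    if not result.mapping:
        raise InvalidInputError("run match_clusters first")
    rates = []
    for c, neu in result.mapping.items():
        total = truth_counts.get(neu, 0)
        if total == 0:
            warnings.warn(f"neuron {neu} has no ground-truth spikes; excluded")
            continue
        correct = int(np.sum((result.assignments == c) & (labels == neu)))
        rates.append(correct / total)
    if not rates:
        raise InvalidInputError("no neuron with ground-truth spikes")
    return float(np.mean(rates))


def false_positive_rate(result: SortingResult, paired_labels: np.ndarray) -> float:
    """Unweighted mean over matched neurons of false-assigned / false pool.

    For neuron i the false pool is every detected spike not belonging to i
    (including unpaired false detections, label -1); the numerator counts
    those assigned to i's cluster.
    """
    labels = np.asarray(paired_labels, dtype=np.int64)
    if not result.mapping:
        raise InvalidInputError("run match_clusters first")
    rates = []
    for c, neu in result.mapping.items():
        pool = int(np.sum(labels != neu))
        if pool == 0:
            warnings.warn(f"neuron {neu}: empty false-spike pool; excluded")
            continue
        false_assigned = int(np.sum((result.assignments == c) & (labels != neu)))
        rates.append(false_assigned / pool)
    if not rates:
        raise InvalidInputError("every false pool is empty")
    return float(np.mean(rates))


def evaluate_sorting(
    detected_times: np.ndarray,
    assignments: np.ndarray | SortingResult,
    truth: GroundTruth,
    fs: float,
    tol_s: float = DEFAULT_MATCH_TOL_S,
) -> dict:
    """Pair detections with truth, match clusters, and compute TPR/FPR."""
    if isinstance(assignments, SortingResult):
        result = assignments
    else:
        assignments = np.asarray(assignments, dtype=np.int64)
        result = SortingResult(assignments, K=int(assignments.max()) + 1 if len(assignments) else 1)
    pairing = match_events(detected_times, truth, tol=int(round(tol_s * fs)))
    paired_labels = np.full(len(detected_times), -1, dtype=np.int64)
    paired_labels[pairing.det_index] = truth.labels[pairing.truth_index]
    matched = match_clusters(result, paired_labels)
    truth_counts = {int(k): int(np.sum(truth.labels == k)) for k in truth.neuron_ids}
    tpr = true_positive_rate(matched, paired_labels, truth_counts)
    fpr = false_positive_rate(matched, paired_labels)
    return {
        "tpr": tpr,
        "fpr": fpr,
        "n_detected": int(len(detected_times)),
        "n_truth": int(len(truth)),
        "n_paired": pairing.n_paired,
        "n_false_detections": int(len(pairing.unpaired_det)),
        "n_missed": int(len(pairing.unpaired_truth)),
        "mapping": {str(k): v for k, v in matched.mapping.items()},
    }
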