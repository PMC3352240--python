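"""Benchmark experiments: sorting accuracy across neuron counts and SNR.

These drive the package's headline comparisons: stream-learned features
versus reference-PCA features through the identical detect -> project ->
cluster -> evaluate pipeline, over 2/3/4-neuron synthetic trains and a grid
of noise levels.
"""

from __future__ import annotations

import numpy as np

from .detection import detect_spikes
from .eigenfilter import StreamingHebbianEigenfilter
from .metrics import cluster_kmeans, error_mean, evaluate_sorting
from .pca import covariance_pca
from .synthetic import SNR_GRID, TrainConfig, generate_train, make_templates

#: default per-neuron firing rates by neuron count: denser trains for fewer
#: neurons so every benchmark yields enough spikes for block training
DEFAULT_RATES = {1: 20.0, 2: 15.0, 3: 13.0, 4: 12.0}


def sorting_run(
    num_neurons: int,
    snr: float,
    seed: int,
    firing_rate: float | None = None,
    duration: float = 100.0,
    l: int = 2,
    n_max: int = 1024,
) -> dict:
    """One benchmark run: generate, detect, train both filters, sort, score.

    The stream eigenfilter and the covariance-PCA reference see exactly the
    same detected spikes: the first block feeds the stream's mean estimate
    (PCA trains on the second block, which is also the stream's learning
    block), and both feature sets are clustered and evaluated identically.
    Block sizes adapt to the detection yield at low SNR: n = N =
    min(n_max, floor(n_detected/2)).
    """
    rate = firing_rate if firing_rate is not None else DEFAULT_RATES[num_neurons]
    cfg = TrainConfig(
        num_neurons=num_neurons, firing_rates=rate, duration=duration,
        snr=snr, seed=seed,
    )
    templates = make_templates(num_neurons, seed=seed)
    recording, truth = generate_train(cfg, templates)
    spikes = detect_spikes(recording)
    n = min(n_max, spikes.n // 2)
    if n < max(8, num_neurons):
        raise RuntimeError(
            f"only {spikes.n} detections at snr={snr}; benchmark needs more"
        )
    res = StreamingHebbianEigenfilter(l=l, n_mean=n, n_learn=n).fit(iter(spikes.spikes))
    block = spikes.spikes[n : 2 * n]
    basis = covariance_pca(block, l=l)

    she_scores = res.project(spikes)
    pca_scores = basis.project(spikes)
    she_eval = evaluate_sorting(
        spikes.event_times, cluster_kmeans(she_scores, K=num_neurons, seed=seed),
        truth, recording.fs,
    )
    pca_eval = evaluate_sorting(
        spikes.event_times, cluster_kmeans(pca_scores, K=num_neurons, seed=seed),
        truth, recording.fs,
    )
    return {
        "num_neurons": num_neurons,
        "snr": snr,
        "seed": seed,
        "n_detected": spikes.n,
        "n_block": n,
        "tpr_she": she_eval["tpr"],
        "fpr_she": she_eval["fpr"],
        "tpr_pca": pca_eval["tpr"],
        "fpr_pca": pca_eval["fpr"],
        "error_pc": [float(e) for e in res.error_pc(basis)],
        "error_mean": error_mean(res.mu, block.mean(axis=0)),
    }


def snr_sweep(
    num_neurons: int,
    seeds: tuple[int, ...] = (1, 2, 3),
    snr_grid: tuple[float, ...] = SNR_GRID,
    **kwargs,
) -> list[dict]:
    """`sorting_run` over the SNR grid; per-level medians across seeds."""
    out = []
    for snr in snr_grid:
        runs = [sorting_run(num_neurons, snr, seed, **kwargs) for seed in seeds]
        out.append({
            "snr": snr,
            "num_neurons": num_neurons,
            "tpr_she": float(np.median([r["tpr_she"] for r in runs])),
            "fpr_she": float(np.median([r["fpr_she"] for r in runs])),
            "tpr_pca": float(np.median([r["tpr_pca"] for r in runs])),
            "fpr_pca": float(np.median([r["fpr_pca"] for r in runs])),
            "runs": runs,
        })
    return out
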