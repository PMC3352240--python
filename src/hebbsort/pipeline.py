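"""End-to-end orchestration: simulate -> detect -> train -> cluster -> evaluate.

One `PipelineConfig` (a nested key/value structure, loadable from YAML)
carries every stage's parameters with defaults reproducing the reference
operating point: 25 kHz sampling, 64-sample spikes with the peak at index 20,
n = N = 1024, eta0 = 0.1, weights initialized to 0.5, l = 2 components,
16-bit words. A single global seed governs the generator and clustering.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import yaml

from . import io as hio
from .detection import detect_spikes
from .eigenfilter import StreamingHebbianEigenfilter
from .exceptions import InvalidConfigurationError, StreamExhaustedError
from .metrics import cluster_kmeans, error_mean, evaluate_sorting
from .pca import covariance_pca
from .synthetic import TrainConfig, generate_train, make_templates

logger = logging.getLogger("hebbsort")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "generator": {
        "num_neurons": 2,
        "firing_rates": 15.0,
        "duration": 100.0,
        "fs": 25000.0,
        "snr": 6.0,
        "background_rate": 2.0,
    },
    "detection": {
        "threshold_mult": 8.0,
        "d": 64,
        "peak_index": 20,
        "band": [300.0, 3000.0],
        "smooth_window": None,
        "dead_time_s": 0.0015,
    },
    "eigenfilter": {
        "l": 2,
        "eta": 0.1,
        "n": 1024,
        "N": 1024,
        "w_init": 0.5,
        "schedule": "decay",
    },
    "clustering": {"k": None},  # None -> the generator's neuron count
    "evaluation": {"match_tol_s": 0.0005},
    "complexity": {"w": 16},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class PipelineConfig:
    """Nested configuration with defaults; overridable from a YAML file."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge(DEFAULT_CONFIG, overrides or {})

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None and not isinstance(loaded, dict):
            raise InvalidConfigurationError(f"config file {path} must hold a mapping")
        return cls(loaded or {})

    def __getitem__(self, key):
        return self.data[key]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)


def run_pipeline(config: PipelineConfig | dict | None = None, outdir=None) -> dict:
    """Execute the full sorting pipeline and return (and optionally write)
    its metrics.

    Stages: synthetic generation, NEO detection and alignment, stream-based
    eigenfilter training (first n detected spikes feed the mean, the next N
    drive learning), reference covariance PCA on the learning block,
    projection of all detected spikes through both filters, K-means
    clustering of both feature sets, and evaluation against ground truth.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    cfg = config.data
    seed = int(cfg["seed"])
    gen, det, eig = cfg["generator"], cfg["detection"], cfg["eigenfilter"]

    tc = TrainConfig(
        num_neurons=int(gen["num_neurons"]),
        firing_rates=gen["firing_rates"],
        duration=float(gen["duration"]),
        fs=float(gen["fs"]),
        snr=float(gen["snr"]),
        background_rate=float(gen["background_rate"]),
        seed=seed,
    )
    templates = make_templates(
        tc.num_neurons, d=int(det["d"]), peak_index=int(det["peak_index"]), seed=seed
    )
    recording, truth = generate_train(tc, templates)
    logger.info("simulate: %d samples, %d ground-truth spikes", len(recording), len(truth))

    band = det.get("band")
    spikes = detect_spikes(
        recording,
        threshold_mult=float(det["threshold_mult"]),
        d=int(det["d"]),
        peak_index=int(det["peak_index"]),
        band=tuple(band) if band else None,
        smooth_window=det["smooth_window"],
        dead_time_s=float(det["dead_time_s"]),
    )
    logger.info(
        "detect: %d spikes (dropped boundary=%d unstable=%d duplicate=%d)",
        spikes.n, spikes.meta["dropped_boundary"],
        spikes.meta["dropped_unstable"], spikes.meta["dropped_duplicate"],
    )

    n, N = int(eig["n"]), int(eig["N"])
    if spikes.n < n + N:
        raise StreamExhaustedError(
            f"only {spikes.n} spikes detected; stream training needs n+N={n + N}. "
            "Increase duration or firing rates, or lower n/N."
        )
    model = StreamingHebbianEigenfilter(
        l=int(eig["l"]), eta=float(eig["eta"]), n_mean=n, n_learn=N,
        w_init=float(eig["w_init"]), schedule=eig["schedule"],
    )
    stream_res = model.fit(iter(spikes.spikes))
    logger.info("train: stream eigenfilter done after %d presentations", N)

    learning_block = spikes.spikes[n : n + N]
    basis = covariance_pca(learning_block, l=int(eig["l"]))
    err_mean = error_mean(stream_res.mu, learning_block.mean(axis=0))
    err_pc = stream_res.error_pc(basis)

    K = cfg["clustering"]["k"] or tc.num_neurons
    tol_s = float(cfg["evaluation"]["match_tol_s"])
    she_scores = stream_res.project(spikes)
    pca_scores = basis.project(spikes)
    she_sort = cluster_kmeans(she_scores, K=K, seed=seed)
    pca_sort = cluster_kmeans(pca_scores, K=K, seed=seed)
    she_eval = evaluate_sorting(spikes.event_times, she_sort, truth, recording.fs, tol_s)
    pca_eval = evaluate_sorting(spikes.event_times, pca_sort, truth, recording.fs, tol_s)
    logger.info(
        "evaluate: SHE tpr=%.3f fpr=%.3f | PCA tpr=%.3f fpr=%.3f",
        she_eval["tpr"], she_eval["fpr"], pca_eval["tpr"], pca_eval["fpr"],
    )

    metrics = {
        "tpr": she_eval["tpr"],
        "fpr": she_eval["fpr"],
        "error_mean": err_mean,
        "error_pc_per_component": [float(e) for e in err_pc],
        "tpr_pca": pca_eval["tpr"],
        "fpr_pca": pca_eval["fpr"],
        "n_detected": spikes.n,
        "n_truth": len(truth),
        "n_missed": she_eval["n_missed"],
        "n_false_detections": she_eval["n_false_detections"],
        "seed": seed,
        "snr": tc.snr,
        "num_neurons": tc.num_neurons,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_trace(outdir / "trace", recording)
        hio.write_truth(outdir / "truth.csv", truth)
        hio.write_spikes(outdir / "detected", spikes)
        stream_res.save(outdir / "filter_stream.json")
        hio.write_metrics(outdir / "metrics.json", metrics)
        (outdir / "config.yaml").write_text(config.to_yaml())
    return metrics
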