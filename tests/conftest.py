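"""Shared fixtures: small synthetic recordings and session-scoped benchmark
sweeps reused by the acceptance tests."""

from __future__ import annotations

import pytest

import hebbsort as h


@pytest.fixture(scope="session")
def short_train():
    """A 20-s two-neuron recording at snr 6 with ground truth."""
    cfg = h.TrainConfig(num_neurons=2, firing_rates=12.0, duration=20.0,
                        snr=6.0, seed=3)
    templates = h.make_templates(2, seed=3)
    rec, truth = h.generate_train(cfg, templates)
    return cfg, templates, rec, truth


@pytest.fixture(scope="session")
def detected(short_train):
    _, _, rec, _ = short_train
    return h.detect_spikes(rec)


@pytest.fixture(scope="session")
def stream_runs():
    """Full-scale (100 s, n = N = 1024) stream-training runs over 5 seeds at
    snr 4: the basis for the oracle-equivalence and block-mean checks."""
    out = []
    for seed in range(1, 6):
        cfg = h.TrainConfig(num_neurons=2, firing_rates=15.0, snr=4.0, seed=seed)
        templates = h.make_templates(2, seed=seed)
        rec, truth = h.generate_train(cfg, templates)
        spikes = h.detect_spikes(rec)
        res = h.StreamingHebbianEigenfilter().fit(iter(spikes.spikes))
        block = spikes.spikes[1024:2048]
        basis = h.covariance_pca(block, l=2)
        out.append({
            "seed": seed,
            "spikes": spikes,
            "results": res,
            "basis": basis,
            "error_pc": res.error_pc(basis),
            "error_mean": h.error_mean(res.mu, block.mean(axis=0)),
        })
    return out


@pytest.fixture(scope="session")
def parity_sweeps():
    """Median sorting accuracy over the SNR grid for 2/3/4 neurons, 5 seeds,
    for both stream-eigenfilter and reference-PCA features."""
    from hebbsort.benchmarks import snr_sweep

    return {nn: snr_sweep(nn, seeds=(1, 2, 3, 4, 5)) for nn in (2, 3, 4)}
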