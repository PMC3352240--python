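"""File formats: traces (int16 binary or CSV + JSON sidecar), ground truth,
spike matrices, filter bundles and metrics.

Round-trip guarantees: integer formats are bit-identical; real-valued
artifacts are written as decimal text with 17 significant digits and
therefore read back to full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ContinuousRecording, GroundTruth, SpikeMatrix
from .exceptions import FormatError

INT16_MAX = 32000  # headroom below the int16 limit for quantization


def write_trace(prefix, recording: ContinuousRecording, fmt: str = "bin") -> None:
    """Write a trace as ``PREFIX.bin`` (int16 LE) or ``PREFIX.csv`` plus a
    ``PREFIX.json`` sidecar recording fs, length, units and the quantization
    scale (units per least significant bit)."""
    prefix = Path(prefix)
    x = np.asarray(recording.samples, dtype=np.float64)
    sidecar = {
        "fs": recording.fs,
        "n_samples": int(len(x)),
        "format": fmt,
        **{k: v for k, v in recording.meta.items()},
    }
    if fmt == "bin":
        peak = float(np.max(np.abs(x))) if len(x) else 1.0
        scale = peak / INT16_MAX if peak > 0 else 1.0
        q = np.round(x / scale).astype("<i2")
        q.tofile(prefix.with_suffix(".bin"))
        sidecar["scale"] = scale
    elif fmt == "csv":
        np.savetxt(prefix.with_suffix(".csv"), x, fmt="%.17g")
    else:
        raise FormatError(f"unknown trace format {fmt!r}")
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_trace(prefix) -> ContinuousRecording:
    prefix = Path(prefix)
    sidecar_path = prefix.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed sidecar {sidecar_path}: {e}") from e
    for key in ("fs", "n_samples", "format"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path} lacks required key {key!r}")
    fmt = meta["format"]
    if fmt == "bin":
        q = np.fromfile(prefix.with_suffix(".bin"), dtype="<i2")
        if len(q) != meta["n_samples"]:
            raise FormatError(
                f"{prefix}.bin holds {len(q)} samples, sidecar says {meta['n_samples']}"
            )
        x = q.astype(np.float64) * meta.get("scale", 1.0)
    elif fmt == "csv":
        x = np.loadtxt(prefix.with_suffix(".csv"), ndmin=1)
        if len(x) != meta["n_samples"]:
            raise FormatError(
                f"{prefix}.csv holds {len(x)} samples, sidecar says {meta['n_samples']}"
            )
    else:
        raise FormatError(f"unknown trace format {fmt!r} in sidecar")
    fs = meta.pop("fs")
    meta.pop("n_samples")
    return ContinuousRecording(x, fs, meta=meta)


def write_truth(path, truth: GroundTruth) -> None:
    pd.DataFrame(
        {"sample_index": truth.spike_times, "neuron_id": truth.labels}
    ).to_csv(path, index=False)


def read_truth(path) -> GroundTruth:
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise FormatError(f"cannot parse ground truth {path}: {e}") from e
    for col in ("sample_index", "neuron_id"):
        if col not in df.columns:
            raise FormatError(f"{path} lacks required column {col!r}")
    return GroundTruth(df["sample_index"].to_numpy(), df["neuron_id"].to_numpy())


def write_spikes(prefix, spikes: SpikeMatrix) -> None:
    """``PREFIX.spikes.csv`` (one spike per row) and ``PREFIX.events.csv``."""
    prefix = Path(prefix)
    np.savetxt(_spikes_path(prefix), spikes.spikes, fmt="%.17g", delimiter=",")
    pd.DataFrame({"sample_index": spikes.event_times}).to_csv(
        _events_path(prefix), index=False
    )


def _spikes_path(prefix: Path) -> Path:
    return prefix.parent / (prefix.name + ".spikes.csv")


def _events_path(prefix: Path) -> Path:
    return prefix.parent / (prefix.name + ".events.csv")


def read_spikes(prefix, peak_index: int = 20) -> SpikeMatrix:
    prefix = Path(prefix)
    try:
        X = np.loadtxt(_spikes_path(prefix), delimiter=",", ndmin=2)
    except Exception as e:
        raise FormatError(f"cannot parse {_spikes_path(prefix)}: {e}") from e
    try:
        events = pd.read_csv(_events_path(prefix))["sample_index"].to_numpy()
    except KeyError as e:
        raise FormatError(f"{_events_path(prefix)} lacks 'sample_index'") from e
    except Exception as e:
        raise FormatError(f"cannot parse {_events_path(prefix)}: {e}") from e
    if X.shape[0] != len(events):
        raise FormatError(
            f"{X.shape[0]} spikes but {len(events)} event times under {prefix}"
        )
    return SpikeMatrix(X, events, peak_index=peak_index)


def write_filter(path, results) -> None:
    """Filter bundle: weights, mean, scale and parameters as JSON."""
    Path(path).write_text(json.dumps(results.to_dict(), indent=2, sort_keys=True))


def read_filter(path) -> dict:
    try:
        bundle = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed filter bundle {path}: {e}") from e
    for key in ("W", "mu", "method"):
        if key not in bundle:
            raise FormatError(f"filter bundle {path} lacks {key!r}")
    bundle["W"] = np.asarray(bundle["W"], dtype=np.float64)
    bundle["mu"] = np.asarray(bundle["mu"], dtype=np.float64)
    return bundle


def write_metrics(path, metrics: dict) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True))


def read_metrics(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed metrics file {path}: {e}") from e
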