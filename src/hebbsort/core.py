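"""Shared data containers for the spike-sorting pipeline.

Conventions used throughout the package: sample indices are 0-based, spike
windows are half-open ``[start, start + d)``, and every aligned spike has its
absolute peak at ``peak_index`` within the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

#: samples per aligned spike (~2.56 ms at 25 kHz)
DEFAULT_D = 64
#: 0-based index of the aligned peak within the spike window (~0.8 ms in)
DEFAULT_PEAK_INDEX = 20
#: default sampling rate in Hz
DEFAULT_FS = 25_000.0


@dataclass
class ContinuousRecording:
    """A single-channel extracellular voltage trace.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence (arbitrary units or µV).
    fs : float
        Sampling rate in Hz; must be positive.
    meta : dict
        Free-form provenance (seed, SNR, quantization scale, ...).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.samples) / self.fs


@dataclass
class GroundTruth:
    """Known spike times and neuron identities of a synthetic recording."""

    spike_times: np.ndarray  # 0-based sample index of each spike peak
    labels: np.ndarray  # neuron id per spike

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.spike_times.shape != self.labels.shape:
            raise InvalidInputError("spike_times and labels must have equal length")
        order = np.argsort(self.spike_times, kind="stable")
        self.spike_times = self.spike_times[order]
        self.labels = self.labels[order]

    def __len__(self) -> int:
        return len(self.spike_times)

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def times_of(self, neuron_id: int) -> np.ndarray:
        return self.spike_times[self.labels == neuron_id]


@dataclass
class SpikeMatrix:
    """n aligned spikes of d samples each, peak at a fixed index.

    ``meta`` records bookkeeping from detection (e.g. dropped boundary events).
    """

    spikes: np.ndarray  # (n, d)
    event_times: np.ndarray  # (n,) sample index of each spike's peak
    peak_index: int = DEFAULT_PEAK_INDEX
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = np.atleast_2d(np.asarray(self.spikes, dtype=np.float64))
        self.event_times = np.asarray(self.event_times, dtype=np.int64)
        if self.spikes.size == 0:
            self.spikes = self.spikes.reshape(0, self.spikes.shape[-1] if self.spikes.ndim > 1 else 0)
        if len(self.event_times) != self.n:
            raise InvalidInputError(
                f"{self.n} spikes but {len(self.event_times)} event times"
            )

    @property
    def n(self) -> int:
        return self.spikes.shape[0]

    @property
    def d(self) -> int:
        return self.spikes.shape[1]

    def check_alignment(self) -> bool:
        """True iff every row's absolute maximum sits at ``peak_index``."""
        if self.n == 0:
            return True
        return bool(np.all(np.argmax(np.abs(self.spikes), axis=1) == self.peak_index))

    def __len__(self) -> int:
        return self.n


@dataclass
class FeatureScores:
    """Projections of aligned spikes onto the learned components (n × l)."""

    scores: np.ndarray
    event_times: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=np.float64))
        self.event_times = np.asarray(self.event_times, dtype=np.int64)
        if not np.all(np.isfinite(self.scores)):
            raise InvalidInputError("feature scores must be finite")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def l(self) -> int:
        return self.scores.shape[1]
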