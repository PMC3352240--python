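"""Spike detection and peak alignment.

Detection uses the nonlinear energy operator (NEO),
``psi(n) = x(n)^2 - x(n-1) x(n+1)``, which responds to signal that is
simultaneously high-amplitude and high-frequency, followed by a mean-based
threshold, dead-time suppression of repeated crossings, and refinement of each
crossing to the local absolute-amplitude peak. Detected peaks are cut into
fixed-length windows aligned so the peak sits at a fixed index.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import DEFAULT_D, DEFAULT_PEAK_INDEX, ContinuousRecording, SpikeMatrix
from .exceptions import InvalidInputError

#: default threshold multiplier applied to the mean NEO energy
DEFAULT_THRESHOLD_MULT = 8.0
#: default detection band-pass edges in Hz (the standard spike band;
#: full-band noise would otherwise dominate the NEO energy floor)
DEFAULT_BAND = (300.0, 3000.0)
#: default dead time between detections, seconds (below the refractory period)
DEFAULT_DEAD_TIME_S = 0.0015
#: default peak-refinement half-window, seconds
DEFAULT_REFINE_S = 0.001


def bandpass_filter(
    trace: np.ndarray,
    fs: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, the standard front end before
    energy-based spike detection."""
    if not (0 < low < high < fs / 2):
        raise InvalidInputError(
            f"band ({low}, {high}) invalid for fs={fs}"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(trace, dtype=np.float64))


def neo_transform(trace: np.ndarray, smooth_window: int | None = None) -> np.ndarray:
    """Nonlinear energy operator of a trace, optionally Bartlett-smoothed.

    Output has the input's length; the two boundary samples are 0. The
    smoothing window is normalized to unit sum so the energy scale (and hence
    any mean-based threshold) is preserved.
    """
    x = np.asarray(trace, dtype=np.float64)
    if x.ndim != 1 or len(x) < 3:
        raise InvalidInputError("neo_transform needs a 1-D trace of length >= 3")
    psi = np.zeros_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    if smooth_window is not None and smooth_window > 1:
        win = np.bartlett(smooth_window)
        psi = np.convolve(psi, win / win.sum(), mode="same")
    return psi


def train_threshold(energy: np.ndarray, multiplier: float = DEFAULT_THRESHOLD_MULT) -> float:
    """Detection threshold: ``multiplier`` times the mean energy."""
    energy = np.asarray(energy, dtype=np.float64)
    if energy.size == 0:
        raise InvalidInputError("empty energy sequence")
    if multiplier <= 0:
        raise InvalidInputError("multiplier must be positive")
    return float(multiplier * np.mean(energy))


def detect_events(
    energy: np.ndarray,
    threshold: float,
    dead_time: int,
    trace: np.ndarray | None = None,
    refine_window: int = 25,
) -> np.ndarray:
    """Upward threshold crossings with dead-time suppression.

    If ``trace`` is given, each crossing is refined to the sample of maximum
    absolute amplitude within ``±refine_window`` samples.
    """
    energy = np.asarray(energy, dtype=np.float64)
    if dead_time < 0:
        raise InvalidInputError("dead_time must be >= 0")
    above = energy > threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    kept: list[int] = []
    last = -np.inf
    for idx in crossings:
        if idx - last > dead_time:
            kept.append(int(idx))
            last = idx
    events = np.asarray(kept, dtype=np.int64)
    if trace is not None and len(events):
        x = np.abs(np.asarray(trace, dtype=np.float64))
        refined = []
        for idx in events:
            lo = max(idx - refine_window, 0)
            hi = min(idx + refine_window + 1, len(x))
            refined.append(lo + int(np.argmax(x[lo:hi])))
        events = np.asarray(refined, dtype=np.int64)
    return events


def align_spikes(
    trace: np.ndarray,
    events: np.ndarray,
    d: int = DEFAULT_D,
    peak_index: int = DEFAULT_PEAK_INDEX,
    max_recenters: int = 3,
) -> SpikeMatrix:
    """Cut peak-aligned windows ``[peak - peak_index, peak - peak_index + d)``.

    Each event is re-centered (at most ``max_recenters`` times) until the
    window's absolute maximum sits at ``peak_index``; events whose window
    would cross the trace boundary are dropped and counted, as are duplicates
    that re-center onto an already-kept peak.
    """
    if not (0 < peak_index < d):
        raise InvalidInputError("require 0 < peak_index < d")
    x = np.asarray(trace, dtype=np.float64)
    rows, times = [], []
    dropped_boundary = dropped_unstable = dropped_duplicate = 0
    seen: set[int] = set()
    for t0 in np.asarray(events, dtype=np.int64):
        t = int(t0)
        ok = False
        for _ in range(max_recenters + 1):
            start = t - peak_index
            if start < 0 or start + d > len(x):
                dropped_boundary += 1
                break
            win = x[start : start + d]
            pk = int(np.argmax(np.abs(win)))
            if pk == peak_index:
                ok = True
                break
            t = start + pk
        else:
            dropped_unstable += 1
        if not ok:
            continue
        if t in seen:
            dropped_duplicate += 1
            continue
        seen.add(t)
        rows.append(x[t - peak_index : t - peak_index + d].copy())
        times.append(t)
    spikes = np.asarray(rows, dtype=np.float64).reshape(len(rows), d)
    return SpikeMatrix(
        spikes,
        np.asarray(times, dtype=np.int64),
        peak_index=peak_index,
        meta={
            "dropped_boundary": dropped_boundary,
            "dropped_unstable": dropped_unstable,
            "dropped_duplicate": dropped_duplicate,
        },
    )


def detect_spikes(
    recording: ContinuousRecording,
    threshold_mult: float = DEFAULT_THRESHOLD_MULT,
    d: int = DEFAULT_D,
    peak_index: int = DEFAULT_PEAK_INDEX,
    band: tuple[float, float] | None = DEFAULT_BAND,
    smooth_window: int | None = None,
    dead_time_s: float = DEFAULT_DEAD_TIME_S,
    refine_s: float = DEFAULT_REFINE_S,
) -> SpikeMatrix:
    """Full detection stage: band-pass -> NEO -> threshold -> aligned spikes.

    Detection (energy, threshold crossing, peak refinement) runs on the
    band-passed trace, where spikes stand out from the noise floor; the
    aligned spike windows are cut from the raw trace so the waveform shapes
    and their full second-order structure are preserved for feature
    extraction. ``band=None`` disables the prefilter.
    """
    x = np.asarray(recording.samples, dtype=np.float64)
    xf = bandpass_filter(x, recording.fs, *band) if band is not None else x
    energy = neo_transform(xf, smooth_window=smooth_window)
    threshold = train_threshold(energy, threshold_mult)
    events = detect_events(
        energy,
        threshold,
        dead_time=int(round(dead_time_s * recording.fs)),
        trace=xf,
        refine_window=int(round(refine_s * recording.fs)),
    )
    out = align_spikes(x, events, d=d, peak_index=peak_index)
    out.meta["threshold"] = threshold
    out.meta["n_crossings"] = int(len(events))
    return out
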