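"""Hebbian eigenfilter: batch GHA and the stream-based single-pass variant.

The generalized Hebbian algorithm (Sanger's rule) learns the leading ``l``
principal components of zero-mean spike vectors by the synaptic update

    y = W x
    dW = eta * (y x^T - LT(y y^T) W)
    W <- W + dW

where ``LT`` zeroes the elements above the diagonal, enforcing the deflation
ordering among the learned components. Its fixed points are the unit-norm
leading eigenvectors of the input covariance.

Two training regimes are provided:

* **batch** — the classical form: store all n spikes, compute their mean,
  zero-mean them, then cycle through them for N presentations.
* **stream** — the memory-free form: the first n spikes are consumed only to
  accumulate the mean (and an input-scale estimate) and are then discarded;
  the next N spikes are mean-subtracted with the frozen mean and presented
  once each. No spike buffer ever exists; the learner holds one spike vector
  at a time. This relies on pseudo-stationarity: spike statistics are stable
  enough over short recording periods for one block's mean to stand in for
  the next block's.

Model-style front ends (`HebbianEigenfilter`, `StreamingHebbianEigenfilter`)
wrap these routines and return an `EigenfilterResults` object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .core import FeatureScores, SpikeMatrix
from .exceptions import (
    DivergenceError,
    InvalidInputError,
    StreamExhaustedError,
)

#: defaults of the learning kernel: all weights 0.5, eta0 = 0.1, n = N = 1024
DEFAULT_W_INIT = 0.5
DEFAULT_ETA = 0.1
DEFAULT_N_MEAN = 1024
DEFAULT_N_LEARN = 1024
#: time constant (presentations) of the harmonic learning-rate decay; slow
#: enough that trailing components still receive substantial learning within
#: N = 1024 presentations (eta only falls to ~2/3 eta0 by the end)
DEFAULT_ETA_TAU = 2048.0


def lt_lower_triangular(M: np.ndarray) -> np.ndarray:
    """Zero all elements above the diagonal (diagonal retained)."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InvalidInputError(f"LT operator needs a square matrix, got {M.shape}")
    return np.tril(M)


@dataclass
class EigenfilterState:
    """Mutable state of the learner.

    ``phase`` moves mean_accumulation -> learning -> done. During mean
    accumulation ``mu`` holds a running sum; afterwards the frozen mean.
    ``scale`` is the input normalization factor (1 / RMS norm of centered
    spikes) estimated during the mean phase, applied before each update so
    that GHA stability is insensitive to the recording's amplitude units.
    """

    l: int
    d: int
    eta: float = DEFAULT_ETA
    n: int = DEFAULT_N_MEAN  # spikes consumed for the mean
    N: int = DEFAULT_N_LEARN  # learning presentations
    w_init: float = DEFAULT_W_INIT
    schedule: str = "decay"  # "decay" or "constant"
    eta_tau: float = DEFAULT_ETA_TAU
    scale_inputs: bool = True
    symmetry_break: float = 0.05

    W: np.ndarray = field(init=False)
    mu: np.ndarray = field(init=False)
    j: int = field(init=False, default=1)  # presentation counter, 1-based
    phase: str = field(init=False, default="mean_accumulation")
    mean_count: int = field(init=False, default=0)
    scale: float = field(init=False, default=1.0)
    _sumsq: float = field(init=False, default=0.0)
    max_retained_spikes: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not (1 <= self.l <= self.d):
            raise InvalidInputError(f"need 1 <= l <= d, got l={self.l}, d={self.d}")
        if self.eta < 0:
            raise InvalidInputError("eta must be nonnegative")
        if self.schedule not in ("decay", "constant"):
            raise InvalidInputError(f"unknown schedule {self.schedule!r}")
        self.W = np.full((self.l, self.d), float(self.w_init))
        # an all-equal-rows init is a degenerate saddle of the GHA dynamics:
        # after deflation the trailing components must regrow from numerical
        # residue, which stalls when the eigenvalue ratio is large. A small
        # deterministic cosine perturbation on rows 2..l breaks the symmetry
        # without touching the l=1 case or the configured w_init level.
        if self.symmetry_break and self.l > 1:
            k = np.arange(self.d)
            for i in range(1, self.l):
                self.W[i] += self.symmetry_break * np.cos(2 * np.pi * (i + 1) * k / self.d)
        self.W_init = self.W.copy()
        self.mu = np.zeros(self.d)

    @property
    def current_eta(self) -> float:
        """Learning rate for presentation ``j`` (eta0 exactly at j=1)."""
        if self.schedule == "constant":
            return self.eta
        return self.eta / (1.0 + (self.j - 1) / self.eta_tau)


def accumulate_mean(state: EigenfilterState, x: np.ndarray) -> EigenfilterState:
    """Fold one spike into the running mean (stream step 2).

    On reaching ``state.n`` spikes the sum is divided by n, the input scale is
    frozen, and the state moves to the learning phase.
    """
    if state.phase != "mean_accumulation":
        raise InvalidInputError(f"accumulate_mean called in phase {state.phase!r}")
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (state.d,):
        raise InvalidInputError(f"expected spike of shape ({state.d},), got {x.shape}")
    state.mu += x
    state._sumsq += float(x @ x)
    state.mean_count += 1
    if state.mean_count == state.n:
        state.mu /= state.n
        # E||x - mu||^2 = E||x||^2 - ||mu||^2, so the centered RMS norm is
        # available without ever having stored a spike
        var = state._sumsq / state.n - float(state.mu @ state.mu)
        if state.scale_inputs and var > 0:
            state.scale = 1.0 / np.sqrt(var)
        state.phase = "learning"
    return state


def hebbian_step(state: EigenfilterState, x: np.ndarray) -> EigenfilterState:
    """One GHA presentation on an already mean-subtracted spike."""
    if state.phase != "learning":
        raise InvalidInputError(f"hebbian_step called in phase {state.phase!r}")
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (state.d,):
        raise InvalidInputError(f"expected spike of shape ({state.d},), got {x.shape}")
    eta = state.current_eta
    y = state.W @ x
    LT = lt_lower_triangular(np.outer(y, y))
    state.W += eta * (np.outer(y, x) - LT @ state.W)
    state.j += 1
    if not np.all(np.isfinite(state.W)):
        raise DivergenceError(
            f"weights diverged at presentation {state.j - 1}; "
            f"learning rate eta={state.eta} is likely too large"
        )
    return state


def _as_spike_iter(source) -> Iterator[np.ndarray]:
    if isinstance(source, SpikeMatrix):
        return iter(source.spikes)
    if isinstance(source, np.ndarray):
        return iter(np.atleast_2d(source))
    return iter(source)


def train_stream(
    source: Iterable[np.ndarray],
    l: int = 2,
    d: int | None = None,
    eta: float = DEFAULT_ETA,
    n: int = DEFAULT_N_MEAN,
    N: int = DEFAULT_N_LEARN,
    w_init: float = DEFAULT_W_INIT,
    schedule: str = "decay",
    eta_tau: float = DEFAULT_ETA_TAU,
    scale_inputs: bool = True,
    symmetry_break: float = 0.05,
    monitor=None,
) -> tuple[np.ndarray, EigenfilterState]:
    """Single-pass training on an ordered spike stream.

    The first ``n`` spikes are folded into the mean and discarded; the next
    ``N`` are mean-subtracted with the frozen mean, scaled, and presented once
    each. At most one spike vector is held at any instant; ``monitor``, if
    given, is called with that retained-spike count after every arrival.
    """
    it = _as_spike_iter(source)
    state: EigenfilterState | None = None
    consumed = 0
    while True:
        try:
            x = np.asarray(next(it), dtype=np.float64)
        except StopIteration:
            phase = state.phase if state is not None else "mean_accumulation"
            raise StreamExhaustedError(
                f"stream ended after {consumed} spikes in phase {phase!r}; "
                f"need n+N = {n + N}"
            ) from None
        if state is None:
            state = EigenfilterState(
                l=l, d=d if d is not None else len(x), eta=eta, n=n, N=N,
                w_init=w_init, schedule=schedule, eta_tau=eta_tau,
                scale_inputs=scale_inputs, symmetry_break=symmetry_break,
            )
        consumed += 1
        state.max_retained_spikes = max(state.max_retained_spikes, 1)
        if monitor is not None:
            monitor(1)
        if state.phase == "mean_accumulation":
            accumulate_mean(state, x)
        else:
            hebbian_step(state, (x - state.mu) * state.scale)
            if state.j > state.N:
                state.phase = "done"
                return state.W.copy(), state
        del x  # the spike is discarded before the next arrives


def train_batch(
    spikes: SpikeMatrix | np.ndarray,
    l: int = 2,
    eta: float = DEFAULT_ETA,
    N: int = DEFAULT_N_LEARN,
    w_init: float = DEFAULT_W_INIT,
    schedule: str = "decay",
    eta_tau: float = DEFAULT_ETA_TAU,
    scale_inputs: bool = True,
    symmetry_break: float = 0.05,
) -> tuple[np.ndarray, EigenfilterState]:
    """Classical GHA on a stored spike matrix.

    The mean is computed over all spikes, all spikes are zero-meaned, and the
    learner cycles through them in order for ``N`` presentations.
    """
    X = spikes.spikes if isinstance(spikes, SpikeMatrix) else np.atleast_2d(np.asarray(spikes, dtype=np.float64))
    n_spikes, d = X.shape
    if n_spikes < 1:
        raise InvalidInputError("train_batch needs at least one spike")
    state = EigenfilterState(
        l=l, d=d, eta=eta, n=n_spikes, N=N, w_init=w_init,
        schedule=schedule, eta_tau=eta_tau, scale_inputs=scale_inputs,
        symmetry_break=symmetry_break,
    )
    for row in X:
        accumulate_mean(state, row)
    Xc = (X - state.mu) * state.scale
    while state.j <= N:
        hebbian_step(state, Xc[(state.j - 1) % n_spikes])
    state.phase = "done"
    return state.W.copy(), state


def project(
    spikes: SpikeMatrix | np.ndarray,
    W: np.ndarray,
    mu: np.ndarray,
    scale: float = 1.0,
) -> FeatureScores:
    """Project aligned spikes onto the learned components: ``W (x - mu)``."""
    if isinstance(spikes, SpikeMatrix):
        X, times = spikes.spikes, spikes.event_times
    else:
        X = np.atleast_2d(np.asarray(spikes, dtype=np.float64))
        times = np.arange(X.shape[0])
    W = np.asarray(W, dtype=np.float64)
    if X.shape[1] != W.shape[1]:
        raise InvalidInputError(
            f"spikes have d={X.shape[1]} but W has d={W.shape[1]}"
        )
    scores = (X - np.asarray(mu)) * scale @ W.T
    return FeatureScores(scores, times)


class EigenfilterResults:
    """Fitted eigenfilter: learned components, diagnostics, projection.

    Attributes
    ----------
    W : ndarray (l, d)
        Raw learned synaptic weights.
    components_ : ndarray (l, d)
        Row-normalized weights (unit vectors).
    mu : ndarray (d,)
        Mean vector used for centering.
    scale : float
        Input normalization factor applied during training and projection.
    """

    def __init__(self, model, W: np.ndarray, state: EigenfilterState, method: str):
        self.model = model
        self.W = np.asarray(W, dtype=np.float64)
        self.state = state
        self.method = method
        self.mu = state.mu.copy()
        self.scale = state.scale

    @property
    def l(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    @property
    def component_norms(self) -> np.ndarray:
        return np.linalg.norm(self.W, axis=1)

    @property
    def components_(self) -> np.ndarray:
        norms = self.component_norms
        return self.W / np.where(norms > 0, norms, 1.0)[:, None]

    def project(self, spikes: SpikeMatrix | np.ndarray) -> FeatureScores:
        return project(spikes, self.W, self.mu, self.scale)

    def score_variances(self, spikes: SpikeMatrix | np.ndarray) -> np.ndarray:
        """Per-component variance of the projections of ``spikes``."""
        return self.project(spikes).scores.var(axis=0)

    def error_pc(self, basis) -> np.ndarray:
        """Per-component deviation 1 - |w_hat . pc_hat| against a PCA basis."""
        from .metrics import error_pc as _error_pc

        return np.array(
            [_error_pc(self.W[i], basis.components[i]) for i in range(min(self.l, len(basis.components)))]
        )

    def summary(self) -> str:
        lines = [
            "Hebbian Eigenfilter Results",
            "=" * 46,
            f"method:            {self.method}",
            f"components (l):    {self.l}",
            f"spike length (d):  {self.d}",
            f"eta0:              {self.state.eta}  ({self.state.schedule} schedule)",
            f"mean spikes (n):   {self.state.n}",
            f"presentations (N): {self.state.N}",
            f"input scale:       {self.scale:.6g}",
            "-" * 46,
            "component   ||w||       ",
        ]
        for i, nrm in enumerate(self.component_norms):
            lines.append(f"  w{i + 1}       {nrm:8.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import write_filter

        write_filter(path, self)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "W": self.W.tolist(),
            "mu": self.mu.tolist(),
            "scale": self.scale,
            "params": {
                "l": self.l,
                "d": self.d,
                "eta": self.state.eta,
                "n": self.state.n,
                "N": self.state.N,
                "schedule": self.state.schedule,
            },
        }


class HebbianEigenfilter:
    """Batch GHA model over a stored spike matrix (Model/fit/Results style)."""

    def __init__(
        self,
        spikes: SpikeMatrix | np.ndarray,
        l: int = 2,
        eta: float = DEFAULT_ETA,
        N: int = DEFAULT_N_LEARN,
        w_init: float = DEFAULT_W_INIT,
        schedule: str = "decay",
        eta_tau: float = DEFAULT_ETA_TAU,
        scale_inputs: bool = True,
    ):
        self.spikes = spikes
        self.l = l
        self.eta = eta
        self.N = N
        self.w_init = w_init
        self.schedule = schedule
        self.eta_tau = eta_tau
        self.scale_inputs = scale_inputs

    @classmethod
    def from_recording(cls, recording, l: int = 2, **detect_kwargs):
        """Build the model directly from a continuous recording."""
        from .detection import detect_spikes

        fit_kw = {}
        for key in ("eta", "N", "w_init", "schedule", "scale_inputs"):
            if key in detect_kwargs:
                fit_kw[key] = detect_kwargs.pop(key)
        return cls(detect_spikes(recording, **detect_kwargs), l=l, **fit_kw)

    def fit(self) -> EigenfilterResults:
        W, state = train_batch(
            self.spikes, l=self.l, eta=self.eta, N=self.N,
            w_init=self.w_init, schedule=self.schedule, eta_tau=self.eta_tau,
            scale_inputs=self.scale_inputs,
        )
        return EigenfilterResults(self, W, state, method="batch_gha")


class StreamingHebbianEigenfilter:
    """Stream-based eigenfilter model: fit consumes an ordered spike stream."""

    def __init__(
        self,
        l: int = 2,
        eta: float = DEFAULT_ETA,
        n_mean: int = DEFAULT_N_MEAN,
        n_learn: int = DEFAULT_N_LEARN,
        w_init: float = DEFAULT_W_INIT,
        schedule: str = "decay",
        eta_tau: float = DEFAULT_ETA_TAU,
        scale_inputs: bool = True,
    ):
        self.l = l
        self.eta = eta
        self.n_mean = n_mean
        self.n_learn = n_learn
        self.w_init = w_init
        self.schedule = schedule
        self.eta_tau = eta_tau
        self.scale_inputs = scale_inputs

    def fit(self, source: Iterable[np.ndarray], monitor=None) -> EigenfilterResults:
        W, state = train_stream(
            source, l=self.l, eta=self.eta, n=self.n_mean, N=self.n_learn,
            w_init=self.w_init, schedule=self.schedule, eta_tau=self.eta_tau,
            scale_inputs=self.scale_inputs, monitor=monitor,
        )
        return EigenfilterResults(self, W, state, method="stream_gha")
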