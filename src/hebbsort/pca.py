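"""Reference batch PCA (covariance + eigendecomposition).

This is the conventional route the eigenfilter replaces; here it serves as
the independent oracle against which learned components are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FeatureScores, SpikeMatrix
from .exceptions import InvalidInputError


@dataclass
class PCBasis:
    """Top-l principal components of a spike matrix.

    ``components`` rows are unit-norm and pairwise orthogonal; eigenvalues are
    sorted descending. Covariance is normalized by n (not n-1).
    """

    components: np.ndarray  # (l, d)
    eigenvalues: np.ndarray  # (l,)
    mu: np.ndarray  # (d,)

    def project(self, spikes: SpikeMatrix | np.ndarray) -> FeatureScores:
        from .eigenfilter import project as _project

        return _project(spikes, self.components, self.mu)


def covariance_pca(spikes: SpikeMatrix | np.ndarray, l: int = 2) -> PCBasis:
    """Mean-center, form the covariance, eigendecompose, return top-l pairs."""
    X = spikes.spikes if isinstance(spikes, SpikeMatrix) else np.atleast_2d(np.asarray(spikes, dtype=np.float64))
    n, d = X.shape
    if n < 2:
        raise InvalidInputError("covariance PCA needs at least 2 spikes")
    if not (1 <= l <= d):
        raise InvalidInputError(f"need 1 <= l <= d, got l={l}, d={d}")
    mu = X.mean(axis=0)
    Xc = X - mu
    C = (Xc.T @ Xc) / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:l]
    evals = evals[order]
    if np.any(evals < -1e-8 * max(evals.max(initial=0.0), 1.0)):
        warnings.warn("covariance has significantly negative eigenvalues")
    rank = np.linalg.matrix_rank(Xc)
    if l > rank:
        warnings.warn(f"requested l={l} components but data rank is {rank}; "
                      "trailing eigenvalues are ~0")
    return PCBasis(evecs[:, order].T.copy(), np.clip(evals, 0.0, None), mu)


def sign_align(W: np.ndarray, basis: PCBasis) -> np.ndarray:
    """Flip rows of W so each has nonnegative dot product with its PC row.

    Eigenvector sign is arbitrary; alignment is required before any row-wise
    comparison of learned weights against reference components.
    """
    W = np.asarray(W, dtype=np.float64)
    P = basis.components
    if W.shape != P.shape:
        raise InvalidInputError(f"shape mismatch: W {W.shape} vs basis {P.shape}")
    signs = np.where(np.einsum("ij,ij->i", W, P) < 0, -1.0, 1.0)
    return W * signs[:, None]
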