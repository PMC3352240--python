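"""Plot helpers for feature-space scatters and learned components."""

from __future__ import annotations

import numpy as np

from .core import FeatureScores


def plot_features(scores, assignments=None, ax=None):
    """Scatter of the first two feature-space coordinates, one color per
    cluster. Returns the matplotlib axis."""
    import matplotlib.pyplot as plt

    X = scores.scores if isinstance(scores, FeatureScores) else np.atleast_2d(scores)
    if ax is None:
        _, ax = plt.subplots()
    y = X[:, 1] if X.shape[1] > 1 else np.zeros(len(X))
    if assignments is not None:
        ax.scatter(X[:, 0], y, c=assignments, s=6, cmap="tab10")
    else:
        ax.scatter(X[:, 0], y, color="k", s=6)
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    return ax


def plot_components(results, basis=None, ax=None):
    """Learned component waveforms, optionally overlaid on reference PCs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, row in enumerate(results.components_):
        ax.plot(row, label=f"w{i + 1}")
    if basis is not None:
        for i, row in enumerate(basis.components):
            ax.plot(row, "--", label=f"PC{i + 1}")
    ax.set_xlabel("sample")
    ax.legend()
    return ax
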