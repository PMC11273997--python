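"""Minimal plotting helpers (diagnostic quality, not publication graphics)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_reconstruction(
    scores_hat: np.ndarray,
    observed: np.ndarray,
    reconstructed: np.ndarray,
    true_scores: np.ndarray | None = None,
    path: str | Path | None = None,
):
    """Scatter of observed and reconstructed item values against scores.

    One panel per item; returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = np.asarray(scores_hat, dtype=float).ravel()
    x = np.asarray(observed, dtype=float)
    xh = np.asarray(reconstructed, dtype=float)
    p = x.shape[1]
    ncols = min(4, p)
    nrows = int(np.ceil(p / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows),
                             squeeze=False)
    st = np.asarray(true_scores).ravel() if true_scores is not None else s
    for j in range(p):
        ax = axes[j // ncols][j % ncols]
        ax.plot(st, x[:, j], ".", ms=1, alpha=0.4, label="observed")
        ax.plot(s, xh[:, j], ".", ms=1, alpha=0.4, color="crimson",
                label="reconstructed")
        ax.set_title(f"item {j + 1}", fontsize=8)
    for k in range(p, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    axes[0][0].legend(fontsize=6, markerscale=5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig
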