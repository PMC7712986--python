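"""Diagnostic plots: entropy-vs-size envelope and PCA score scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .entropy import EntropyEnvelope
from .stats import PcaDecomposition

__all__ = ["plot_entropy_envelope", "plot_scores"]


def plot_entropy_envelope(
    group_entropies: pd.DataFrame,
    baseline: dict[int, EntropyEnvelope],
    path: str | Path,
) -> None:
    """Rule-group entropies over the random-group envelope, by size."""
    fig, ax = plt.subplots(figsize=(7, 5))
    sizes = sorted(baseline)
    for lo, hi, alpha in ((1, 99, 0.15), (5, 95, 0.2), (25, 75, 0.3)):
        ax.fill_between(
            sizes,
            [baseline[s].quantiles[lo] for s in sizes],
            [baseline[s].quantiles[hi] for s in sizes],
            color="grey", alpha=alpha, linewidth=0,
        )
    ax.plot(sizes, [baseline[s].quantiles[50] for s in sizes], color="grey", lw=1,
            label="random groups (median)")
    ax.scatter(group_entropies["size"], group_entropies["entropy"], s=18,
               color="tab:blue", zorder=3, label="shared-rule groups")
    ax.set_xlabel("group size (reactions)")
    ax.set_ylabel("induced entropy (bits)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scores(dec: PcaDecomposition, path: str | Path, labels=None) -> None:
    """Scatter of the first two (or three) PCA score components."""
    k = dec.scores.shape[1]
    fig = plt.figure(figsize=(6, 5))
    color = None
    if labels is not None:
        uniq = sorted(set(labels))
        color = [uniq.index(l) for l in labels]
    if k >= 3:
        ax = fig.add_subplot(projection="3d")
        ax.scatter(dec.scores.iloc[:, 0], dec.scores.iloc[:, 1], dec.scores.iloc[:, 2],
                   c=color, cmap="tab10", s=14)
        ax.set_zlabel("PC3")
    else:
        ax = fig.add_subplot()
        y = dec.scores.iloc[:, 1] if k > 1 else np.zeros(len(dec.scores))
        ax.scatter(dec.scores.iloc[:, 0], y, c=color, cmap="tab10", s=14)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
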