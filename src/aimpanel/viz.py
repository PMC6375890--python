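"""Minimal qualitative plots: stacked ancestry bars and PC scatter."""

from __future__ import annotations

import os

from .admixture import AdmixtureFit
from .evaluate import PCAProjection


def plot_admixture_bars(fit: AdmixtureFit, path: str | os.PathLike, title: str = "") -> None:
    """Stacked per-individual ancestry-proportion bars (one bar per genome)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q = fit.Q.proportions
    n, K = q.shape
    fig, ax = plt.subplots(figsize=(max(6, n * 0.25), 3))
    bottom = q[:, 0] * 0
    x = range(n)
    for k in range(K):
        ax.bar(x, q[:, k], bottom=bottom, width=1.0, label=f"component {k + 1}")
        bottom = bottom + q[:, k]
    ax.set_xticks(list(x))
    ax.set_xticklabels(fit.Q.individual_ids, rotation=90, fontsize=6)
    ax.set_ylabel("ancestry proportion")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(projection: PCAProjection, path: str | os.PathLike, labels=None, title: str = "") -> None:
    """PC1 vs PC2 scatter, optionally coloured by population label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = projection.coordinates
    fig, ax = plt.subplots(figsize=(5, 4))
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=18)
    else:
        labels = list(labels)
        for lab in sorted(set(labels)):
            rows = [i for i, l in enumerate(labels) if l == lab]
            ax.scatter(coords[rows, 0], coords[rows, 1], s=18, label=lab)
        ax.legend(fontsize=7)
    ve = projection.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.0f}% variance)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.0f}% variance)" if len(ve) > 1 else "PC2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
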