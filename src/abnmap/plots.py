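"""SVG rendering of the nomogram and the model ROC curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_nomogram", "plot_roc"]


def plot_nomogram(nomogram, path) -> None:
    """Draw one horizontal axis per feature, value ticks mapped to points."""
    fig, ax = plt.subplots(figsize=(7, 3))
    names = nomogram.feature_names
    for row, name in enumerate(names):
        i = list(names).index(name)
        lo, hi = nomogram.ranges[i]
        vals = np.linspace(lo, hi, 6)
        pts = nomogram.scale * (vals * nomogram.coefficients[i]
                                - nomogram.offsets[i])
        y = len(names) - row
        ax.plot([0, 100], [y, y], color="0.8", lw=1)
        ax.scatter(pts, np.full_like(pts, y), s=10, color="C0")
        for v, p in zip(vals, pts):
            ax.annotate(f"{v:.2f}", (p, y), textcoords="offset points",
                        xytext=(0, 5), ha="center", fontsize=7)
        ax.annotate(name, (-2, y), ha="right", va="center", fontsize=9)
    ax.axvline(nomogram.threshold_points, color="C3", ls="--", lw=1,
               label=f"threshold = {nomogram.threshold_points:.1f} points")
    ax.set_xlabel("points")
    ax.set_yticks([])
    ax.set_xlim(-35, 105)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_roc(scores, labels, path) -> None:
    """Empirical ROC curve of model scores against binary outcome labels."""
    from sklearn.metrics import roc_curve

    from .metrics import rank_auc

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = rank_auc(scores[labels == 1], scores[labels == 0])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, color="C0", label=f"AUC = {auc:.2f}")
    ax.plot([0, 1], [0, 1], color="0.7", ls=":")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
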