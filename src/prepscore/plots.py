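"""Agreement figures: predicted-vs-reference scatter and Bland–Altman."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import PairedScores, bland_altman

__all__ = ["scatter_plot", "bland_altman_plot"]


def scatter_plot(p: PairedScores, path: str | Path, title: str = "") -> Path:
    """Predicted vs reference totals with the 45° identity line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    lo = min(p.reference.min(), p.predicted.min()) - 1
    hi = max(p.reference.max(), p.predicted.max()) + 1
    ax.plot([lo, hi], [lo, hi], "--", color="grey", lw=1, label="identity")
    ax.scatter(p.reference, p.predicted, s=30, alpha=0.8)
    ax.set_xlabel("reference total (rubric points)")
    ax.set_ylabel("predicted total (rubric points)")
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def bland_altman_plot(p: PairedScores, path: str | Path, title: str = "") -> Path:
    """Differences against means with bias and 95% limits of agreement."""
    bias, lo, hi = bland_altman(p)
    means = (p.reference + p.predicted) / 2.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, p.differences, s=30, alpha=0.8)
    for y, style, label in ((bias, "-", f"bias {bias:+.2f}"),
                            (lo, "--", f"LoA {lo:+.2f}"),
                            (hi, "--", f"LoA {hi:+.2f}")):
        ax.axhline(y, ls=style, color="grey", lw=1)
        ax.annotate(label, xy=(1.01, y), xycoords=("axes fraction", "data"),
                    fontsize=8, va="center", annotation_clip=False)
    ax.set_xlabel("mean of methods (rubric points)")
    ax.set_ylabel("predicted − reference (rubric points)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
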