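"""Thin plotting layer over the curve families.

Every plot has an exact TSV/JSON twin written by :mod:`curveval.io`; the
figures here are conveniences, never the data of record.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

_FAMILY_AXES = {
    "roc": ("false positive rate", "true positive rate"),
    "prc": ("recall", "precision"),
    "croc": ("magnified false positive rate", "true positive rate"),
    "cc": ("PCF(+)", "NE[C]"),
}


def plot_curves(
    curves: Mapping[str, tuple[np.ndarray, np.ndarray]],
    path: Union[str, Path],
    baselines: Optional[Mapping[str, float]] = None,
    title: Optional[str] = None,
) -> None:
    """Multi-panel plot, one panel per curve family.

    ``curves`` maps a family name (roc/prc/croc/cc) to its (x, y) arrays;
    ``baselines`` optionally adds the random-classifier reference — the
    diagonal for roc, a horizontal line at P/(P+N) for prc, the tent
    min(x, 1-x) for cc.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    families = list(curves)
    ncols = min(2, len(families))
    nrows = (len(families) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 4 * nrows), squeeze=False)
    for ax in axes.ravel()[len(families):]:
        ax.set_visible(False)
    for ax, fam in zip(axes.ravel(), families):
        x, y = curves[fam]
        ax.plot(x, y, lw=1.5)
        xlabel, ylabel = _FAMILY_AXES.get(fam, ("x", "y"))
        if fam == "roc":
            ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        elif fam == "cc":
            grid = np.linspace(0, 1, 101)
            ax.plot(grid, np.minimum(grid, 1 - grid), ls="--", c="grey", lw=0.8)
        elif fam == "prc" and baselines and "prc" in baselines:
            ax.axhline(baselines["prc"], ls="--", c="grey", lw=0.8)
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.02)
        ax.set_title(fam.upper())
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rank_distribution(
    ranks_pos: Sequence[int],
    ranks_neg: Sequence[int],
    path: Union[str, Path],
    title: Optional[str] = None,
) -> None:
    """Scatter of ranks by class, visualising how a level separates classes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.scatter(ranks_neg, np.zeros(len(ranks_neg)), marker="o", s=12,
               c="firebrick", alpha=0.5, label="negatives")
    ax.scatter(ranks_pos, np.ones(len(ranks_pos)), marker="^", s=12,
               c="seagreen", alpha=0.5, label="positives")
    ax.set_yticks([0, 1], ["neg", "pos"])
    ax.set_xlabel("rank (low to high score)")
    ax.legend(loc="center right", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
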